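"""Loop enumeration, Bucher inconsistency factors, global test."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nma_stiffness import enumerate_loops, global_test, loop_if
from nma_stiffness.data import (
    ArmSummary,
    NetworkDataset,
    StudyRecord,
    TreatmentClass,
    default_codebook,
)
from nma_stiffness.inconsistency import canonical_loop
from nma_stiffness.preprocess import ContrastRecord


def _contrast(study, treat, comp, md, se):
    by = {t.code: t for t in default_codebook()}
    return ContrastRecord(study, by[treat], by[comp], md, se, True)


def _network_from_pairs(pairs):
    """Minimal one-study-per-pair network for geometry tests."""
    codes = sorted({c for p in pairs for c in p})
    cb = tuple(
        TreatmentClass(c, c, is_reference=(c == "placebo")) for c in ["placebo"] + [c for c in codes if c != "placebo"]
    )
    by = {t.code: t for t in cb}
    studies = []
    for i, (a, b) in enumerate(pairs):
        studies.append(
            StudyRecord(
                f"s{i}",
                (ArmSummary(by[a], 20, -0.2, 1.0), ArmSummary(by[b], 20, 0.1, 1.0)),
                "T2DM",
                24,
            )
        )
    return NetworkDataset(tuple(studies), cb)


class TestEnumerateLoops:
    def test_fixture_has_exactly_six_loops(self, table1):
        loops = enumerate_loops(table1)
        assert len(loops) == 6
        assert set(loops) == {
            canonical_loop(("placebo", "GLP1RA", "SGLT2i")),
            canonical_loop(("placebo", "GLP1RA", "metformin")),
            canonical_loop(("placebo", "TZD", "metformin")),
            canonical_loop(("placebo", "DPP4i", "metformin")),
            canonical_loop(("metformin", "TZD", "sulfonylurea", "DPP4i")),
            canonical_loop(("placebo", "TZD", "sulfonylurea", "DPP4i")),
        }

    def test_star_network_has_no_loops(self):
        ds = _network_from_pairs(
            [("GLP1RA", "placebo"), ("SGLT2i", "placebo"), ("TZD", "placebo")]
        )
        assert enumerate_loops(ds) == []

    def test_triangle_network_has_one_loop(self):
        ds = _network_from_pairs(
            [("GLP1RA", "placebo"), ("SGLT2i", "placebo"), ("GLP1RA", "SGLT2i")]
        )
        assert enumerate_loops(ds) == [canonical_loop(("placebo", "GLP1RA", "SGLT2i"))]

    def test_matches_bruteforce_chordless_cycle_search(self, table1):
        g = table1.graph()
        found = set()
        for r in (3, 4):
            for nodes in itertools.combinations(sorted(g.nodes), r):
                sub = g.subgraph(nodes)
                if sub.number_of_edges() == r and all(
                    d == 2 for _, d in sub.degree()
                ) and nx.is_connected(sub):
                    cyc = [nodes[0]]
                    while len(cyc) < r:
                        cyc.append(
                            next(
                                n
                                for n in sub.neighbors(cyc[-1])
                                if n not in cyc or (len(cyc) == r and n == cyc[0])
                            )
                        )
                    found.add(canonical_loop(tuple(cyc)))
        assert set(enumerate_loops(table1)) == found


class TestLoopIF:
    def test_exactly_consistent_triangle(self):
        cs = [
            _contrast("ab", "GLP1RA", "placebo", -1.0, 0.5),
            _contrast("ac", "SGLT2i", "placebo", -0.6, 0.4),
            _contrast("bc", "SGLT2i", "GLP1RA", 0.4, 0.3),
        ]
        rep = loop_if(("placebo", "GLP1RA", "SGLT2i"), cs)
        assert rep.if_abs == pytest.approx(0.0, abs=1e-12)
        assert rep.p == pytest.approx(1.0)
        assert not rep.inconsistent

    def test_hand_computed_inconsistency(self):
        cs = [
            _contrast("ab", "GLP1RA", "placebo", -0.2, 0.5),
            _contrast("ac", "SGLT2i", "placebo", -0.6, 0.4),
            _contrast("bc", "SGLT2i", "GLP1RA", 0.4, 0.3),
        ]
        rep = loop_if(("placebo", "GLP1RA", "SGLT2i"), cs)
        assert rep.if_abs == pytest.approx(0.8, abs=1e-12)
        assert rep.se_if == pytest.approx(np.sqrt(0.25 + 0.16 + 0.09), abs=1e-9)
        assert rep.z == pytest.approx(0.8 / np.sqrt(0.5), abs=1e-4)
        assert rep.ci_low == 0.0  # truncated at zero by convention

    def test_orientation_and_start_invariance(self, table1, contrasts_table1):
        loop = ("placebo", "GLP1RA", "SGLT2i")
        base = loop_if(loop, contrasts_table1)
        for variant in [
            ("GLP1RA", "SGLT2i", "placebo"),
            ("SGLT2i", "GLP1RA", "placebo"),
            tuple(reversed(loop)),
        ]:
            rep = loop_if(variant, contrasts_table1)
            assert rep.if_abs == pytest.approx(base.if_abs, abs=1e-12)
            assert rep.se_if == pytest.approx(base.se_if, abs=1e-12)

    def test_scale_invariance_of_z(self):
        cs = [
            _contrast("ab", "GLP1RA", "placebo", -0.2, 0.5),
            _contrast("ac", "SGLT2i", "placebo", -0.6, 0.4),
            _contrast("bc", "SGLT2i", "GLP1RA", 0.4, 0.3),
        ]
        scaled = [
            _contrast(c.study_id, c.treat.code, c.comparator.code, 3.0 * c.md, 3.0 * c.se)
            for c in cs
        ]
        z0 = loop_if(("placebo", "GLP1RA", "SGLT2i"), cs).z
        z1 = loop_if(("placebo", "GLP1RA", "SGLT2i"), scaled).z
        assert z1 == pytest.approx(z0, abs=1e-9)

    def test_missing_direct_evidence_rejected(self):
        cs = [
            _contrast("ab", "GLP1RA", "placebo", -0.2, 0.5),
            _contrast("ac", "SGLT2i", "placebo", -0.6, 0.4),
        ]
        with pytest.raises(ValueError, match="no direct evidence"):
            loop_if(("placebo", "GLP1RA", "SGLT2i"), cs)


class TestGlobalTest:
    def test_exactly_consistent_network_gives_zero_statistic(self):
        # single design per edge, mds satisfying d_G = -1.0, d_S = -0.6
        cs = [
            _contrast("ab", "GLP1RA", "placebo", -1.0, 0.5),
            _contrast("ac", "SGLT2i", "placebo", -0.6, 0.4),
            _contrast("bc", "SGLT2i", "GLP1RA", 0.4, 0.3),
        ]
        g = global_test(cs)
        assert g.statistic == pytest.approx(0.0, abs=1e-10)
        assert g.df == 1
        assert g.p == pytest.approx(1.0)

    def test_no_loops_is_an_error(self):
        cs = [
            _contrast("a", "GLP1RA", "placebo", -1.0, 0.5),
            _contrast("b", "SGLT2i", "placebo", -0.6, 0.4),
        ]
        with pytest.raises(ValueError, match="no loops"):
            global_test(cs)

    def test_fixture_degrees_of_freedom(self, contrasts_table1):
        g = global_test(contrasts_table1)
        assert g.df == 5  # 11 two-arm designs - 6 basic effects
        assert 0.0 <= g.p <= 1.0

    def test_large_planted_offset_detected(self):
        # consistent triangle with strong evidence, then shift one edge by 5 se
        rng = np.random.default_rng(0)
        cs = []
        for i in range(3):
            cs.append(_contrast(f"ab{i}", "GLP1RA", "placebo", -1.0 + 0.05 * rng.standard_normal(), 0.2))
            cs.append(_contrast(f"ac{i}", "SGLT2i", "placebo", -0.6 + 0.05 * rng.standard_normal(), 0.2))
            cs.append(_contrast(f"bc{i}", "SGLT2i", "GLP1RA", 0.4 + 0.05 * rng.standard_normal(), 0.2))
        shifted = [
            _contrast(c.study_id, c.treat.code, c.comparator.code, c.md + (1.0 if c.study_id.startswith("ab") else 0.0), c.se)
            for c in cs
        ]
        assert global_test(cs).p > 0.05
        assert global_test(shifted).p < 0.05
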