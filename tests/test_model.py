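"""Bayesian network model: conjugate limits, oracles, reproducibility."""

import math

import numpy as np
import pytest

from nma_stiffness import (
    ConvergenceError,
    McmcConfig,
    ModelSpec,
    fit_nma,
    league_table,
    summarize,
)
from nma_stiffness.data import (
    ArmSummary,
    NetworkDataset,
    StudyRecord,
    TreatmentClass,
    default_codebook,
)


def _single_study_network(md=-1.0, sd=2.0, n=40):
    cb = (
        TreatmentClass("placebo", "Placebo", is_reference=True),
        TreatmentClass("GLP1RA", "GLP-1 RA"),
    )
    study = StudyRecord(
        "only",
        (
            ArmSummary(cb[1], n, md, sd),
            ArmSummary(cb[0], n, 0.0, sd),
        ),
        "T2DM",
        24,
    )
    return NetworkDataset((study,), cb), math.sqrt(2.0) * sd / math.sqrt(n)


def _wls_fixed_effect(contrasts, treatments, reference):
    """Independent oracle: weighted least squares on the contrast data."""
    free = [t for t in treatments if t != reference]
    X = np.zeros((len(contrasts), len(free)))
    for j, c in enumerate(contrasts):
        if c.treat.code != reference:
            X[j, free.index(c.treat.code)] += 1.0
        if c.comparator.code != reference:
            X[j, free.index(c.comparator.code)] -= 1.0
    w = np.array([1.0 / c.se**2 for c in contrasts])
    y = np.array([c.md for c in contrasts])
    beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
    return dict(zip(free, beta))


class TestVaguePriorLimits:
    def test_single_study_posterior_matches_study_contrast(self):
        ds, se = _single_study_network()
        draws = fit_nma(
            ds,
            ModelSpec(tau_fixed=0.0),
            McmcConfig(chains=3, burn_in=500, samples=5000, seed=6),
        )
        vec = draws.contrast_draws("GLP1RA", "placebo")
        assert vec.mean() == pytest.approx(-1.0, abs=0.02)
        assert vec.std() == pytest.approx(se, rel=0.05)

    def test_tau_zero_matches_wls_network_estimate(self, table1, contrasts_table1):
        draws = fit_nma(
            table1,
            ModelSpec(tau_fixed=0.0),
            McmcConfig(chains=3, burn_in=1000, samples=5000, seed=5),
        )
        oracle = _wls_fixed_effect(
            contrasts_table1, draws.treatments, draws.reference
        )
        for t, beta in oracle.items():
            mean, _, _ = summarize(draws, t, "placebo")
            assert mean == pytest.approx(beta, abs=0.05)


class TestDrawInvariants:
    def test_reference_column_identically_zero(self, draws_short):
        ref_idx = draws_short.index("placebo")
        assert np.all(draws_short.d[:, :, ref_idx] == 0.0)

    def test_tau_within_prior_support(self, draws_short):
        tau = draws_short.pooled_tau()
        assert np.all(tau > 0.0)
        assert np.all(tau < 5.0)

    def test_consistency_identity_per_draw(self, draws_short):
        d = draws_short.pooled_d()
        ia = draws_short.index("GLP1RA")
        ib = draws_short.index("metformin")
        ic = draws_short.index("SGLT2i")
        lhs = d[:, ia] - d[:, ib]
        rhs = (d[:, ia] - d[:, ic]) + (d[:, ic] - d[:, ib])
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_diagnostics_reported_for_all_monitored(self, draws_short):
        names = set(draws_short.diagnostics["parameter"])
        assert "tau" in names
        assert sum(n.startswith("d[") for n in names) == 6


class TestSummaries:
    def test_self_contrast_is_zero(self, draws_short):
        assert summarize(draws_short, "placebo", "placebo") == (0.0, 0.0, 0.0)

    def test_antisymmetry(self, draws_short):
        m_ab, lo_ab, hi_ab = summarize(draws_short, "GLP1RA", "metformin")
        m_ba, lo_ba, hi_ba = summarize(draws_short, "metformin", "GLP1RA")
        assert m_ab == pytest.approx(-m_ba, abs=1e-12)
        assert lo_ab == pytest.approx(-hi_ba, abs=1e-9)
        assert hi_ab == pytest.approx(-lo_ba, abs=1e-9)

    def test_unknown_treatment_rejected(self, draws_short):
        with pytest.raises(KeyError):
            summarize(draws_short, "GLP1RA", "insulin")

    def test_league_table_consistent_with_summarize(self, draws_short):
        league = league_table(draws_short)
        assert len(league) == 49
        row = league[
            (league["treat"] == "SGLT2i") & (league["comparator"] == "placebo")
        ].iloc[0]
        mean, lo, hi = summarize(draws_short, "SGLT2i", "placebo")
        assert row["mean"] == mean
        assert (row["ci_low"], row["ci_high"]) == (lo, hi)
        diag = league[league["treat"] == league["comparator"]]
        assert (diag["mean"] == 0.0).all()
        assert not diag["significant"].any()


class TestReproducibility:
    def test_same_seed_bit_identical(self, table1):
        mc = McmcConfig(chains=2, burn_in=200, samples=800, seed=99, check_convergence=False)
        a = fit_nma(table1, mcmc=mc)
        b = fit_nma(table1, mcmc=mc)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.tau, b.tau)

    def test_different_seeds_agree_within_mc_error(self, table1):
        out = []
        for seed in (21, 22):
            d = fit_nma(
                table1,
                mcmc=McmcConfig(chains=3, burn_in=2000, samples=6000, seed=seed),
            )
            out.append(summarize(d, "GLP1RA", "placebo")[0])
        assert out[0] == pytest.approx(out[1], abs=0.06)

    def test_reference_invariance_of_contrasts(self, table1, draws_short):
        alt = fit_nma(
            table1,
            ModelSpec(reference="metformin"),
            McmcConfig(chains=3, burn_in=2000, samples=8000, seed=13),
        )
        for a, b in [("GLP1RA", "placebo"), ("SGLT2i", "TZD")]:
            m0, _, _ = summarize(draws_short, a, b)
            m1, _, _ = summarize(alt, a, b)
            assert m0 == pytest.approx(m1, abs=0.12)

    def test_contrast_likelihood_agrees_with_arm_based(self, table1, draws_short):
        alt = fit_nma(
            table1,
            ModelSpec(likelihood="contrast"),
            McmcConfig(chains=3, burn_in=2000, samples=8000, seed=14),
        )
        for t in ("GLP1RA", "SGLT2i", "metformin"):
            m0, _, _ = summarize(draws_short, t, "placebo")
            m1, _, _ = summarize(alt, t, "placebo")
            assert m0 == pytest.approx(m1, abs=0.12)


class TestFailureModes:
    def test_unconverged_chains_fail_loudly(self, table1):
        with pytest.raises(ConvergenceError):
            fit_nma(
                table1,
                mcmc=McmcConfig(chains=3, burn_in=0, samples=30, seed=1),
            )

    def test_empty_dataset_rejected(self):
        cb = default_codebook()
        with pytest.raises(Exception):
            fit_nma(NetworkDataset((), tuple(cb)))

    def test_invalid_likelihood_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(likelihood="binomial")
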