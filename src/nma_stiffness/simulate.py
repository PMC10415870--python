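"""Synthetic trial networks with known truth for parameter recovery.

The generator emulates the structure of the real evidence base: a set of
(by default two-arm) randomized trials on a connected network of drug
classes, each trial reporting per-arm change-score means, SDs and sample
sizes.  The data-generating process mirrors the analysis model: a trial
draws its baseline change ``mu_i``, a trial-specific contrast effect around
the true basic-effect difference with between-trial SD ``tau_true``, and
arm means with sampling noise ``sd^2/n``.  An optional constant offset can
be planted on one edge to create genuine inconsistency for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ArmSummary,
    NetworkDataset,
    StudyRecord,
    TreatmentClass,
    default_codebook,
)
from .fixture import fixture_table1
from .model import PosteriorDraws


def _default_true_effects() -> dict[str, float]:
    # magnitudes typical of the PWV evidence base (m/s vs placebo)
    return {
        "placebo": 0.0,
        "GLP1RA": -1.11,
        "sulfonylurea": -0.78,
        "SGLT2i": -0.76,
        "metformin": -0.73,
        "DPP4i": -0.70,
        "TZD": -0.51,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Truth and design of a synthetic trial network.

    ``edge_design`` chooses the comparison structure: ``star`` (every
    non-reference class vs placebo), ``published_geometry`` (the 18-trial
    published design list) or ``random_connected`` (a random spanning tree
    plus random extra comparisons).  ``inconsistency_offset`` plants a
    constant shift on every trial of one edge.
    """

    d_true: dict[str, float] = field(default_factory=_default_true_effects)
    tau_true: float = 0.6
    n_studies: int = 18
    arms_per_study: int = 2
    n_per_arm: tuple[int, int] = (13, 97)
    baseline_mean_range: tuple[float, float] = (-1.0, 1.0)
    arm_sd_range: tuple[float, float] = (0.3, 3.5)
    edge_design: str = "published_geometry"
    inconsistency_offset: tuple[tuple[str, str], float] | None = None
    reference: str = "placebo"
    population: str = "T2DM"
    duration_weeks: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_design not in ("star", "published_geometry", "random_connected"):
            raise ValueError(f"unknown edge design {self.edge_design!r}")
        if self.tau_true < 0:
            raise ValueError("tau_true must be nonnegative")
        if self.arms_per_study != 2:
            raise ValueError("only two-arm studies are generated")


def _design_list(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """(treat, comparator) pair per study; comparator is the baseline arm."""
    codes = list(cfg.d_true)
    ref = cfg.reference
    if ref not in codes:
        raise ValueError(f"reference {ref!r} missing from d_true")
    others = [c for c in codes if c != ref]
    if cfg.edge_design == "star":
        return [(others[i % len(others)], ref) for i in range(cfg.n_studies)]
    if cfg.edge_design == "published_geometry":
        fixture = fixture_table1()
        pairs = []
        for s in fixture.studies:
            b = s.baseline_arm_index()
            t = 1 - b
            pairs.append((s.arms[t].treatment.code, s.arms[b].treatment.code))
        reps = [pairs[i % len(pairs)] for i in range(cfg.n_studies)]
        return reps
    # random_connected: spanning tree over all classes, then random edges
    order = list(rng.permutation(others))
    tree = [(order[0], ref)]
    for i, node in enumerate(order[1:], start=1):
        attach = rng.choice([ref] + order[:i])
        tree.append((node, str(attach)))
    pairs = list(tree)
    while len(pairs) < cfg.n_studies:
        a, b = rng.choice(codes, size=2, replace=False)
        pairs.append((str(a), str(b)))
    return pairs[: cfg.n_studies]


def simulate_network(
    cfg: SimulationConfig,
) -> tuple[NetworkDataset, dict]:
    """Generate a synthetic network dataset plus its truth record.

    The truth record carries the basic effects, the heterogeneity SD, the
    per-study sampled trial effects and any planted inconsistency offset, so
    recovery can be scored after refitting.
    """
    rng = np.random.default_rng(cfg.seed)
    codebook = [
        TreatmentClass(code, code, is_reference=(code == cfg.reference))
        for code in cfg.d_true
    ]
    by_code = {t.code: t for t in codebook}
    pairs = _design_list(cfg, rng)

    offset_edge = None
    offset_val = 0.0
    if cfg.inconsistency_offset is not None:
        (ea, eb), offset_val = cfg.inconsistency_offset
        offset_edge = frozenset((ea, eb))

    studies = []
    true_deltas = []
    for i, (treat, comp) in enumerate(pairs):
        mu_i = rng.uniform(*cfg.baseline_mean_range)
        d_contrast = cfg.d_true[treat] - cfg.d_true[comp]
        if offset_edge is not None and frozenset((treat, comp)) == offset_edge:
            d_contrast += offset_val
        delta_i = rng.normal(d_contrast, cfg.tau_true)
        true_deltas.append(delta_i)
        arms = []
        for code, expect in ((treat, mu_i + delta_i), (comp, mu_i)):
            n = int(rng.integers(cfg.n_per_arm[0], cfg.n_per_arm[1] + 1))
            sd = rng.uniform(*cfg.arm_sd_range)
            mean = rng.normal(expect, sd / np.sqrt(n))
            arms.append(
                ArmSummary(
                    treatment=by_code[code],
                    n=n,
                    change_mean=float(mean),
                    change_sd=float(sd),
                )
            )
        studies.append(
            StudyRecord(
                study_id=f"sim{i + 1:03d}",
                arms=tuple(arms),
                population=cfg.population,
                duration_weeks=cfg.duration_weeks,
            )
        )
    ds = NetworkDataset(studies=tuple(studies), treatments=tuple(codebook))
    truth = {
        "d_true": dict(cfg.d_true),
        "tau_true": cfg.tau_true,
        "trial_effects": true_deltas,
        "designs": pairs,
        "inconsistency_offset": cfg.inconsistency_offset,
        "seed": cfg.seed,
    }
    return ds, truth


def score_recovery(
    truths: list[dict], fits: list[PosteriorDraws]
) -> pd.DataFrame:
    """Bias, RMSE and 95% credible-interval coverage per treatment.

    ``truths`` and ``fits`` are matched replicates; effects are scored
    relative to the reference so the truth and posterior live on the same
    scale.
    """
    if len(truths) != len(fits):
        raise ValueError("truths and fits must match one-to-one")
    if not fits:
        raise ValueError("no replicates")
    treatments = fits[0].treatments
    for fit, truth in zip(fits, truths):
        if set(fit.treatments) != set(truth["d_true"]):
            raise ValueError("treatment sets of truth and fit differ")

    rows = []
    for t in treatments:
        errs, covered = [], []
        for truth, fit in zip(truths, fits):
            true_val = truth["d_true"][t] - truth["d_true"][fit.reference]
            vec = fit.contrast_draws(t, fit.reference)
            lo, hi = np.percentile(vec, [2.5, 97.5])
            errs.append(vec.mean() - true_val)
            covered.append(lo <= true_val <= hi)
        errs_arr = np.asarray(errs)
        rows.append(
            {
                "treatment": t,
                "bias": float(errs_arr.mean()),
                "rmse": float(np.sqrt(np.mean(errs_arr**2))),
                "ci_coverage": float(np.mean(covered)),
            }
        )
    # heterogeneity SD recovery
    taus_cov = [
        np.percentile(f.pooled_tau(), 2.5) <= t["tau_true"] <= np.percentile(f.pooled_tau(), 97.5)
        for t, f in zip(truths, fits)
    ]
    rows.append(
        {
            "treatment": "tau",
            "bias": float(
                np.mean([f.pooled_tau().mean() - t["tau_true"] for t, f in zip(truths, fits)])
            ),
            "rmse": float(
                np.sqrt(
                    np.mean(
                        [
                            (f.pooled_tau().mean() - t["tau_true"]) ** 2
                            for t, f in zip(truths, fits)
                        ]
                    )
                )
            ),
            "ci_coverage": float(np.mean(taus_cov)),
        }
    )
    return pd.DataFrame(rows)
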