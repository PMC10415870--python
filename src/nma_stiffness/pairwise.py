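"""Conventional pairwise random-effects meta-analysis per direct comparison.

Each network edge with direct evidence is pooled with the
DerSimonian-Laird random-effects model.  Heterogeneity is summarized by
Cochran's Q, I-squared and the DL moment estimate of the between-trial
variance; an edge is flagged ``mild`` when p(Q) >= 0.1 and I2 <= 50% and
``investigate`` otherwise.  Comparison-adjusted funnel data (study effects
centered on their edge's fixed-effect mean, against SE) support the visual
publication-bias check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ContrastRecord
from .data import TreatmentClass


@dataclass(frozen=True)
class PairwiseResult:
    treat: TreatmentClass
    comparator: TreatmentClass
    k: int
    md_pooled: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    i2: float
    p_het: float
    tau2_dl: float
    heterogeneity_flag: str  # "mild" | "investigate"


def _dl_components(md: np.ndarray, se: np.ndarray):
    """Fixed-effect weights, Q and the DL tau^2 moment estimate."""
    w = 1.0 / se**2
    mu_fe = float(np.sum(w * md) / np.sum(w))
    q = float(np.sum(w * (md - mu_fe) ** 2))
    df = len(md) - 1
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    return mu_fe, q, df, tau2


def pool_pairwise(contrasts: list[ContrastRecord]) -> PairwiseResult:
    """DerSimonian-Laird random-effects pooling of one edge's studies.

    All contrasts must share the same ordered (treat, comparator) pair.
    """
    if not contrasts:
        raise ValueError("no contrasts to pool")
    pair = (contrasts[0].treat.code, contrasts[0].comparator.code)
    if any((c.treat.code, c.comparator.code) != pair for c in contrasts):
        raise ValueError("contrasts mix different ordered treatment pairs")
    md = np.array([c.md for c in contrasts])
    se = np.array([c.se for c in contrasts])

    _, q, df, tau2 = _dl_components(md, se)
    if df > 0:
        p_het = float(stats.chi2.sf(q, df))
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    else:
        p_het, i2 = 1.0, 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * md) / np.sum(w_re))
    se_pooled = float(1.0 / np.sqrt(np.sum(w_re)))
    z = stats.norm.ppf(0.975)
    flag = "mild" if (p_het >= 0.1 and i2 <= 50.0) else "investigate"
    return PairwiseResult(
        treat=contrasts[0].treat,
        comparator=contrasts[0].comparator,
        k=len(contrasts),
        md_pooled=pooled,
        ci_low=pooled - z * se_pooled,
        ci_high=pooled + z * se_pooled,
        q=q,
        df=df,
        i2=i2,
        p_het=p_het,
        tau2_dl=tau2,
        heterogeneity_flag=flag,
    )


def pool_all_edges(contrasts: list[ContrastRecord]) -> list[PairwiseResult]:
    """Pool every direct comparison present in the contrast list.

    Contrast orientation within an edge is harmonized to the orientation of
    the first study seen on that edge.
    """
    groups: dict[frozenset[str], list[ContrastRecord]] = {}
    for c in contrasts:
        groups.setdefault(c.edge, []).append(c)
    out = []
    for edge_contrasts in groups.values():
        ref_pair = (edge_contrasts[0].treat.code, edge_contrasts[0].comparator.code)
        harmonized = [
            c if (c.treat.code, c.comparator.code) == ref_pair else c.reversed()
            for c in edge_contrasts
        ]
        out.append(pool_pairwise(harmonized))
    return out


def funnel_data(contrasts: list[ContrastRecord]) -> pd.DataFrame:
    """Comparison-adjusted funnel-plot coordinates.

    Each study effect is centered on the fixed-effect pooled mean of its own
    edge, so all edges share a common zero axis; rows are sorted by SE for an
    inverted-funnel scatter.
    """
    if not contrasts:
        raise ValueError("no contrasts")
    groups: dict[frozenset[str], list[ContrastRecord]] = {}
    for c in contrasts:
        groups.setdefault(c.edge, []).append(c)
    rows = []
    for edge_contrasts in groups.values():
        ref_pair = (edge_contrasts[0].treat.code, edge_contrasts[0].comparator.code)
        harmonized = [
            c if (c.treat.code, c.comparator.code) == ref_pair else c.reversed()
            for c in edge_contrasts
        ]
        md = np.array([c.md for c in harmonized])
        se = np.array([c.se for c in harmonized])
        mu_fe, *_ = _dl_components(md, se)
        for c in harmonized:
            rows.append(
                {
                    "study_id": c.study_id,
                    "edge": f"{ref_pair[0]} vs {ref_pair[1]}",
                    "centered_effect": c.md - mu_fe,
                    "se": c.se,
                }
            )
    return (
        pd.DataFrame(rows, columns=["study_id", "edge", "centered_effect", "se"])
        .sort_values("se", kind="stable")
        .reset_index(drop=True)
    )
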