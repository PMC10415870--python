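"""Change-score SD imputation and within-trial contrast construction.

Trials that report only baseline and final SDs get their change-score SD
imputed from the standard pre/post-correlation identity

    SD_change = sqrt(SD_base^2 + SD_final^2 - 2 * corr * SD_base * SD_final)

with a configurable correlation (default 0.5).  Medians reported with a range
or an interquartile range are converted with the usual range/6 and
(Q3 - Q1)/1.35 rules.  Each study then yields mean-difference contrasts of
every non-baseline arm against its baseline arm, with standard error
sqrt(sd_k^2/n_k + sd_b^2/n_b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .data import ArmSummary, NetworkDataset, StudyRecord, TreatmentClass


@dataclass(frozen=True)
class ImputationPolicy:
    """How to fill in change-score SDs and summary-statistic conversions.

    ``corr`` is the assumed correlation between baseline and final PWV within
    a participant; 0.5 is the conventional conservative default.  The range
    and IQR divisors are the standard conversion constants and rarely need
    changing.
    """

    corr: float = 0.5
    median_as_mean: bool = True
    range_divisor: float = 6.0
    iqr_divisor: float = 1.35
    force_imputation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr <= 1.0:
            raise ValueError(f"corr must be in [0, 1], got {self.corr}")


@dataclass(frozen=True)
class ContrastRecord:
    """A within-trial treatment contrast: mean difference in PWV change (m/s)."""

    study_id: str
    treat: TreatmentClass
    comparator: TreatmentClass
    md: float
    se: float
    agmd: bool

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study_id}: contrast SE must be positive")
        if self.treat.code == self.comparator.code:
            raise ValueError(f"{self.study_id}: treat and comparator identical")

    def reversed(self) -> "ContrastRecord":
        return ContrastRecord(
            study_id=self.study_id,
            treat=self.comparator,
            comparator=self.treat,
            md=-self.md,
            se=self.se,
            agmd=self.agmd,
        )

    @property
    def edge(self) -> frozenset[str]:
        return frozenset((self.treat.code, self.comparator.code))


def sd_change(baseline_sd: float, final_sd: float, corr: float) -> float:
    """Impute a change-score SD from baseline and final SDs.

    Monotone decreasing in ``corr``; zero only in the degenerate case of
    identical SDs with perfect correlation.
    """
    if baseline_sd <= 0 or final_sd <= 0:
        raise ValueError("baseline_sd and final_sd must be positive")
    if not 0.0 <= corr <= 1.0:
        raise ValueError(f"corr must be in [0, 1], got {corr}")
    radicand = baseline_sd**2 + final_sd**2 - 2.0 * corr * baseline_sd * final_sd
    # corr <= 1 guarantees radicand >= (baseline_sd - final_sd)^2 >= 0;
    # clip tiny negatives from floating point
    return math.sqrt(max(radicand, 0.0))


def sd_from_range(range_width: float, divisor: float = 6.0) -> float:
    """SD estimated from a reported range (max - min)."""
    if range_width <= 0:
        raise ValueError(f"range width must be positive, got {range_width}")
    return range_width / divisor


def sd_from_iqr(q1: float, q3: float, divisor: float = 1.35) -> float:
    """SD estimated from a reported interquartile range."""
    if q3 <= q1:
        raise ValueError(f"need q3 > q1, got q1={q1}, q3={q3}")
    return (q3 - q1) / divisor


def arm_change_sd(arm: ArmSummary, policy: ImputationPolicy) -> float:
    """Resolve the change-score SD of an arm, imputing when needed.

    With ``policy.force_imputation`` the baseline/final route is used even
    when a change SD is printed (sensitivity analyses).
    """
    use_imputed = arm.change_sd is None or (
        policy.force_imputation
        and arm.baseline_sd is not None
        and arm.final_sd is not None
    )
    if not use_imputed:
        assert arm.change_sd is not None
        return arm.change_sd
    if arm.baseline_sd is None or arm.final_sd is None:
        raise ValueError(
            f"arm ({arm.treatment.code}) has no change_sd and no "
            "baseline/final SDs to impute from"
        )
    sd = sd_change(arm.baseline_sd, arm.final_sd, policy.corr)
    if sd <= 0:
        raise ValueError(
            f"imputed change SD is zero for arm ({arm.treatment.code}); "
            "perfectly correlated identical SDs cannot be used"
        )
    return sd


def study_contrasts(
    study: StudyRecord, policy: ImputationPolicy
) -> list[ContrastRecord]:
    """All-vs-baseline contrasts for one study."""
    b = study.baseline_arm_index()
    base = study.arms[b]
    sd_b = arm_change_sd(base, policy)
    out = []
    for i, arm in enumerate(study.arms):
        if i == b:
            continue
        sd_k = arm_change_sd(arm, policy)
        se = math.sqrt(sd_k**2 / arm.n + sd_b**2 / base.n)
        out.append(
            ContrastRecord(
                study_id=study.study_id,
                treat=arm.treatment,
                comparator=base.treatment,
                md=arm.change_mean - base.change_mean,
                se=se,
                agmd=study.agmd,
            )
        )
    return out


def build_contrasts(
    ds: NetworkDataset, policy: ImputationPolicy | None = None
) -> list[ContrastRecord]:
    """Mean-difference contrasts (treat vs baseline arm) for every study."""
    policy = policy or ImputationPolicy()
    out: list[ContrastRecord] = []
    for study in ds.studies:
        out.extend(study_contrasts(study, policy))
    return out
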