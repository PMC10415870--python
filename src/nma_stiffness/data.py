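"""Arm-level trial data model, validation and delimited-text I/O.

One *study* is a randomized trial contributing two or more arms; each arm
reports the number of participants analysed and the change in pulse wave
velocity from baseline (mean +/- SD, m/s).  A collection of studies forms a
treatment network whose nodes are drug classes and whose edges are the
within-study comparisons; everything downstream (contrast building, pairwise
pooling, the Bayesian network model) consumes the validated
:class:`NetworkDataset`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

#: Populations counted as abnormal glucose metabolism disease (AGMD).
AGMD_POPULATIONS = frozenset({"pre-T2DM", "T1DM", "T2DM"})

#: All population labels the data model accepts.
POPULATIONS = frozenset({"pre-T2DM", "T1DM", "T2DM", "CAD", "CHF", "NAFLD"})

#: Columns of the one-arm-per-row delimited format, in canonical order.
CSV_COLUMNS = [
    "study_id",
    "treatment",
    "n",
    "change_mean",
    "change_sd",
    "baseline_mean",
    "baseline_sd",
    "final_mean",
    "final_sd",
    "population",
    "duration_weeks",
]


class ValidationError(ValueError):
    """Raised when a dataset violates the data model.

    ``errors`` carries one message per problem so callers can report all
    violations in a file at once rather than failing on the first.
    """

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class TreatmentClass:
    """A drug class (or placebo) appearing as a network node."""

    code: str
    label: str
    is_reference: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def default_codebook() -> list[TreatmentClass]:
    """The six antidiabetic drug classes plus placebo (the reference)."""
    return [
        TreatmentClass("placebo", "Placebo", is_reference=True),
        TreatmentClass("GLP1RA", "GLP-1 receptor agonists"),
        TreatmentClass("SGLT2i", "SGLT-2 inhibitors"),
        TreatmentClass("DPP4i", "DPP-4 inhibitors"),
        TreatmentClass("TZD", "Thiazolidinediones"),
        TreatmentClass("sulfonylurea", "Sulfonylureas"),
        TreatmentClass("metformin", "Metformin"),
    ]


@dataclass(frozen=True)
class ArmSummary:
    """Aggregate outcome of one trial arm.

    ``change_mean``/``change_sd`` summarize the change in PWV (m/s) from
    baseline to end of treatment.  When the change SD is not reported it can
    be imputed downstream from ``baseline_sd`` and ``final_sd`` with an
    assumed pre/post correlation.
    """

    treatment: TreatmentClass
    n: int
    change_mean: float
    change_sd: float | None = None
    baseline_mean: float | None = None
    baseline_sd: float | None = None
    final_mean: float | None = None
    final_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"arm needs n >= 2, got {self.n}")
        if self.change_sd is not None and self.change_sd <= 0:
            raise ValueError(f"change_sd must be positive, got {self.change_sd}")
        if self.change_sd is None and (self.baseline_sd is None or self.final_sd is None):
            raise ValueError(
                "arm without change_sd needs both baseline_sd and final_sd "
                "so the change SD can be imputed"
            )


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: ordered arms, population label and duration.

    Arm order follows the convention that the comparator/control arm comes
    last; when the reference treatment (placebo) is present it is always that
    baseline arm.
    """

    study_id: str
    arms: tuple[ArmSummary, ...]
    population: str
    duration_weeks: int

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValueError(f"{self.study_id}: study needs >= 2 arms")
        codes = [a.treatment.code for a in self.arms]
        if len(set(codes)) != len(codes):
            raise ValueError(f"{self.study_id}: duplicate treatment within study")
        if self.population not in POPULATIONS:
            raise ValueError(
                f"{self.study_id}: unknown population {self.population!r}"
            )
        if self.duration_weeks < 12:
            raise ValueError(
                f"{self.study_id}: duration_weeks must be >= 12 "
                "(trials below the long-term observation window are excluded)"
            )

    @property
    def agmd(self) -> bool:
        """Whether the population is an abnormal glucose metabolism disease."""
        return self.population in AGMD_POPULATIONS

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(a.treatment.code for a in self.arms)

    def baseline_arm_index(self) -> int:
        """Index of the arm used as the within-study baseline.

        The reference treatment, when present, is the baseline; otherwise the
        last (control) arm is.
        """
        for i, arm in enumerate(self.arms):
            if arm.treatment.is_reference:
                return i
        return len(self.arms) - 1


@dataclass(frozen=True)
class NetworkDataset:
    """Validated study collection with its treatment codebook and geometry."""

    studies: tuple[StudyRecord, ...]
    treatments: tuple[TreatmentClass, ...]

    def __post_init__(self) -> None:
        errors = _validate(self.studies, self.treatments)
        if errors:
            raise ValidationError(errors)

    @property
    def reference(self) -> TreatmentClass:
        return next(t for t in self.treatments if t.is_reference)

    @property
    def edges(self) -> frozenset[frozenset[str]]:
        """Unordered treatment pairs with direct (within-study) evidence."""
        out: set[frozenset[str]] = set()
        for s in self.studies:
            codes = s.treatments
            out.update(
                frozenset((a, b)) for i, a in enumerate(codes) for b in codes[i + 1 :]
            )
        return frozenset(out)

    def edge_multiplicity(self) -> dict[frozenset[str], int]:
        """Number of studies informing each direct comparison."""
        counts: dict[frozenset[str], int] = {}
        for s in self.studies:
            codes = s.treatments
            for i, a in enumerate(codes):
                for b in codes[i + 1 :]:
                    key = frozenset((a, b))
                    counts[key] = counts.get(key, 0) + 1
        return counts

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(t.code for t in self.treatments if self._code_in_use(t.code))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    def _code_in_use(self, code: str) -> bool:
        return any(code in s.treatments for s in self.studies)

    def treatment(self, code: str) -> TreatmentClass:
        for t in self.treatments:
            if t.code == code:
                return t
        raise KeyError(f"unknown treatment code {code!r}")


def _validate(
    studies: Sequence[StudyRecord], treatments: Sequence[TreatmentClass]
) -> list[str]:
    errors: list[str] = []
    codes = [t.code for t in treatments]
    if len(set(codes)) != len(codes):
        errors.append("treatment codes not unique")
    refs = [t for t in treatments if t.is_reference]
    if len(refs) != 1:
        errors.append(f"exactly one reference treatment required, found {len(refs)}")
        return errors
    ref = refs[0]
    if not studies:
        errors.append("empty network: no studies")
        return errors
    known = set(codes)
    used: set[str] = set()
    for s in studies:
        for code in s.treatments:
            if code not in known:
                errors.append(f"{s.study_id}: treatment {code!r} not in codebook")
            used.add(code)
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        errors.append("duplicate study_id")
    if not errors:
        g = nx.Graph()
        g.add_nodes_from(used | {ref.code})
        for s in studies:
            codes_s = s.treatments
            g.add_edges_from(
                (a, b) for i, a in enumerate(codes_s) for b in codes_s[i + 1 :]
            )
        if not nx.is_connected(g):
            comp = nx.node_connected_component(g, ref.code)
            missing = sorted(set(g.nodes) - comp)
            errors.append(
                "disconnected network: "
                f"{missing} unreachable from reference {ref.code!r}"
            )
    return errors


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_dataset(
    path: str | Path | io.TextIOBase,
    codebook: Sequence[TreatmentClass] | None = None,
) -> NetworkDataset:
    """Read a one-arm-per-row CSV/TSV file into a validated network.

    The file needs a header with at least ``study_id, treatment, n,
    change_mean, change_sd, population, duration_weeks``; baseline/final
    columns are optional.  Rows sharing a ``study_id`` form one study, in file
    order.  All validation problems are aggregated into a single
    :class:`ValidationError` with row numbers.
    """
    codebook = list(codebook) if codebook is not None else default_codebook()
    by_code = {t.code: t for t in codebook}

    sep = None
    if isinstance(path, (str, Path)) and str(path).endswith((".tsv", ".txt")):
        sep = "\t"
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {"study_id", "treatment", "n", "change_mean", "population", "duration_weeks"} - set(
        df.columns
    )
    if missing:
        raise ValidationError([f"missing required columns: {sorted(missing)}"])

    errors: list[str] = []
    studies: list[StudyRecord] = []
    for study_id, grp in df.groupby("study_id", sort=False):
        arms: list[ArmSummary] = []
        seen: set[str] = set()
        pop = str(grp["population"].iloc[0])
        dur = grp["duration_weeks"].iloc[0]
        for row in grp.itertuples():
            rowno = row.Index + 2  # header is line 1
            code = str(row.treatment)
            if code not in by_code:
                errors.append(f"row {rowno}: unknown treatment code {code!r}")
                continue
            if code in seen:
                errors.append(f"row {rowno}: duplicate treatment {code!r} in study {study_id!r}")
                continue
            seen.add(code)
            try:
                arms.append(
                    ArmSummary(
                        treatment=by_code[code],
                        n=int(row.n),
                        change_mean=float(row.change_mean),
                        change_sd=_opt(getattr(row, "change_sd", None)),
                        baseline_mean=_opt(getattr(row, "baseline_mean", None)),
                        baseline_sd=_opt(getattr(row, "baseline_sd", None)),
                        final_mean=_opt(getattr(row, "final_mean", None)),
                        final_sd=_opt(getattr(row, "final_sd", None)),
                    )
                )
            except (TypeError, ValueError) as exc:
                errors.append(f"row {rowno}: {exc}")
        if len(arms) < 2:
            errors.append(f"study {study_id!r}: single-arm study (needs >= 2 arms)")
            continue
        try:
            studies.append(
                StudyRecord(
                    study_id=str(study_id),
                    arms=tuple(arms),
                    population=pop,
                    duration_weeks=int(dur),
                )
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"study {study_id!r}: {exc}")
    if errors:
        raise ValidationError(errors)
    return NetworkDataset(studies=tuple(studies), treatments=tuple(codebook))


def _opt(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    return float(value)


def to_frame(ds: NetworkDataset) -> pd.DataFrame:
    """One row per arm, in the canonical column order."""
    rows = []
    for s in ds.studies:
        for a in s.arms:
            rows.append(
                {
                    "study_id": s.study_id,
                    "treatment": a.treatment.code,
                    "n": a.n,
                    "change_mean": a.change_mean,
                    "change_sd": a.change_sd,
                    "baseline_mean": a.baseline_mean,
                    "baseline_sd": a.baseline_sd,
                    "final_mean": a.final_mean,
                    "final_sd": a.final_sd,
                    "population": s.population,
                    "duration_weeks": s.duration_weeks,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_dataset(ds: NetworkDataset, path: str | Path) -> None:
    """Write the dataset as CSV; ``read_dataset`` round-trips it exactly."""
    # repr-based float formatting keeps the round trip bit-identical
    df = to_frame(ds)
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def subset_agmd(ds: NetworkDataset) -> NetworkDataset:
    """Restrict to abnormal-glucose-metabolism studies (pre-T2DM/T1DM/T2DM).

    Network geometry is recomputed and connectivity re-validated; raises
    :class:`ValidationError` if no AGMD study remains or the subnetwork is
    disconnected.
    """
    kept = tuple(s for s in ds.studies if s.agmd)
    if not kept:
        raise ValidationError(["empty network: no AGMD studies"])
    if all(s.agmd for s in ds.studies):
        return ds
    return replace(ds, studies=kept)
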