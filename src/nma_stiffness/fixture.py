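"""The embedded 18-trial dataset of antidiabetic drugs and PWV change.

Arm summaries (participants analysed, change in PWV mean +/- SD in m/s),
population labels and treatment durations for the 18 randomized trials the
analysis rests on, transcribed exactly as published.  Ten trials are
placebo-controlled and eight are head-to-head; fifteen enrolled patients with
abnormal glucose metabolism (pre-T2DM, T1DM or T2DM) and three enrolled
CAD, CHF and NAFLD patients respectively.

One quirk is preserved deliberately: the Kolwelter trial studied
empagliflozin (an SGLT-2 inhibitor) but is labelled DPP-4i in the published
baseline table, and the published network analysis follows that label.  The
default here reproduces the published classification; pass
``reclassify_kolwelter=True`` to file the trial under SGLT2i instead.  Either
way the network keeps the same 11 edges, since both placebo--DPP4i and
placebo--SGLT2i comparisons exist independently.
"""

from __future__ import annotations

from importlib import resources

from .data import ArmSummary, NetworkDataset, StudyRecord, default_codebook

# study_id, experimental (treatment, n, change_mean, change_sd),
# control (treatment, n, change_mean, change_sd), population, duration_weeks.
# Control arm last, matching the baseline-arm convention.
_TABLE1 = [
    ("Christoph 2012", ("TZD", 27, 0.7, 2.1), ("placebo", 27, 0.5, 2.1), "CAD", 36),
    ("Antonio 2021", ("SGLT2i", 42, -0.6, 1.4), ("placebo", 42, 0.6, 1.2), "T2DM", 24),
    ("Ikonomidis 2020", ("GLP1RA", 40, -1.1, 2.4), ("SGLT2i", 40, -1.1, 2.5), "T2DM", 48),
    ("Stakos 2005", ("TZD", 40, 1.1, 0.4), ("placebo", 97, 0.7, 0.4), "T2DM", 48),
    ("Lambadiari 2018", ("GLP1RA", 30, -0.6, 2.8), ("metformin", 30, -0.2, 3.2), "T2DM", 24),
    ("Tuttolomondo 2021", ("GLP1RA", 56, -0.3, 0.8), ("metformin", 56, 0.1, 0.7), "T2DM", 36),
    ("Kato 2010", ("TZD", 25, 0.08, 0.4), ("metformin", 25, 0.01, 0.4), "T2DM", 12),
    ("Papadopoulou 2021", ("SGLT2i", 43, -0.2, 1.1), ("placebo", 42, 0.01, 1.3), "T2DM", 12),
    ("deBoer 2021", ("DPP4i", 22, -0.4, 0.3), ("placebo", 22, 0.4, 0.3), "T2DM", 26),
    ("Kolwelter 2021", ("DPP4i", 48, -0.3, 1.6), ("placebo", 26, 0.3, 1.7), "CHF", 12),
    ("Zografou 2015", ("DPP4i", 32, -0.3, 1.5), ("metformin", 32, 0.2, 1.8), "T2DM", 24),
    ("Paiman 2021", ("GLP1RA", 22, 0.2, 2.1), ("placebo", 25, -0.2, 1.7), "T2DM", 26),
    ("Kim 2008", ("TZD", 45, -0.9, 2.5), ("placebo", 40, 0.02, 2.0), "pre-T2DM", 12),
    ("Bjornstad 2018", ("metformin", 24, -1.1, 1.2), ("placebo", 21, 4.1, 1.6), "T1DM", 12),
    ("Scalzo 2017", ("sulfonylurea", 13, -0.3, 0.9), ("DPP4i", 14, 0.2, 1.1), "T2DM", 12),
    ("Martin 2015", ("DPP4i", 24, -0.1, 1.2), ("sulfonylurea", 24, -0.4, 1.3), "T2DM", 24),
    ("Sofer 2021", ("metformin", 32, -1.0, 0.9), ("placebo", 31, 0.2, 1.0), "NAFLD", 12),
    ("Watanabe 2004", ("TZD", 13, -1.0, 2.2), ("sulfonylurea", 14, 0.1, 1.8), "T2DM", 24),
]


def fixture_table1(reclassify_kolwelter: bool = False) -> NetworkDataset:
    """The 18-study PWV-change network, as published.

    Parameters
    ----------
    reclassify_kolwelter
        File the Kolwelter empagliflozin arm under SGLT2i instead of the
        published DPP-4i label (see module docstring).
    """
    codebook = default_codebook()
    by_code = {t.code: t for t in codebook}
    studies = []
    for study_id, eg, cg, population, weeks in _TABLE1:
        arms = []
        for code, n, mean, sd in (eg, cg):
            if (
                reclassify_kolwelter
                and study_id == "Kolwelter 2021"
                and code == "DPP4i"
            ):
                code = "SGLT2i"
            arms.append(
                ArmSummary(
                    treatment=by_code[code], n=n, change_mean=mean, change_sd=sd
                )
            )
        studies.append(
            StudyRecord(
                study_id=study_id,
                arms=tuple(arms),
                population=population,
                duration_weeks=weeks,
            )
        )
    return NetworkDataset(studies=tuple(studies), treatments=tuple(codebook))


def fixture_csv_path():
    """Path to the same fixture shipped as a CSV file."""
    return resources.files("nma_stiffness").joinpath("data/pwv_trials.csv")
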