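"""End-to-end analysis orchestration and publication-style outputs.

``run_full_analysis`` chains the whole pipeline — contrasts, pairwise
pooling, the Bayesian network fit on all studies and on the
abnormal-glucose-metabolism subgroup, SUCRA ranking, and the loop/global
consistency checks — into one deterministic report with plot-ready tables.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from importlib.metadata import version as _pkg_version

from .data import NetworkDataset, read_dataset, subset_agmd
from .inconsistency import GlobalTest, LoopReport, all_loop_reports, global_test
from .model import McmcConfig, ModelSpec, PosteriorDraws, fit_nma, league_table, summarize
from .pairwise import funnel_data, pool_all_edges
from .preprocess import ImputationPolicy, build_contrasts
from .ranking import RankResult, sucra


@dataclass
class AnalysisReport:
    """Assembled outputs of the full network meta-analysis."""

    league_all: pd.DataFrame
    league_agmd: pd.DataFrame
    sucra_all: RankResult
    sucra_agmd: RankResult
    pairwise: pd.DataFrame
    forest_rows: pd.DataFrame
    funnel: pd.DataFrame
    loops: list[LoopReport]
    global_test: GlobalTest
    draws_all: PosteriorDraws
    draws_agmd: PosteriorDraws
    provenance: dict = field(default_factory=dict)

    def significant_vs_reference(self, subgroup: bool = False) -> list[str]:
        """Treatments whose 95% CrI vs the reference excludes zero."""
        league = self.league_agmd if subgroup else self.league_all
        ref = self.draws_all.reference
        hit = league[
            (league["comparator"] == ref)
            & (league["treat"] != ref)
            & league["significant"]
        ]
        return sorted(hit["treat"])


def _forest_rows(draws: PosteriorDraws) -> pd.DataFrame:
    ref = draws.reference
    rows = []
    for t in draws.treatments:
        if t == ref:
            continue
        mean, lo, hi = summarize(draws, t, ref)
        rows.append(
            {
                "label": f"{t} vs {ref}",
                "md": mean,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(
    data: NetworkDataset | str | Path,
    spec: ModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    policy: ImputationPolicy | None = None,
) -> AnalysisReport:
    """Run the complete analysis and return the assembled report.

    Deterministic given the MCMC seed: the subgroup fit and the ranking use
    seeds derived from it.
    """
    ds = data if isinstance(data, NetworkDataset) else read_dataset(data)
    spec = spec or ModelSpec()
    mcmc = mcmc or McmcConfig()
    policy = policy or ImputationPolicy()

    contrasts = build_contrasts(ds, policy)
    pairwise = pd.DataFrame(
        [
            {
                "treat": r.treat.code,
                "comparator": r.comparator.code,
                "k": r.k,
                "md_pooled": r.md_pooled,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "q": r.q,
                "df": r.df,
                "i2": r.i2,
                "p_het": r.p_het,
                "tau2_dl": r.tau2_dl,
                "heterogeneity_flag": r.heterogeneity_flag,
            }
            for r in pool_all_edges(contrasts)
        ]
    )
    funnel = funnel_data(contrasts)

    draws_all = fit_nma(ds, spec, mcmc, policy)
    ds_agmd = subset_agmd(ds)
    mcmc_agmd = McmcConfig(
        chains=mcmc.chains,
        burn_in=mcmc.burn_in,
        samples=mcmc.samples,
        thin=mcmc.thin,
        seed=mcmc.seed + 1,
        rhat_threshold=mcmc.rhat_threshold,
        check_convergence=mcmc.check_convergence,
        keep_mu=mcmc.keep_mu,
    )
    draws_agmd = fit_nma(ds_agmd, spec, mcmc_agmd, policy)

    report = AnalysisReport(
        league_all=league_table(draws_all),
        league_agmd=league_table(draws_agmd),
        sucra_all=sucra(draws_all, seed=mcmc.seed + 2),
        sucra_agmd=sucra(draws_agmd, seed=mcmc.seed + 3),
        pairwise=pairwise,
        forest_rows=pd.concat(
            [
                _forest_rows(draws_all).assign(analysis="all"),
                _forest_rows(draws_agmd).assign(analysis="agmd"),
            ],
            ignore_index=True,
        ),
        funnel=funnel,
        loops=all_loop_reports(ds, contrasts),
        global_test=global_test(contrasts),
        draws_all=draws_all,
        draws_agmd=draws_agmd,
    )
    config_blob = json.dumps(
        {
            "spec": vars(spec) | {},
            "mcmc": vars(mcmc) | {},
            "policy": vars(policy) | {},
        },
        sort_keys=True,
        default=str,
    )
    report.provenance = {
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "seed": mcmc.seed,
        "package_version": _pkg_version("nma-stiffness"),
        "python": sys.version.split()[0],
        "n_studies_all": len(ds.studies),
        "n_studies_agmd": len(ds_agmd.studies),
    }
    return report


def _round(df: pd.DataFrame, cols: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, nd in cols.items():
        if col in out:
            out[col] = out[col].round(nd)
    return out


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    """Write the report tables as CSV/JSON under ``outdir``.

    Mean differences and interval endpoints are written to 2 decimals and
    SUCRA percentages to 1, matching the usual presentation of league and
    ranking tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    league_round = {"mean": 2, "ci_low": 2, "ci_high": 2}
    _round(report.league_all, league_round).to_csv(outdir / "league_all.csv", index=False)
    _round(report.league_agmd, league_round).to_csv(outdir / "league_agmd.csv", index=False)

    sucra_rows = []
    for label, res in (("all", report.sucra_all), ("agmd", report.sucra_agmd)):
        for t, val in res.sucra_percent().items():
            sucra_rows.append({"analysis": label, "treatment": t, "sucra_pct": round(val, 1)})
    pd.DataFrame(sucra_rows).to_csv(outdir / "sucra.csv", index=False)

    _round(report.forest_rows, {"md": 2, "ci_low": 2, "ci_high": 2}).to_csv(
        outdir / "forest.csv", index=False
    )
    report.pairwise.to_csv(outdir / "pairwise.csv", index=False)
    report.funnel.to_csv(outdir / "funnel.csv", index=False)

    pd.DataFrame(
        [
            {
                "loop": "-".join(r.loop),
                "if_abs": r.if_abs,
                "se_if": r.se_if,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "z": r.z,
                "p": r.p,
                "inconsistent": r.inconsistent,
            }
            for r in report.loops
        ]
    ).to_csv(outdir / "loops.csv", index=False)

    with open(outdir / "global.json", "w") as fh:
        json.dump(
            {
                "statistic": report.global_test.statistic,
                "df": report.global_test.df,
                "p": report.global_test.p,
                "tau2": report.global_test.tau2,
            },
            fh,
            indent=2,
        )
    with open(outdir / "run.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2)
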