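# Methods

## Outcome and data model

The outcome is the change in pulse wave velocity (ΔPWV, m/s) from baseline
to end of treatment; negative values mean arterial stiffness improved. The
unit of input is the trial arm: participants analysed `n`, change-score
mean and SD, optional baseline/final summaries, a population label and the
treatment duration in weeks (trials shorter than 12 weeks are rejected, the
long-term observation window this evidence base was assembled under). Arms
sharing a study id form a trial; trials form a treatment network whose
nodes are drug classes and whose edges carry direct randomized evidence.
Validation is aggregated (every problem in a file is reported with its row
number) and requires a connected network: every class must be reachable
from placebo, the reference.

The embedded dataset contains 18 two-arm trials over seven nodes and
11 edges. Population labels drive the abnormal-glucose-metabolism (AGMD)
subgroup: pre-T2DM, T1DM and T2DM trials (15 of 18) are in; the CAD, CHF
and NAFLD trials are out. One trial of empagliflozin is classified under
DPP-4 inhibitors, following the classification used in the published
baseline table this fixture transcribes; `fixture_table1(reclassify_kolwelter=True)`
moves it to SGLT-2 inhibitors. Either way the edge set is unchanged, since
placebo–DPP4i and placebo–SGLT2i comparisons both exist independently.

## Preprocessing

Change-score SDs missing from an arm are imputed from baseline and final
SDs via

    SD_change = sqrt(SD_base² + SD_final² − 2·corr·SD_base·SD_final)

with `corr` defaulting to 0.5 — the conventional conservative choice when
the pre/post correlation is unreported — and exposed in
`ImputationPolicy` for sensitivity sweeps (`force_imputation` re-derives
SDs even where a change SD is printed). Medians with ranges or IQRs
convert by range/6 and (Q3−Q1)/1.35. None of the 18 embedded trials
actually needs imputation: all print a change SD directly.

Within-trial contrasts are all-vs-baseline mean differences,
`md = y_treat − y_base`, `se = sqrt(sd_t²/n_t + sd_b²/n_b)`. The baseline
arm is the placebo arm when present, else the trial's control arm.

## Pairwise meta-analysis

Each edge is pooled with DerSimonian–Laird random effects: Cochran's Q
against χ² for the heterogeneity p-value, I² = max(0, (Q−df)/Q)·100, and
the DL moment estimator for τ². An edge is flagged `mild` when p ≥ 0.1 and
I² ≤ 50% and `investigate` otherwise. DL is used because it is the default
moment estimator in the meta-analysis toolchains this pipeline mirrors.
Funnel data are comparison-adjusted: each study effect is centered on its
edge's fixed-effect mean, so all edges share a common zero axis. No
regression asymmetry test is fitted; the funnel output supports visual
inspection only.

## The network model

Arm-based hierarchical normal likelihood with known arm variances:

    y_ik ~ Normal(mu_i + delta_ik, sd_ik²/n_ik)

`delta` is zero in the baseline arm; non-baseline effects are exchangeable
around the consistency contrast `d_t(i,k) − d_t(i,b)` with between-trial
variance τ² (joint normal with τ²/2 covariance for multi-arm trials, which
keeps the trial-level effects coherent). The consistency identity
`d_ab = d_ac + d_cb` holds for every posterior draw by construction
because only basic effects `d` are sampled.

Priors: Normal(0, precision 1e-4) on every `mu_i` and `d_k`
(i.e. variance 1e4 — a vague prior; the alternative literal reading,
variance 1e-4, would be a near point mass at zero and contradict the
intent of a vague prior, but is available via `ModelSpec.prior_precision`
for sensitivity), and `tau ~ Uniform(0, 5)` on the between-trial SD, the
standard BUGS-style bounded-uniform heterogeneity prior. A contrast-based
likelihood (study mean differences with known SEs, no baseline
parameters) is available via `ModelSpec(likelihood="contrast")`; for
two-arm data it agrees with the arm-based fit within Monte Carlo error,
and the test suite checks that.

### Sampler

Gibbs updates throughout: `mu`, `delta` and the free `d` block all have
conjugate normal full conditionals (the `d` block is sampled jointly from
its multivariate normal conditional via Cholesky). `tau` has a nonstandard
full conditional under the uniform prior and is updated by slice sampling
with shrinkage on (0, 5). Chains start overdispersed: effects at 0/+1/−1
across chains, `tau` at 0.1/1.0/2.5. Default schedule: 3 chains, 20,000
burn-in, 80,000 kept draws, thinning 1. Convergence is assessed with split
R-hat on all monitored parameters (`d` and `tau`); the fit raises
`ConvergenceError` above 1.05 rather than returning silently suspect
draws. `ModelSpec.tau_fixed=0` gives the fixed-effect network model, whose
posterior means match a weighted-least-squares consistency fit to within
0.05 m/s (tested against an independent WLS oracle).

Degenerate inputs: a dataset with no studies, a disconnected network, or
an arm whose SD can neither be read nor imputed all fail loudly before
sampling; `corr = 1` with equal SDs would impute a zero change SD and is
rejected.

## Ranking

Per pooled posterior draw, all seven nodes (placebo included) are ranked by
effect, most negative ΔPWV first; `direction="higher"` inverts. Exact ties
are broken by a uniform random permutation of the tied set, which keeps
the rank-probability matrix doubly stochastic and gives exchangeable tied
treatments equal expected SUCRA. SUCRA is the mean of the first a−1
cumulative rank probabilities; across treatments SUCRA always averages to
0.5 exactly.

## Inconsistency

Loops are the chordless cycles of length 3 or 4 of the comparison graph,
canonicalized over rotation and reflection; the embedded network has six
(four triangles, two quadrilaterals). For each loop, edge-level direct
estimates are pooled by inverse variance with a loop-common
method-of-moments τ², and the inconsistency factor is the absolute signed
sum of pooled estimates around the cycle, with variance the sum of edge
variances; a two-sided z test at p < 0.05 flags inconsistency, and the
IF's 95% CI is truncated at zero by convention.

The global check is a design-by-treatment interaction Wald test: the
consistency model is nested in a saturated model with one mean per
(design, comparison); the drop in weighted residual sum of squares is
χ²-distributed on the interaction degrees of freedom (5 for the embedded
geometry: 11 two-arm designs minus 6 basic effects). τ² is estimated once
by a generalized method of moments on the saturated model and shared by
both fits. Networks without loops raise an error rather than reporting
p = 1. At small numbers of studies per design the plug-in τ² makes the
test somewhat anti-conservative under heterogeneity; it is exactly
calibrated when τ = 0, and the test suite checks the planted-offset
rejection behaviour by simulation.

## Synthetic data generator

`simulate_network` mirrors the analysis model: per trial a baseline change
`mu_i ~ Uniform(−1, 1)` m/s, a trial effect
`delta_i ~ Normal(d_contrast, tau_true²)` (plus any planted inconsistency
offset on one edge), and per-arm means with `sd²/n` noise. Defaults are
chosen to emulate the embedded evidence base: the 18-trial published
comparison geometry; true effects equal to the vs-placebo mean differences
that evidence base reports (GLP1RA −1.11 … TZD −0.51 m/s);
`tau_true = 0.6` m/s, a mid-range value for this outcome; arm SDs uniform
on 0.3–3.5 m/s and arm sizes uniform on 13–97, the spans observed in the
embedded trials. Alternative designs: `star` and `random_connected`.

What the generator does not emulate: publication bias or small-study
effects, non-normal outcome summaries (medians/IQRs), missing change SDs,
correlation between an arm's SD and its treatment, and multi-arm trials
(it emits two-arm studies only, though the model itself accepts
multi-arm). Passing recovery tests therefore show the estimator is
calibrated under the assumed data-generating process, not that real trial
networks satisfy those assumptions.

## Problem sizes used in the test suite

Full-schedule fits (3 × (20k + 80k)) back the reproduction checks and the
acceptance script. Parameter recovery uses 200 replicates at the 18-trial
geometry with shortened chains (2 × (500 + 1500), convergence check off),
enough for Monte Carlo error of ~±0.015 on a 95% coverage estimate; the
measured coverage band asserted is [0.90, 0.98]. Power for the global test
uses 60 replicates with a 5×median-SE offset planted on the TZD–placebo
edge (the edge with the most direct studies).

## Known limitations

- The embedded arm summaries are transcribed exactly as published, and
  they are internally discordant: a handful of trials print change SDs an
  order of magnitude tighter than the rest (implying standard errors near
  0.08–0.11 m/s) while disagreeing with each other by 0.5–5 m/s, and one
  placebo arm prints a +4.1 m/s twelve-week PWV increase that is
  physiologically implausible. A faithful random-effects fit therefore
  yields a large between-trial SD, wide credible intervals, two
  quadrilateral loops flagged inconsistent, and a SUCRA ordering led by
  metformin — not the tight intervals the original report of this evidence
  base presents. The package reproduces what the data imply, not what was
  printed alongside them; the cross-checks against independent frequentist
  fits in the test suite confirm the estimates are not an artifact of this
  sampler.
- Aggregate data only: no individual-participant modelling, no
  meta-regression on trial covariates, no informative priors, and no
  binary/count outcomes.
- The design-by-treatment τ² plug-in is noisy at this network's size;
  global-test p-values near 0.05 should be read cautiously.
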