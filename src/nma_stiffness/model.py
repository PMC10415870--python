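"""Bayesian random-effects consistency model for the treatment network.

The model is the standard arm-based hierarchical normal formulation for
aggregate continuous outcomes.  Arm k of trial i reports a change-score mean
``y_ik`` whose sampling variance ``sd_ik^2 / n_ik`` is treated as known:

    y_ik ~ Normal(mu_i + delta_ik,  sd_ik^2 / n_ik)

with ``delta`` fixed to zero in the trial's baseline arm.  Trial-specific
effects of non-baseline arms are exchangeable around the difference of basic
effects (consistency parameterization, reference effect fixed at zero):

    delta_ik ~ Normal(d_t(i,k) - d_t(i,b),  tau^2)

multi-arm trials using the joint normal with tau^2/2 covariance between arms.
Vague normal priors (mean 0, small precision) are placed on all trial
baselines mu_i and basic effects d_k, and a Uniform(0, upper) prior on the
between-trial SD tau.

Posterior sampling is Gibbs: all conditionals for mu, delta and d are
conjugate normals, and tau gets a slice-sampling update (its full
conditional under the uniform prior is nonstandard).  Multiple chains start
from overdispersed initial values; convergence is checked with the
Gelman-Rubin split R-hat and the fit fails loudly when any monitored
parameter exceeds the threshold.

A contrast-based likelihood (study mean differences with known SEs, no
baseline parameters) is available as an alternative; for two-arm trials the
two parameterizations agree within Monte Carlo error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import NetworkDataset
from .preprocess import ImputationPolicy, arm_change_sd, build_contrasts


class ConvergenceError(RuntimeError):
    """Raised when chains fail the R-hat convergence check."""


@dataclass(frozen=True)
class ModelSpec:
    """Priors and likelihood choices for the network model.

    ``prior_precision`` is the precision of the vague normal priors on trial
    baselines and basic effects (1e-4, i.e. variance 1e4).  ``tau_upper`` is
    the upper bound of the uniform prior on the between-trial SD.
    ``tau_fixed`` pins the heterogeneity SD (0 gives the fixed-effect
    network model).  ``likelihood`` selects the arm-based formulation
    (default) or the contrast-based alternative.
    """

    reference: str = "placebo"
    prior_mean: float = 0.0
    prior_precision: float = 1e-4
    tau_upper: float = 5.0
    tau_fixed: float | None = None
    likelihood: str = "arm"  # "arm" | "contrast"

    def __post_init__(self) -> None:
        if self.likelihood not in ("arm", "contrast"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.tau_upper <= 0:
            raise ValueError("tau_upper must be positive")
        if self.tau_fixed is not None and not 0 <= self.tau_fixed <= self.tau_upper:
            raise ValueError("tau_fixed must lie in [0, tau_upper]")


@dataclass(frozen=True)
class McmcConfig:
    """Chain schedule: three overdispersed chains, 20k burn-in, 80k kept."""

    chains: int = 3
    burn_in: int = 20000
    samples: int = 80000
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    check_convergence: bool = True
    keep_mu: bool = False

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if self.samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid chain schedule")


@dataclass
class PosteriorDraws:
    """Per-chain MCMC draws of the basic effects and heterogeneity SD.

    ``d`` has shape (chains, draws, treatments) and includes the reference
    column, which is identically zero.  ``tau`` has shape (chains, draws).
    ``mu`` (trial baselines, arm-based likelihood only) is retained on
    request.
    """

    treatments: tuple[str, ...]
    reference: str
    d: np.ndarray
    tau: np.ndarray
    diagnostics: pd.DataFrame
    mu: np.ndarray | None = None
    study_ids: tuple[str, ...] = field(default_factory=tuple)

    def index(self, code: str) -> int:
        try:
            return self.treatments.index(code)
        except ValueError:
            raise KeyError(f"unknown treatment {code!r}") from None

    def pooled_d(self) -> np.ndarray:
        """Draws pooled over chains, shape (chains*draws, treatments)."""
        return self.d.reshape(-1, self.d.shape[-1])

    def pooled_tau(self) -> np.ndarray:
        return self.tau.reshape(-1)

    def contrast_draws(self, a: str, b: str) -> np.ndarray:
        """Pooled draws of d_a - d_b."""
        pooled = self.pooled_d()
        return pooled[:, self.index(a)] - pooled[:, self.index(b)]

    def to_inference_data(self):
        """arviz InferenceData view of the monitored parameters."""
        import arviz as az

        free = [t for t in self.treatments if t != self.reference]
        idx = [self.treatments.index(t) for t in free]
        return az.from_dict(
            posterior={"d": self.d[:, :, idx], "tau": self.tau},
            coords={"treatment": free},
            dims={"d": ["treatment"]},
        )


# ---------------------------------------------------------------------------
# sampler internals


class _ArmData:
    """Index arrays for the arm-based likelihood, baseline arms separated."""

    def __init__(self, ds: NetworkDataset, spec: ModelSpec, policy: ImputationPolicy):
        ref = spec.reference
        codes = [t.code for t in ds.treatments]
        if ref not in codes:
            raise ValueError(f"reference {ref!r} not in codebook")
        self.treatments = tuple([ref] + [c for c in codes if c != ref])
        t_index = {c: i for i, c in enumerate(self.treatments)}

        self.study_ids = tuple(s.study_id for s in ds.studies)
        yb, vb = [], []
        si, y, v, ti, bi = [], [], [], [], []
        arms_per_study = []
        for s_idx, study in enumerate(ds.studies):
            b = study.baseline_arm_index()
            base = study.arms[b]
            sd_b = arm_change_sd(base, policy)
            yb.append(base.change_mean)
            vb.append(sd_b**2 / base.n)
            m = 0
            for i, arm in enumerate(study.arms):
                if i == b:
                    continue
                sd_k = arm_change_sd(arm, policy)
                si.append(s_idx)
                y.append(arm.change_mean)
                v.append(sd_k**2 / arm.n)
                ti.append(t_index[arm.treatment.code])
                bi.append(t_index[base.treatment.code])
                m += 1
            arms_per_study.append(m)
        self.S = len(ds.studies)
        self.M = len(y)
        self.yb = np.asarray(yb)
        self.vb = np.asarray(vb)
        self.si = np.asarray(si, dtype=int)
        self.y = np.asarray(y)
        self.v = np.asarray(v)
        self.ti = np.asarray(ti, dtype=int)
        self.bi = np.asarray(bi, dtype=int)
        self._finish(arms_per_study)

    def _finish(self, arms_per_study: list[int]) -> None:
        P = len(self.treatments) - 1
        self.P = P
        X = np.zeros((self.M, P))
        for j in range(self.M):
            if self.ti[j] > 0:
                X[j, self.ti[j] - 1] += 1.0
            if self.bi[j] > 0:
                X[j, self.bi[j] - 1] -= 1.0
        self.X = X
        # K/tau^2 is the joint prior precision of the delta block: K is the
        # identity for two-arm trials and 2*(I - J/(m+1)) for m contrasts of
        # a multi-arm trial (inverse of the tau^2/2-correlated covariance).
        K = np.zeros((self.M, self.M))
        pos = 0
        for m in arms_per_study:
            block = 2.0 * (np.eye(m) - np.ones((m, m)) / (m + 1))
            K[pos : pos + m, pos : pos + m] = block
            pos += m
        self.K = K
        self.A_base = X.T @ K @ X
        self.Agg = np.zeros((self.S, self.M))
        if self.S:
            self.Agg[self.si, np.arange(self.M)] = 1.0
        self.multi = [m for m in arms_per_study if m > 1]


class _ContrastData(_ArmData):
    """Contrast-based likelihood: study mean differences with known SEs."""

    def __init__(self, ds: NetworkDataset, spec: ModelSpec, policy: ImputationPolicy):
        ref = spec.reference
        codes = [t.code for t in ds.treatments]
        if ref not in codes:
            raise ValueError(f"reference {ref!r} not in codebook")
        self.treatments = tuple([ref] + [c for c in codes if c != ref])
        t_index = {c: i for i, c in enumerate(self.treatments)}

        contrasts = build_contrasts(ds, policy)
        self.study_ids = tuple(s.study_id for s in ds.studies)
        sid_index = {sid: i for i, sid in enumerate(self.study_ids)}
        si, y, v, ti, bi = [], [], [], [], []
        per_study = [0] * len(self.study_ids)
        for c in contrasts:
            si.append(sid_index[c.study_id])
            y.append(c.md)
            v.append(c.se**2)
            ti.append(t_index[c.treat.code])
            bi.append(t_index[c.comparator.code])
            per_study[sid_index[c.study_id]] += 1
        self.S = 0  # no baseline parameters
        self.M = len(y)
        self.yb = np.zeros(0)
        self.vb = np.zeros(0)
        self.si = np.asarray(si, dtype=int)
        self.y = np.asarray(y)
        self.v = np.asarray(v)
        self.ti = np.asarray(ti, dtype=int)
        self.bi = np.asarray(bi, dtype=int)
        self._finish([m for m in per_study if m > 0])
        self.Agg = np.zeros((0, self.M))


def _slice_sample_tau(
    tau0: float, q: float, m: int, upper: float, rng: np.random.Generator
) -> float:
    """One slice-sampling update of tau on (0, upper).

    Log full conditional (up to constants): -m*log(tau) - q/(2*tau^2),
    where q is the prior-precision-weighted residual sum of squares of the
    trial effects and m the total number of contrast dimensions.
    """

    def logf(t: float) -> float:
        return -m * math.log(t) - q / (2.0 * t * t)

    level = logf(tau0) - rng.exponential(1.0)
    lo, hi = 1e-12, upper
    while True:
        prop = rng.uniform(lo, hi)
        if logf(prop) > level:
            return prop
        if prop < tau0:
            lo = prop
        else:
            hi = prop


def fit_nma(
    ds: NetworkDataset,
    spec: ModelSpec | None = None,
    mcmc: McmcConfig | None = None,
    policy: ImputationPolicy | None = None,
) -> PosteriorDraws:
    """Fit the Bayesian random-effects consistency model by Gibbs sampling.

    Returns posterior draws of the basic effects ``d`` (m/s vs the
    reference) and the between-trial SD ``tau``, with split R-hat and
    effective-sample-size diagnostics; raises :class:`ConvergenceError` if
    any monitored R-hat exceeds the configured threshold.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or McmcConfig()
    policy = policy or ImputationPolicy()
    if not ds.studies:
        raise ValueError("empty dataset")

    data = (
        _ArmData(ds, spec, policy)
        if spec.likelihood == "arm"
        else _ContrastData(ds, spec, policy)
    )
    C, S, M, P = mcmc.chains, data.S, data.M, data.P
    p_prec = spec.prior_precision
    p_mean = spec.prior_mean
    rng = np.random.default_rng(mcmc.seed)

    tau_fixed = spec.tau_fixed
    tau0_mode = tau_fixed is not None and tau_fixed == 0.0

    # overdispersed starts: effects at 0/+1/-1 across chains, tau spread
    start_eff = np.array([0.0, 1.0, -1.0])
    start_tau = np.array([0.1, 1.0, 2.5])
    d = np.tile(start_eff[np.arange(C) % 3][:, None], (1, P))
    mu = np.tile(start_eff[np.arange(C) % 3][:, None], (1, S)) if S else np.zeros((C, 0))
    if tau_fixed is not None:
        tau = np.full(C, float(tau_fixed))
    else:
        tau = np.clip(start_tau[np.arange(C) % 3], 1e-6, spec.tau_upper * 0.99)
    delta = d @ data.X.T

    inv_v = 1.0 / data.v
    prec_mu = (
        1.0 / data.vb + data.Agg @ inv_v + p_prec if S else np.zeros(0)
    )

    keep_mu = mcmc.keep_mu and S > 0
    d_out = np.empty((C, mcmc.samples, P))
    tau_out = np.empty((C, mcmc.samples))
    mu_out = np.empty((C, mcmc.samples, S)) if keep_mu else None

    total = mcmc.burn_in + mcmc.samples * mcmc.thin
    eyeP = np.eye(P)
    kept = 0
    for it in range(total):
        # --- trial baselines mu (conjugate normal)
        if S:
            num = data.yb / data.vb + ((data.y - delta) * inv_v) @ data.Agg.T
            num = num + p_prec * p_mean
            mu = num / prec_mu + rng.standard_normal((C, S)) / np.sqrt(prec_mu)

        resid_obs = data.y - (mu[:, data.si] if S else 0.0)

        # --- trial-specific effects delta
        if tau0_mode:
            delta = d @ data.X.T
        else:
            prior_mean = d @ data.X.T
            if not data.multi:
                prec_d = inv_v + 1.0 / tau[:, None] ** 2
                num = resid_obs * inv_v + prior_mean / tau[:, None] ** 2
                delta = num / prec_d + rng.standard_normal((C, M)) / np.sqrt(prec_d)
            else:
                delta = _sample_delta_blocks(
                    data, resid_obs, prior_mean, tau, rng
                )

        # --- basic effects d (joint conjugate normal over free treatments)
        if tau0_mode:
            A = data.X.T @ (data.X * inv_v[:, None]) + p_prec * eyeP
            b = (resid_obs * inv_v) @ data.X + p_prec * p_mean
            A = np.broadcast_to(A, (C, P, P))
        else:
            A = data.A_base[None] / tau[:, None, None] ** 2 + p_prec * eyeP
            b = (delta @ data.K) @ data.X / tau[:, None] ** 2 + p_prec * p_mean
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b[..., None])[..., 0]
        z = rng.standard_normal((C, P, 1))
        d = mean + np.linalg.solve(np.swapaxes(L, 1, 2), z)[..., 0]

        # --- between-trial SD tau (slice sampling, Uniform(0, upper) prior)
        if tau_fixed is None:
            r = delta - d @ data.X.T
            qs = np.einsum("cm,mn,cn->c", r, data.K, r)
            for c in range(C):
                tau[c] = _slice_sample_tau(
                    tau[c], float(qs[c]), M, spec.tau_upper, rng
                )

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            d_out[:, kept] = d
            tau_out[:, kept] = tau
            if keep_mu:
                mu_out[:, kept] = mu  # type: ignore[index]
            kept += 1

    d_full = np.zeros((C, mcmc.samples, P + 1))
    d_full[:, :, 1:] = d_out

    diagnostics = _diagnostics(data.treatments, d_out, tau_out, tau_fixed is None)
    if mcmc.check_convergence and C >= 2:
        worst = diagnostics["rhat"].max()
        if worst > mcmc.rhat_threshold:
            bad = diagnostics.loc[diagnostics["rhat"].idxmax(), "parameter"]
            raise ConvergenceError(
                f"chains not converged: max R-hat {worst:.4f} ({bad}) exceeds "
                f"{mcmc.rhat_threshold}"
            )

    return PosteriorDraws(
        treatments=data.treatments,
        reference=data.treatments[0],
        d=d_full,
        tau=tau_out,
        diagnostics=diagnostics,
        mu=mu_out,
        study_ids=data.study_ids,
    )


def _sample_delta_blocks(data, resid_obs, prior_mean, tau, rng):
    """Block-MVN delta update when multi-arm trials are present."""
    C, M = resid_obs.shape
    delta = np.empty((C, M))
    pos = 0
    # reconstruct block extents from K's diagonal structure
    sizes = []
    while pos < M:
        m = 1
        while pos + m < M and data.K[pos, pos + m] != 0.0:
            m += 1
        sizes.append(m)
        pos += m
    pos = 0
    for m in sizes:
        sl = slice(pos, pos + m)
        K_block = data.K[sl, sl]
        for c in range(C):
            omega = K_block / tau[c] ** 2
            prec = omega + np.diag(1.0 / data.v[sl])
            b = omega @ prior_mean[c, sl] + resid_obs[c, sl] / data.v[sl]
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, b)
            z = rng.standard_normal(m)
            delta[c, sl] = mean + np.linalg.solve(L.T, z)
        pos += m
    return delta


def _diagnostics(
    treatments: tuple[str, ...],
    d_out: np.ndarray,
    tau_out: np.ndarray,
    include_tau: bool,
) -> pd.DataFrame:
    import arviz as az

    free = list(treatments[1:])
    posterior = {"d": d_out}
    if include_tau:
        posterior["tau"] = tau_out
    idata = az.from_dict(
        posterior=posterior,
        coords={"treatment": free},
        dims={"d": ["treatment"]},
    )
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for i, t in enumerate(free):
        rows.append(
            {
                "parameter": f"d[{t}]",
                "rhat": float(rhat["d"].values[i]),
                "ess_bulk": float(ess["d"].values[i]),
            }
        )
    if include_tau:
        rows.append(
            {
                "parameter": "tau",
                "rhat": float(rhat["tau"].values),
                "ess_bulk": float(ess["tau"].values),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior summaries


def summarize(
    draws: PosteriorDraws, a: str, b: str
) -> tuple[float, float, float]:
    """Posterior mean and equal-tailed 95% credible interval of d_a - d_b."""
    if a == b:
        draws.index(a)
        return (0.0, 0.0, 0.0)
    vec = draws.contrast_draws(a, b)
    lo, hi = np.percentile(vec, [2.5, 97.5])
    return (float(vec.mean()), float(lo), float(hi))


def league_table(draws: PosteriorDraws) -> pd.DataFrame:
    """All ordered treatment pairs with posterior mean, 95% CrI and a
    significance flag (credible interval excluding zero)."""
    rows = []
    for a in draws.treatments:
        for b in draws.treatments:
            mean, lo, hi = summarize(draws, a, b)
            rows.append(
                {
                    "treat": a,
                    "comparator": b,
                    "mean": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return pd.DataFrame(rows)
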