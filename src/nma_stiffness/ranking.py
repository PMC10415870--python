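"""SUCRA treatment ranking from posterior draws.

Every posterior draw induces a complete ranking of the treatments (including
the reference) by their effect on PWV change; with lower-is-better the most
negative effect gets rank 1.  Averaging over draws gives the rank-probability
matrix, its cumulative version, and the surface under the cumulative ranking
curve

    SUCRA_k = sum_{j=1}^{a-1} cum_{k,j} / (a - 1)

which is 1 for a treatment certain to be best and 0 for one certain to be
worst.  Exact ties within a draw are broken by a uniform random permutation
of the tied treatments, which keeps the rank-probability matrix doubly
stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorDraws


@dataclass(frozen=True)
class RankResult:
    """Rank probabilities, cumulative ranking curves and SUCRA values."""

    treatments: tuple[str, ...]
    rank_probs: np.ndarray  # (a, a): P(treatment k has rank r+1)
    cum_probs: np.ndarray  # (a, a): P(rank <= r+1)
    sucra: np.ndarray  # (a,), in [0, 1]

    def sucra_percent(self) -> dict[str, float]:
        return {t: float(100.0 * s) for t, s in zip(self.treatments, self.sucra)}

    def ordering(self) -> list[str]:
        """Treatments from highest to lowest SUCRA."""
        order = np.argsort(-self.sucra, kind="stable")
        return [self.treatments[i] for i in order]


def rank_with_ties(effects: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-draw ranks (0-based) with uniform random tie-breaking.

    ``effects`` is (draws, a); lower values get lower (better) ranks.  Ties
    are broken by ranking the tied set in a uniformly random order, so each
    tied treatment is equally likely to take each of the tied ranks.
    """
    effects = np.atleast_2d(effects)
    u = rng.random(effects.shape)
    order = np.lexsort((u, effects), axis=-1)
    ranks = np.empty_like(order)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(effects.shape[-1]), effects.shape), axis=-1
    )
    return ranks


def sucra(
    draws: PosteriorDraws,
    direction: str = "lower",
    seed: int = 0,
) -> RankResult:
    """Rank probabilities and SUCRA for all treatments in the network.

    ``direction="lower"`` (the default, appropriate for PWV change where
    negative means stiffness improved) ranks the most negative effect first;
    ``"higher"`` inverts.
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    effects = draws.pooled_d()
    a = effects.shape[1]
    if a < 2:
        raise ValueError("ranking needs at least two treatments")
    if direction == "higher":
        effects = -effects
    rng = np.random.default_rng(seed)
    ranks = rank_with_ties(effects, rng)

    n = effects.shape[0]
    counts = np.zeros((a, a), dtype=np.int64)
    flat = (np.arange(a)[None, :] * a + ranks).ravel()
    counts.ravel()[:] = np.bincount(flat, minlength=a * a)
    rank_probs = counts / n
    cum_probs = np.cumsum(rank_probs, axis=1)
    sucra_vals = cum_probs[:, : a - 1].mean(axis=1)
    return RankResult(
        treatments=draws.treatments,
        rank_probs=rank_probs,
        cum_probs=cum_probs,
        sucra=sucra_vals,
    )
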