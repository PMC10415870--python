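"""Loop-specific and global consistency checks for the treatment network.

Indirect evidence around a closed loop of comparisons must agree with the
direct evidence on every edge if the network is consistent.  For each
chordless loop of three or four treatments the inconsistency factor (IF) is
the absolute signed sum of the pooled direct estimates taken around the
loop; its variance is the sum of the edge variances, and a z test with
p < 0.05 flags the loop as inconsistent.  Edge estimates are pooled by
random effects with a loop-common method-of-moments heterogeneity variance.

The global check is a design-by-treatment interaction test: the consistency
model (basic effects only) is nested in a saturated model with one mean per
design and comparison, and the drop in weighted residual sum of squares is
a Wald chi-square statistic on the interaction degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import NetworkDataset
from .pairwise import _dl_components
from .preprocess import ContrastRecord


@dataclass(frozen=True)
class LoopReport:
    """Bucher-style inconsistency assessment of one loop."""

    loop: tuple[str, ...]
    if_abs: float
    se_if: float
    ci_low: float
    ci_high: float
    z: float
    p: float

    @property
    def inconsistent(self) -> bool:
        return self.p < 0.05


@dataclass(frozen=True)
class GlobalTest:
    """Design-by-treatment interaction Wald test."""

    statistic: float
    df: int
    p: float
    tau2: float


def canonical_loop(cycle: tuple[str, ...]) -> tuple[str, ...]:
    """Canonical orientation: lexicographically smallest rotation over both
    directions, so a loop compares equal regardless of start node or
    orientation."""
    best = None
    for seq in (cycle, tuple(reversed(cycle))):
        for i in range(len(seq)):
            rot = seq[i:] + seq[:i]
            if best is None or rot < best:
                best = rot
    assert best is not None
    return best


def enumerate_loops(ds: NetworkDataset) -> list[tuple[str, ...]]:
    """All chordless cycles of length 3 or 4 in the comparison graph."""
    g = ds.graph()
    loops: set[tuple[str, ...]] = set()
    nodes = sorted(g.nodes)
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            loops.add(canonical_loop((a, b, c)))
    for quad in itertools.combinations(nodes, 4):
        sub = g.subgraph(quad)
        if sub.number_of_edges() != 4:
            continue  # a chord (5-6 edges) or not a cycle (<4 edges)
        if any(d != 2 for _, d in sub.degree()):
            continue
        # walk the 4-cycle
        start = quad[0]
        nbrs = list(sub.neighbors(start))
        second = nbrs[0]
        third = next(n for n in sub.neighbors(second) if n != start)
        fourth = next(n for n in sub.neighbors(third) if n != second)
        loops.add(canonical_loop((start, second, third, fourth)))
    return sorted(loops)


def _edge_direct(
    edge: tuple[str, str], contrasts: list[ContrastRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Signed study estimates of ``edge[1]`` vs ``edge[0]`` with their SEs."""
    a, b = edge
    mds, ses = [], []
    for c in contrasts:
        pair = (c.comparator.code, c.treat.code)
        if pair == (a, b):
            mds.append(c.md)
            ses.append(c.se)
        elif pair == (b, a):
            mds.append(-c.md)
            ses.append(c.se)
    if not mds:
        raise ValueError(f"loop edge {a}--{b} has no direct evidence")
    return np.asarray(mds), np.asarray(ses)


def loop_if(
    loop: tuple[str, ...],
    contrasts: list[ContrastRecord],
    common_tau2: bool = True,
) -> LoopReport:
    """Inconsistency factor of one loop from the direct contrast data.

    Edge estimates are pooled by inverse variance with a loop-common
    method-of-moments tau^2 (set ``common_tau2=False`` to force tau^2 = 0).
    The 95% CI of |IF| is truncated at zero by convention.
    """
    loop = canonical_loop(tuple(loop))
    m = len(loop)
    edges = [(loop[i], loop[(i + 1) % m]) for i in range(m)]
    per_edge = [_edge_direct(e, contrasts) for e in edges]

    tau2 = 0.0
    if common_tau2:
        q_sum = df_sum = denom_sum = 0.0
        for md, se in per_edge:
            if len(md) < 2:
                continue
            _, q, df, _ = _dl_components(md, se)
            w = 1.0 / se**2
            q_sum += q
            df_sum += df
            denom_sum += float(np.sum(w) - np.sum(w**2) / np.sum(w))
        if denom_sum > 0:
            tau2 = max(0.0, (q_sum - df_sum) / denom_sum)

    total = 0.0
    var = 0.0
    for md, se in per_edge:
        w = 1.0 / (se**2 + tau2)
        total += float(np.sum(w * md) / np.sum(w))
        var += float(1.0 / np.sum(w))
    if_abs = abs(total)
    se_if = float(np.sqrt(var))
    z = if_abs / se_if
    p = float(2.0 * stats.norm.sf(z))
    zcrit = stats.norm.ppf(0.975)
    return LoopReport(
        loop=loop,
        if_abs=if_abs,
        se_if=se_if,
        ci_low=max(0.0, if_abs - zcrit * se_if),
        ci_high=if_abs + zcrit * se_if,
        z=z,
        p=p,
    )


def all_loop_reports(
    ds: NetworkDataset, contrasts: list[ContrastRecord]
) -> list[LoopReport]:
    return [loop_if(loop, contrasts) for loop in enumerate_loops(ds)]


def _wls_rss(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> float:
    """Weighted residual sum of squares of the WLS fit (rank-deficient ok)."""
    sw = np.sqrt(w)
    Xs = X * sw[:, None]
    ys = y * sw
    if X.shape[1] == 0:
        return float(np.sum(ys**2))
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ beta
    return float(np.sum(r**2))


def global_test(contrasts: list[ContrastRecord]) -> GlobalTest:
    """Design-by-treatment interaction test of network consistency.

    Two-stage: the between-trial variance is estimated once by a generalized
    method of moments on the saturated design model and then shared by both
    nested weighted least-squares fits.  Raises ``ValueError`` when the
    network has no loops (the interaction block is empty and the test is
    undefined).
    """
    if not contrasts:
        raise ValueError("no contrasts")
    codes = sorted({c.treat.code for c in contrasts} | {c.comparator.code for c in contrasts})
    anchor = codes[0]
    col = {t: i - 1 for i, t in enumerate(codes)}  # anchor -> -1 (dropped)

    y = np.array([c.md for c in contrasts])
    se2 = np.array([c.se**2 for c in contrasts])
    n = len(contrasts)

    Xc = np.zeros((n, len(codes) - 1))
    for j, c in enumerate(contrasts):
        if c.treat.code != anchor:
            Xc[j, col[c.treat.code]] += 1.0
        if c.comparator.code != anchor:
            Xc[j, col[c.comparator.code]] -= 1.0

    # saturated model: one mean per (design, comparison)
    design_of_study: dict[str, frozenset[str]] = {}
    for c in contrasts:
        design_of_study.setdefault(c.study_id, frozenset())
        design_of_study[c.study_id] = design_of_study[c.study_id] | {
            c.treat.code,
            c.comparator.code,
        }
    keys = []
    key_index: dict[tuple, int] = {}
    for c in contrasts:
        key = (design_of_study[c.study_id], frozenset((c.treat.code, c.comparator.code)))
        if key not in key_index:
            key_index[key] = len(keys)
            keys.append(key)
    Xf = np.zeros((n, len(keys)))
    for j, c in enumerate(contrasts):
        key = (design_of_study[c.study_id], frozenset((c.treat.code, c.comparator.code)))
        sign = 1.0 if c.treat.code == max(key[1]) else -1.0  # orient within key
        Xf[j, key_index[key]] = sign

    rank_c = np.linalg.matrix_rank(Xc)
    rank_f = np.linalg.matrix_rank(Xf)
    df = int(rank_f - rank_c)
    if df == 0:
        raise ValueError(
            "global inconsistency test undefined: the network has no loops"
        )

    # stage 1: shared tau^2 by generalized method of moments on the
    # saturated model (pure within-design heterogeneity)
    w_fe = 1.0 / se2
    q_f = _wls_rss(y, Xf, w_fe)
    XtWX = Xf.T @ (Xf * w_fe[:, None])
    XtW2X = Xf.T @ (Xf * (w_fe**2)[:, None])
    denom = float(np.sum(w_fe) - np.trace(np.linalg.pinv(XtWX) @ XtW2X))
    tau2 = max(0.0, (q_f - (n - rank_f)) / denom) if denom > 0 else 0.0

    # stage 2: Wald chi-square from the drop in weighted RSS
    w = 1.0 / (se2 + tau2)
    stat = max(0.0, _wls_rss(y, Xc, w) - _wls_rss(y, Xf, w))
    p = float(stats.chi2.sf(stat, df))
    return GlobalTest(statistic=stat, df=df, p=p, tau2=tau2)
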