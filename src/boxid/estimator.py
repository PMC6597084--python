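"""Box-counting intrinsic dimensionality from n-D tree level statistics.

The box-counting dimension of a point set is the limiting slope of
``log N(eps)`` against ``log(1/eps)`` as the box side ``eps`` shrinks, where
``N(eps)`` is the number of side-``eps`` hypercubes containing data.  The tree
supplies ``N`` per level: occupied nodes at that level plus all leaves frozen
at shallower levels (frozen points are not re-inserted deeper).

With a finite sample the log-log curve is linear only over a prefix of
levels: once ``N`` approaches the sample size ``n`` the curve flattens into
an asymptote, and the slope of a fit that includes those levels is biased
low.  The linear region is therefore bounded both by the *break level* — the
first level at which the count of nodes with data decreases, marking the
tree's maximum expansion — and by a saturation guard that excludes levels
where ``N`` already exceeds a configured fraction of ``n``.  Two ordinary
least-squares lines are fitted, over the selected prefix and over the prefix
extended by one level, and their average slope is reported as the estimate.

The per-level side length follows ``eps = 1 / (d * 2^l)`` for nominal
dimension ``d``; the ``1/d`` factor shifts ``log(1/eps)`` by a constant and
so never affects a slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .ndtree import DEFAULT_MAX_DEPTH, TreeStats, build_tree

logger = logging.getLogger(__name__)

#: Default fraction of the sample size above which a level's box count is
#: considered saturated and excluded from the linear region.
DEFAULT_SATURATION_FRACTION = 0.1


def epsilon_for_level(level: int, dim: int) -> float:
    """Hypercube side length at a tree level: ``eps = 1 / (d * 2^l)``."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return 1.0 / (dim * 2.0 ** level)


@dataclass(frozen=True)
class LevelSummary:
    """One row of the log-log curve."""

    level: int
    epsilon: float
    n_boxes: int
    log_inv_eps: float
    log_n: float


@dataclass(frozen=True)
class IDEstimate:
    """Averaged two-fit slope estimate of the intrinsic dimension."""

    break_level: int | None
    fit_level: int
    slope_a: float
    slope_b: float
    id_value: float
    fit_r2s: tuple[float, float]


@dataclass(frozen=True)
class CamastraCheck:
    """Sample-size condition ``d < 2 log10 n`` for a reliable estimate."""

    d: int
    n: int
    bound: float
    satisfied: bool


def count_boxes(stats: TreeStats, level: int) -> int:
    """Occupied boxes of side ``2^-level``: nodes with data at the level plus
    leaves frozen at shallower levels.  Beyond the deepest level every point
    sits in its own (or its multiplicity leaf's) box."""
    if level < 0:
        raise ValueError("level must be >= 0")
    if level > stats.depth:
        return stats.n_distinct
    return stats.nodes_with_data[level] + stats.cum_frozen_below[level]


def level_summaries(stats: TreeStats, dim: int | None = None) -> list[LevelSummary]:
    """Log-log coordinates for every computed level."""
    d = dim if dim is not None else stats.dim
    out = []
    for l in range(stats.depth + 1):
        eps = epsilon_for_level(l, d)
        n = count_boxes(stats, l)
        out.append(
            LevelSummary(
                level=l,
                epsilon=eps,
                n_boxes=n,
                log_inv_eps=math.log10(1.0 / eps),
                log_n=math.log10(n) if n > 0 else float("-inf"),
            )
        )
    return out


def find_break_level(stats: TreeStats) -> int | None:
    """First level where the count of nodes with data strictly decreases.

    Marks the onset of the asymptotic regime (the tree's maximum expansion).
    Plateaus are skipped; a monotone non-decreasing profile has no break and
    ``None`` is returned — the estimator then needs an explicit fit range.
    """
    nwd = stats.nodes_with_data
    if len(nwd) < 3:
        raise ValueError("need at least 3 levels of statistics")
    for l in range(1, len(nwd)):
        if nwd[l] < nwd[l - 1]:
            return l
    return None


def find_fit_level(
    summaries: list[LevelSummary],
    break_level: int | None,
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION,
) -> int:
    """End of the linear region of the log-log curve.

    The deepest level whose box count is at most ``saturation_fraction * n``
    (n = the final, fully separated count), additionally capped at
    ``break_level - 1`` (the last level before nodes-with-data starts to
    decrease) when a break exists, and kept at 2 or more so a line can be
    fitted.
    """
    if not summaries:
        raise ValueError("no level summaries")
    n = summaries[-1].n_boxes
    cutoff = max(l.level for l in summaries)
    for s in summaries:
        if s.n_boxes > saturation_fraction * n:
            cutoff = max(s.level - 1, 1)
            break
    if break_level is not None:
        cutoff = min(cutoff, break_level - 1)
    return max(cutoff, 2)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def estimate_id(
    summaries: list[LevelSummary],
    fit_level: int,
    break_level: int | None = None,
) -> IDEstimate:
    """Average the slopes of the two candidate linear prefixes.

    Ordinary least squares of ``log10 N`` on ``log10(1/eps)`` over levels
    ``1..fit_level`` and ``1..fit_level + 1`` (level 0 is the degenerate
    point ``log N = 0`` and is excluded).  The mean of the two slopes is the
    reported intrinsic dimension.
    """
    if fit_level < 2:
        raise ValueError("fit_level must be >= 2 (need >= 2 points per fit)")
    by_level = {s.level: s for s in summaries}
    deepest = max(by_level)
    end_b = min(fit_level + 1, deepest)
    if end_b <= fit_level and fit_level >= deepest:
        # cannot extend: fall back to the prefix itself for the second fit
        end_b = fit_level
    levels_a = [l for l in range(1, fit_level + 1) if l in by_level]
    levels_b = [l for l in range(1, end_b + 1) if l in by_level]
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("fewer than 2 points in a fit prefix")
    xa = np.array([by_level[l].log_inv_eps for l in levels_a])
    ya = np.array([by_level[l].log_n for l in levels_a])
    xb = np.array([by_level[l].log_inv_eps for l in levels_b])
    yb = np.array([by_level[l].log_n for l in levels_b])
    slope_a, r2_a = _ols_slope(xa, ya)
    slope_b, r2_b = _ols_slope(xb, yb)
    return IDEstimate(
        break_level=break_level,
        fit_level=fit_level,
        slope_a=slope_a,
        slope_b=slope_b,
        id_value=0.5 * (slope_a + slope_b),
        fit_r2s=(r2_a, r2_b),
    )


def camastra_check(d: int, n: int) -> CamastraCheck:
    """Sample-size condition ``d < 2 log10 n``; a warning, not an error."""
    if n < 1:
        raise ValueError("n must be >= 1")
    bound = 2.0 * math.log10(n)
    ok = d < bound
    if not ok:
        logger.warning(
            "d=%d is not below 2*log10(n)=%.3f; the estimate may be "
            "unreliable", d, bound,
        )
    return CamastraCheck(d=d, n=n, bound=bound, satisfied=ok)


@dataclass(frozen=True)
class BoxCountResult:
    """Bundle of everything the estimator computes for one dataset."""

    estimate: IDEstimate
    summaries: list[LevelSummary]
    stats: TreeStats
    camastra: CamastraCheck


def estimate_intrinsic_dimension(
    points,
    dim: int | None = None,
    max_depth: int = DEFAULT_MAX_DEPTH,
    saturation_fraction: float = DEFAULT_SATURATION_FRACTION,
    fit_level: int | None = None,
) -> BoxCountResult:
    """End-to-end estimate: build the tree, locate the linear region, fit.

    ``fit_level`` forces an explicit end of the linear region; otherwise it
    is detected automatically (break level and saturation guard).
    """
    arr = np.asarray(points, dtype=float)
    tree = build_tree(arr, dim=dim, max_depth=max_depth)
    stats = tree.level_stats()
    summaries = level_summaries(stats)
    break_level = find_break_level(stats)
    if fit_level is None:
        fit_level = find_fit_level(summaries, break_level, saturation_fraction)
        if break_level is None:
            logger.warning(
                "no break level detected (nodes-with-data never decreases); "
                "using saturation guard alone"
            )
    est = estimate_id(summaries, fit_level, break_level=break_level)
    cam = camastra_check(stats.dim, stats.n_points)
    return BoxCountResult(estimate=est, summaries=summaries, stats=stats, camastra=cam)
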