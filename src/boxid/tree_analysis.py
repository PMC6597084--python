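"""Structural analytics of the built tree: occupancy, sparsity trend, treemap.

The decomposition becomes sparser with depth: the proportion of allocated
nodes that contain data is 1 at levels 0-1 and decays roughly like ``c / l``
thereafter.  Because apparent structure below the sensor noise floor is not
behavioral, trend fitting ignores levels deeper than a configurable cutoff
(default 24).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ndtree import TreeStats

#: Deepest level used in trend fitting; deeper structure reflects sensor
#: noise rather than behavior.
DEFAULT_NOISE_FLOOR_LEVEL = 24


@dataclass(frozen=True)
class SparsityTrend:
    """Fitted coefficient of ``proportion(l) = c / l`` and its fit quality."""

    c: float
    r2: float
    fit_range: tuple[int, int]


def occupancy_profile(stats: TreeStats) -> pd.DataFrame:
    """Per-level proportion of allocated nodes that contain data.

    Levels with zero allocated nodes (beyond the last split) are excluded.
    """
    rows = []
    for l in range(stats.depth + 1):
        alloc = stats.nodes_allocated[l]
        if alloc == 0:
            continue
        rows.append(
            {
                "level": l,
                "nodes_allocated": alloc,
                "nodes_with_data": stats.nodes_with_data[l],
                "proportion": stats.nodes_with_data[l] / alloc,
            }
        )
    return pd.DataFrame(rows)


def fit_sparsity_trend(
    profile: pd.DataFrame, max_level: int = DEFAULT_NOISE_FLOOR_LEVEL
) -> SparsityTrend:
    """Least-squares fit of ``proportion = c / level`` over levels 1..max_level.

    The functional form is fixed; only ``c`` is free, so the optimum is the
    closed form ``c = sum(p_l / l) / sum(1 / l^2)``.  The reported r2
    (``1 - SSres/SStot``) is indicative only for a non-linear form.
    """
    sel = profile[(profile["level"] >= 1) & (profile["level"] <= max_level)]
    if len(sel) < 3:
        raise ValueError("need at least 3 levels to fit the sparsity trend")
    l = sel["level"].to_numpy(dtype=float)
    p = sel["proportion"].to_numpy(dtype=float)
    c = float(np.sum(p / l) / np.sum(1.0 / l**2))
    resid = p - c / l
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("-inf")
    return SparsityTrend(c=c, r2=r2, fit_range=(int(l[0]), int(l[-1])))


def export_level_treemap(
    stats: TreeStats, level_min: int = 3, level_max: int = 14
) -> tuple[pd.DataFrame, int]:
    """(level, nodes_with_data) table for a treemap, plus the level holding
    the plurality of frozen leaves."""
    if level_min > level_max:
        raise ValueError("empty level range")
    lo = max(level_min, 0)
    hi = min(level_max, stats.depth)
    if lo > hi:
        raise ValueError(
            f"range [{level_min}, {level_max}] outside computed levels"
        )
    table = pd.DataFrame(
        {
            "level": range(lo, hi + 1),
            "nodes_with_data": stats.nodes_with_data[lo : hi + 1],
        }
    )
    plurality = int(np.argmax(stats.frozen_leaves))
    return table, plurality
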