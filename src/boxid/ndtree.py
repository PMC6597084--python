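"""Lazy n-dimensional tree (hypercube) decomposition with leaf freezing.

The tree recursively halves the unit hypercube ``[0, 1]^d``.  Each node is an
axis-aligned hypercube with half-open per-axis ranges ``(a_i, b_i]`` (the root
is closed below so that coordinate 0 is insertable).  A node holding a single
point is *frozen*: it is never expanded, and the point is not re-inserted at
deeper levels.  When a second point lands in an occupied node, the node splits
into ``2^d`` half-side children and both points descend until they separate
(or a configurable maximum depth is reached, at which point they collapse into
one leaf with multiplicity).

Per-level occupancy statistics from the built tree feed the box-counting
dimension estimate: the number of occupied boxes of side ``2^-l`` equals the
number of nodes with data at level ``l`` plus all leaves frozen at shallower
levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_DEPTH = 64


class _Node:
    """A materialized tree node.  Every materialized node contains data.

    ``point`` is set on leaves (frozen once created), ``children`` on internal
    nodes; ``count`` carries multiplicity for coincident points at the depth
    cap.  ``lo`` holds the per-axis lower bounds; the side length is implied
    by ``level`` (``2**-level``), so bounds stay exact under repeated halving.
    """

    __slots__ = ("lo", "level", "point", "count", "children")

    def __init__(self, lo: tuple[float, ...], level: int):
        self.lo = lo
        self.level = level
        self.point: tuple[float, ...] | None = None
        self.count = 0
        self.children: dict[int, "_Node"] | None = None

    @property
    def side(self) -> float:
        return 2.0 ** (-self.level)

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class TreeStats:
    """Per-level occupancy statistics of a built tree.

    ``nodes_allocated[l]`` follows sibling accounting: a split allocates all
    ``2^d`` children, so the level-``l`` total is ``2^d`` per split node at
    ``l - 1`` (and 1 at the root).  ``nodes_with_data[l]`` counts nodes whose
    subtree holds at least one point; ``frozen_leaves[l]`` counts leaves
    frozen exactly at level ``l``; ``cum_frozen_below[l]`` sums frozen leaves
    at levels strictly shallower than ``l``.
    """

    dim: int
    n_points: int
    n_distinct: int
    nodes_allocated: list[int]
    nodes_with_data: list[int]
    frozen_leaves: list[int]
    cum_frozen_below: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cum_frozen_below:
            acc, out = 0, []
            for f in self.frozen_leaves:
                out.append(acc)
                acc += f
            self.cum_frozen_below = out

    @property
    def depth(self) -> int:
        """Deepest level with any node."""
        return len(self.nodes_with_data) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "level": range(len(self.nodes_with_data)),
                "nodes_allocated": self.nodes_allocated,
                "nodes_with_data": self.nodes_with_data,
                "frozen_leaves": self.frozen_leaves,
                "cum_frozen_below": self.cum_frozen_below,
            }
        )


def contains(lo: Sequence[float], level: int, point: Sequence[float]) -> bool:
    """Membership test for a hypercube with lower bounds ``lo`` at ``level``.

    Ranges are half-open ``(a, b]`` except at the root, whose lower bounds are
    closed so that a coordinate exactly 0 (e.g. the "Not Charging" battery
    code) belongs to the tree.
    """
    if len(lo) != len(point):
        raise ValueError(
            f"dimension mismatch: cube is {len(lo)}-d, point is {len(point)}-d"
        )
    side = 2.0 ** (-level)
    closed_low = level == 0
    for a, r in zip(lo, point):
        if closed_low:
            if not (a <= r <= a + side):
                return False
        elif not (a < r <= a + side):
            return False
    return True


def cells_at_level(level: int, dim: int) -> int:
    """Total hypercubes at ``level`` if every node were divided: ``(2^d)^l``."""
    return 2 ** (dim * level)


class NDTree:
    """The n-D tree: insert points, then query per-level statistics."""

    def __init__(self, dim: int, max_depth: int = DEFAULT_MAX_DEPTH):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        self.dim = dim
        self.max_depth = max_depth
        self.root: _Node | None = None
        self.n_points = 0
        # splits per level: number of nodes at that level that were split
        self._splits_per_level: dict[int, int] = {}

    # -- insertion ---------------------------------------------------------

    def _child_index(self, node: _Node, point: Sequence[float]) -> int:
        """d-bit child code: bit i set iff the point lies in the upper half
        (strictly above the midpoint) on axis i — matches the (a, b] rule."""
        half = 2.0 ** (-(node.level + 1))
        idx = 0
        for i in range(self.dim):
            if point[i] > node.lo[i] + half:
                idx |= 1 << i
        return idx

    def _child_lo(self, node: _Node, idx: int) -> tuple[float, ...]:
        half = 2.0 ** (-(node.level + 1))
        return tuple(
            node.lo[i] + half if idx >> i & 1 else node.lo[i]
            for i in range(self.dim)
        )

    def insert(self, point: Sequence[float]) -> None:
        pt = tuple(float(r) for r in point)
        if len(pt) != self.dim:
            raise ValueError(
                f"point dimension {len(pt)} != tree dimension {self.dim}"
            )
        for r in pt:
            if not (0.0 <= r <= 1.0) or math.isnan(r):
                raise ValueError(f"coordinates must lie in [0, 1]; got {pt}")
        self.n_points += 1
        if self.root is None:
            self.root = _Node((0.0,) * self.dim, 0)
            self.root.point = pt
            self.root.count = 1
            return
        node = self.root
        # descend to the deepest existing cube containing the point
        while node.children is not None:
            idx = self._child_index(node, pt)
            child = node.children.get(idx)
            if child is None:
                leaf = _Node(self._child_lo(node, idx), node.level + 1)
                leaf.point = pt
                leaf.count = 1
                node.children[idx] = leaf
                return
            node = child
        # occupied leaf: split until the two points separate (or depth cap)
        while True:
            if node.level >= self.max_depth:
                if node.point != pt:
                    logger.warning(
                        "points unseparated at max depth %d; leaf keeps "
                        "multiplicity", self.max_depth,
                    )
                else:
                    logger.warning("exact duplicate point at max depth")
                node.count += 1
                return
            old, old_count = node.point, node.count
            node.point, node.count = None, 0
            node.children = {}
            self._splits_per_level[node.level] = (
                self._splits_per_level.get(node.level, 0) + 1
            )
            i_old = self._child_index(node, old)
            i_new = self._child_index(node, pt)
            child = _Node(self._child_lo(node, i_old), node.level + 1)
            child.point = old
            child.count = old_count
            node.children[i_old] = child
            if i_new != i_old:
                leaf = _Node(self._child_lo(node, i_new), node.level + 1)
                leaf.point = pt
                leaf.count = 1
                node.children[i_new] = leaf
                return
            node = child  # cohabiting: keep splitting the shared child

    def insert_all(self, points: Iterable[Sequence[float]] | np.ndarray) -> None:
        for p in np.asarray(points, dtype=float):
            self.insert(p)

    # -- statistics --------------------------------------------------------

    def level_stats(self) -> TreeStats:
        """Count, per level: allocated nodes, nodes with data, frozen leaves."""
        if self.root is None:
            return TreeStats(self.dim, 0, 0, [0], [0], [0])
        with_data: list[int] = []
        frozen: list[int] = []
        n_distinct = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            l = node.level
            while len(with_data) <= l:
                with_data.append(0)
                frozen.append(0)
            with_data[l] += 1
            if node.children is None:
                frozen[l] += 1
                n_distinct += 1
            else:
                stack.extend(node.children.values())
        allocated = [1] + [
            self._splits_per_level.get(l, 0) * (2 ** self.dim)
            for l in range(len(with_data) - 1)
        ]
        return TreeStats(
            dim=self.dim,
            n_points=self.n_points,
            n_distinct=n_distinct,
            nodes_allocated=allocated,
            nodes_with_data=with_data,
            frozen_leaves=frozen,
        )


def build_tree(
    points: Iterable[Sequence[float]] | np.ndarray,
    dim: int | None = None,
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> NDTree:
    """Build an :class:`NDTree` from an ``(n, d)`` array of points in [0,1]."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2:
        raise ValueError("points must be a 2-D array (n, d)")
    d = dim if dim is not None else arr.shape[1]
    tree = NDTree(d, max_depth=max_depth)
    tree.insert_all(arr)
    return tree
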