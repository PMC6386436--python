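"""Uniform x-quantization and constant-time rebinning.

The preprocessor first bins points into ``m`` equal x-intervals (a single
vectorized pass), records each bin's y-extremes, and later — after the
fence polylines have been convexified — relabels every point against the
*non-uniform* intervals induced by the surviving fence vertices.  The
relabeling is the method's key trick: instead of an O(lg m) binary search
per point, an inclusive prefix sum ``S`` over the removed-fence-slot flags
turns the old uniform label ``q`` into the new label in O(1):

    new = q + 1 - S[q + 1]   if x >= C[q + 1]      (1-based arrays)
    new = q - S[q]           otherwise

where ``C`` holds the x-projections of the pre-convexification fence slots.
Empty bins and deduplicated endpoint slots are carried as slots flagged
removed up front (with the bin's left edge as placeholder abscissa), which
keeps ``C`` non-decreasing and the slot-to-bin indexing intact; no point
ever carries an empty bin's label, so those placeholders are never read by
the branch test.  The resulting label provably equals a binary search of x
over the surviving boundaries (clamped to the last segment at x = xmax),
and the test suite asserts exactly that equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InternalConsistencyError, ValidationError
from .geometry import Side
from .pointset import PointSet

__all__ = [
    "BinAssignment",
    "BinExtremes",
    "RebinTables",
    "find_x_extremes",
    "quantize_uniform",
    "per_bin_extremes",
    "build_rebin_tables",
    "rebin",
]


@dataclass(frozen=True)
class BinAssignment:
    """Per-point 1-based bin labels plus the uniform-bin metadata."""

    labels: np.ndarray  # int, in [1, m]
    m: int
    xmin: float
    xmax: float
    width: float

    def boundaries(self) -> np.ndarray:
        """The m+1 uniform interval boundaries xmin + j*width, j = 0..m."""
        return self.xmin + np.arange(self.m + 1) * self.width

    def left_edge(self, j: int) -> float:
        """Left boundary of 1-based bin j."""
        return self.xmin + (j - 1) * self.width


@dataclass(frozen=True)
class BinExtremes:
    """Per-bin indices of the min-y and max-y points; empty bins flagged."""

    min_y_index: np.ndarray  # point index, or -1 where empty
    max_y_index: np.ndarray
    empty: np.ndarray  # bool per bin


@dataclass(frozen=True)
class RebinTables:
    """Projected fence boundaries C, removed flags, and prefix sums S.

    ``c`` holds the x-projection of every pre-convexification fence slot
    (first = xmin, last = xmax, non-decreasing); ``removed`` marks slots
    dropped by convexification, empty bins, and endpoint duplicates; ``s``
    is the inclusive prefix sum of ``removed`` (1-based S_j = s[j-1]).
    """

    c: np.ndarray
    removed: np.ndarray
    s: np.ndarray

    @property
    def n_slots(self) -> int:
        return self.c.shape[0]

    def surviving_boundaries(self) -> np.ndarray:
        return self.c[~self.removed]

    @property
    def n_segments(self) -> int:
        return int((~self.removed).sum()) - 1


def find_x_extremes(points: PointSet, tie: Side = Side.LOWER) -> tuple[int, int]:
    """Indices of the min-x and max-x points.

    Multiple points may share the extreme x value; for the lower fence the
    tie goes to the smallest y (at both ends), for the upper fence to the
    largest y, so each fence's endpoints are extreme for its own side.
    Remaining ties (exact duplicate coordinates) go to the smallest index.
    """
    points.require_nonempty()
    x, y = points.x, points.y

    def pick(cand: np.ndarray) -> int:
        yc = y[cand]
        j = int(np.argmin(yc)) if tie is Side.LOWER else int(np.argmax(yc))
        return int(cand[j])

    ixmin = pick(np.flatnonzero(x == x.min()))
    ixmax = pick(np.flatnonzero(x == x.max()))
    return ixmin, ixmax


def quantize_uniform(points: PointSet, m: int) -> BinAssignment:
    """Label each point with its 1-based uniform x-bin in one pass.

    Bin j covers [xmin + (j-1)*width, xmin + j*width) with the last bin
    closed on the right; x = xmax is clamped into bin m.
    """
    points.require_nonempty()
    if m < 1:
        raise ValidationError(f"bin count must be >= 1, got {m}")
    xmin = float(points.x.min())
    xmax = float(points.x.max())
    if xmax == xmin:
        raise ValidationError(
            "all x-coordinates identical; caller must take the vertical-line path"
        )
    width = (xmax - xmin) / m
    labels = np.floor((points.x - xmin) / width).astype(np.int64) + 1
    np.clip(labels, 1, m, out=labels)
    return BinAssignment(labels, m, xmin, xmax, width)


def per_bin_extremes(points: PointSet, bins: BinAssignment) -> BinExtremes:
    """Min-y and max-y point per bin, found simultaneously in one pass.

    Ties within a bin keep the first-seen (smallest) index.
    """
    m = bins.m
    b = bins.labels - 1  # 0-based bin ids
    min_y = np.full(m, np.inf)
    max_y = np.full(m, -np.inf)
    np.minimum.at(min_y, b, points.y)
    np.maximum.at(max_y, b, points.y)
    empty = ~np.isfinite(min_y)
    min_idx = np.full(m, -1, dtype=np.intp)
    max_idx = np.full(m, -1, dtype=np.intp)
    # second vectorized pass: smallest index attaining each bin's extreme
    hit_min = points.y == min_y[b]
    hit_max = points.y == max_y[b]
    sentinel = np.full(m, len(points), dtype=np.intp)
    first_min = sentinel.copy()
    np.minimum.at(first_min, b[hit_min], np.flatnonzero(hit_min))
    first_max = sentinel.copy()
    np.minimum.at(first_max, b[hit_max], np.flatnonzero(hit_max))
    min_idx[~empty] = first_min[~empty]
    max_idx[~empty] = first_max[~empty]
    return BinExtremes(min_idx, max_idx, empty)


def build_rebin_tables(
    fence_projection: np.ndarray, removed_flags: np.ndarray
) -> RebinTables:
    """Assemble C, the removed flags, and the inclusive prefix sum S."""
    c = np.asarray(fence_projection, dtype=np.float64)
    removed = np.asarray(removed_flags, dtype=bool)
    if c.shape != removed.shape or c.ndim != 1:
        raise InternalConsistencyError("projection and flags must be parallel 1-D")
    if c.shape[0] < 2:
        raise InternalConsistencyError("a fence projection needs >= 2 slots")
    if np.any(np.diff(c) < 0):
        raise InternalConsistencyError("fence projection must be non-decreasing")
    if removed[0] or removed[-1]:
        raise InternalConsistencyError("fence endpoints can never be removed")
    s = np.cumsum(removed.astype(np.int64))
    return RebinTables(c, removed, s)


def rebin(points: PointSet, bins: BinAssignment, tables: RebinTables) -> np.ndarray:
    """Relabel every point against the surviving fence boundaries in O(1) each.

    Implements the prefix-sum rebinning rule (1-based): if x >= C[q+1] the
    new label is q+1-S[q+1], otherwise q-S[q].  Labels are clamped to the
    valid segment range [1, n_segments] so that x = xmax maps onto the last
    fence segment.  The result equals, for every point, a binary search of
    x over ``tables.surviving_boundaries()`` (side='right', same clamp).
    """
    q = np.asarray(bins.labels, dtype=np.int64)
    if q.min() < 1 or q.max() > tables.n_slots - 2:
        raise InternalConsistencyError("bin label out of range for these tables")
    c, s = tables.c, tables.s
    # 1-based C_{q+1} = c[q];  S_{q+1} = s[q];  S_q = s[q-1]
    ge = points.x >= c[q]
    new = np.where(ge, q + 1 - s[q], q - s[q - 1])
    n_seg = tables.n_segments
    if n_seg < 1:
        raise InternalConsistencyError("fewer than two surviving boundaries")
    np.clip(new, 1, n_seg, out=new)
    return new
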