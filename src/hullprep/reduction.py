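"""The end-to-end point-set reduction.

Pipeline: find the x-extreme endpoints, quantize into m uniform x-bins,
record per-bin y-extremes, assemble and convexify the lower/upper fences,
rebin every point against the surviving fence boundaries with the
prefix-sum rule, and keep exactly the points strictly outside either
convex fence plus the fence vertices themselves.  Every step is a constant
number of vectorized passes over the points, so the whole reduction is
O(n) for fixed m.

The contract: the strict convex hull vertex set of the kept subset equals
that of the full input.  Points exactly on a fence segment are rejected by
the outside test (they are convex combinations of two fence vertices and
can never be strict hull vertices); fence vertices enter the output set
directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binning import find_x_extremes, per_bin_extremes, quantize_uniform, rebin
from .errors import InternalConsistencyError, ValidationError
from .fence import build_fences, convexify_fences
from .geometry import Polyline, Side
from .pointset import PointSet

__all__ = ["ReductionResult", "keep_points", "reduce_points", "choose_m"]


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of one reduction run.

    ``indices`` are the sorted unique 0-based indices of the kept points;
    ``reduction_factor`` is p_r = 1 - s/n, the fraction of points the hull
    algorithm no longer has to look at.
    """

    indices: np.ndarray
    n: int
    m_used: int
    fence_lower_kept: int
    fence_upper_kept: int
    outside_lower_kept: int
    outside_upper_kept: int

    @property
    def s(self) -> int:
        return self.indices.shape[0]

    @property
    def reduction_factor(self) -> float:
        return 1.0 - self.s / self.n

    @property
    def discarded(self) -> int:
        return self.n - self.s


def keep_points(
    points: PointSet, new_labels: np.ndarray, fence: Polyline, side: Side
) -> np.ndarray:
    """Indices of points strictly outside the given convex fence.

    Label j selects fence segment (F[j], F[j+1]) (1-based); the point is
    kept iff it lies strictly below a lower-fence segment (orient < 0) or
    strictly above an upper-fence segment (orient > 0).  Collinear points
    are not kept here — fence vertices are added by the orchestrator — so
    no boundary point is double-counted.
    """
    q = np.asarray(new_labels, dtype=np.int64)
    n_seg = len(fence) - 1
    if n_seg < 1:
        raise InternalConsistencyError("fence has no segments")
    if q.min() < 1 or q.max() > n_seg:
        raise InternalConsistencyError("rebinned label outside fence segment range")
    p1x, p1y = fence.x[q - 1], fence.y[q - 1]
    p2x, p2y = fence.x[q], fence.y[q]
    o = (p2x - p1x) * (points.y - p1y) - (p2y - p1y) * (points.x - p1x)
    outside = o < 0.0 if side is Side.LOWER else o > 0.0
    return np.flatnonzero(outside)


def _degenerate_vertical(points: PointSet) -> ReductionResult:
    # all x equal: the strict hull is the min-y/max-y segment (or a point)
    imin = int(np.argmin(points.y))
    imax = int(np.argmax(points.y))
    idx = np.unique(np.array([imin, imax], dtype=np.intp))
    return ReductionResult(idx, len(points), 0, idx.shape[0], 0, 0, 0)


def reduce_points(points: PointSet, m: int | str = "auto") -> ReductionResult:
    """Reduce ``points`` to a subset with the identical strict convex hull.

    ``m`` is the uniform bin count ("auto" applies :func:`choose_m`);
    it is clamped to at most n.  Degenerate inputs take short paths:
    n <= 3 returns every index, an all-equal-x input returns its y-extremes.
    """
    points.require_nonempty()
    points.validate_finite()
    n = len(points)
    if n <= 3:
        return ReductionResult(np.arange(n, dtype=np.intp), n, 0, n, 0, 0, 0)
    if float(points.x.min()) == float(points.x.max()):
        return _degenerate_vertical(points)

    if m == "auto":
        m_used = choose_m(n)
    else:
        m_used = int(m)
        if m_used < 1:
            raise ValidationError(f"bin count must be >= 1, got {m_used}")
        m_used = min(m_used, n)

    bins = quantize_uniform(points, m_used)
    extremes = per_bin_extremes(points, bins)
    pair = build_fences(
        points,
        bins,
        extremes,
        find_x_extremes(points, Side.LOWER),
        find_x_extremes(points, Side.UPPER),
    )
    pair = convexify_fences(pair)

    kept = [pair.lower.polyline.indices, pair.upper.polyline.indices]
    counts = {}
    for fs, side in ((pair.lower, Side.LOWER), (pair.upper, Side.UPPER)):
        labels = rebin(points, bins, fs.tables)
        outside = keep_points(points, labels, fs.polyline, side)
        kept.append(outside)
        counts[side] = outside.shape[0]

    indices = np.unique(np.concatenate(kept)).astype(np.intp)
    return ReductionResult(
        indices,
        n,
        m_used,
        len(pair.lower.polyline),
        len(pair.upper.polyline),
        counts[Side.LOWER],
        counts[Side.UPPER],
    )


def choose_m(n: int, mode: str = "default") -> int:
    """Heuristic bin count.

    The useful region is between 10 bins and lg n: "default" returns 10
    once lg n >= 10 (10 is also the histogram default in Matlab and R) and
    max(2, floor(lg n)) for smaller inputs; "lg" returns ceil(lg n), the
    variant used for data-size-dependent comparisons.  Never exceeds n.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    lg = math.log2(n) if n > 1 else 0.0
    if mode == "default":
        m = 10 if lg >= 10 else max(2, int(math.floor(lg)))
    elif mode == "lg":
        m = max(2, int(math.ceil(lg)))
    else:
        raise ValidationError(f"unknown choose_m mode: {mode!r}")
    return min(m, n)
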