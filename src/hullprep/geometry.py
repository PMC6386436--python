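"""Orientation predicate and x-monotone convex polylines.

These are the geometric primitives shared by the fence machinery and the
hull algorithms: the signed cross-product orientation test, the
strictly-outside test against a fence segment, and a stack-based
convexification pass for x-sorted polylines.

Predicates use plain double-precision arithmetic with exact sign tests (no
epsilon); exact/robust arithmetic is deliberately out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["Side", "Polyline", "orient", "is_strictly_outside", "convexify_polyline"]


class Side(enum.Enum):
    """Which envelope a polyline represents."""

    LOWER = "lower"
    UPPER = "upper"


def orient(a, b, c):
    """Signed area test: (b.x-a.x)(c.y-a.y) - (b.y-a.y)(c.x-a.x).

    Positive when ``c`` is strictly left of the directed line a->b
    (counterclockwise turn), negative when strictly right, zero when the
    three points are collinear.  ``a``, ``b``, ``c`` are (x, y) pairs whose
    entries may be scalars or broadcastable arrays, so the same predicate
    serves both single triples and vectorized per-point scans.
    """
    ax, ay = a
    bx, by = b
    cx, cy = c
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def is_strictly_outside(p1, p2, p, side: Side):
    """True where ``p`` lies strictly outside the fence segment p1->p2.

    Segments are stored left-to-right (p1.x < p2.x).  For the lower fence,
    outside means strictly below (orient < 0); for the upper fence the sign
    is negated rather than the segment reversed, so outside means strictly
    above (orient > 0).  Points exactly on the segment line are inside.
    """
    o = orient(p1, p2, p)
    if side is Side.LOWER:
        return o < 0
    return o > 0


@dataclass(frozen=True)
class Polyline:
    """An x-sorted polyline of points, referenced by index into a PointSet.

    ``x``/``y`` are the polyline's own coordinate arrays (in sequence
    order); ``indices`` maps each polyline point back to its original
    point-set index so results can be reported as input indices.
    """

    indices: np.ndarray
    x: np.ndarray
    y: np.ndarray
    side: Side

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))

    def __len__(self) -> int:
        return self.indices.shape[0]

    @classmethod
    def from_points(cls, points, indices, side: Side) -> "Polyline":
        idx = np.asarray(indices, dtype=np.intp)
        return cls(idx, points.x[idx], points.y[idx], side)


def convexify_polyline(poly: Polyline) -> tuple[np.ndarray, Polyline]:
    """One left-to-right stack pass making an x-sorted polyline convex.

    Returns ``(removed, convex)`` where ``removed`` is a boolean array
    parallel to the input marking dropped interior points.  For a lower
    polyline every surviving interior triple (a, b, c) turns strictly left
    (orient > 0); for an upper polyline strictly right (orient < 0).
    Collinear interior points are removed too (strict convexity): a point
    interior to a segment between two other input points can never be a
    strict hull vertex.  The first and last points always survive.

    This is the x-monotone specialization that a general simple-polyline
    convexifier (e.g. Melkman's deque algorithm) would reduce to here,
    since fences are x-sorted by construction.
    """
    k = len(poly)
    if k < 2:
        raise ValidationError("polyline must have at least 2 points")
    sign = 1.0 if poly.side is Side.LOWER else -1.0
    xs, ys = poly.x, poly.y
    stack: list[int] = [0]
    for i in range(1, k):
        while len(stack) >= 2:
            a, b = stack[-2], stack[-1]
            o = orient((xs[a], ys[a]), (xs[b], ys[b]), (xs[i], ys[i]))
            if sign * o <= 0.0:
                stack.pop()
            else:
                break
        stack.append(i)
    removed = np.ones(k, dtype=bool)
    removed[stack] = False
    keep = np.asarray(stack, dtype=np.intp)
    convex = Polyline(poly.indices[keep], xs[keep], ys[keep], poly.side)
    return removed, convex
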