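"""Self-contained 2D convex hull algorithms.

Three algorithms with one canonical output contract:

* :func:`monotone_chain_hull` — Andrew's monotone chain, O(n lg n); the
  production hull used by the benchmark harness.
* :func:`chan_hull` — Chan's output-sensitive O(n lg h) construction
  (partition into groups, per-group sub-hulls, gift-wrap over sub-hulls
  with tangent searches, group size doubling-squared per round).
* :func:`jarvis_hull` — gift wrapping, O(nh), written with no shared code
  paths with the other two so it can serve as an independent test oracle.

All three return the *strict* hull: collinear boundary midpoints are never
vertices, collinear input collapses to a 2-vertex segment, and coincident
input collapses to a single vertex.  Vertices are reported counterclockwise
starting at the lexicographically smallest (x, then y) vertex, so vertex
sequences are directly comparable across algorithms and across subsets.
Where a hull-vertex coordinate is duplicated in the input, the smallest
original index represents it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .pointset import PointSet

__all__ = ["HullPolygon", "monotone_chain_hull", "chan_hull", "jarvis_hull"]


@dataclass(frozen=True)
class HullPolygon:
    """Strict convex hull: vertex indices (CCW, canonical start) + coords."""

    vertices: np.ndarray  # 0-based indices into the original PointSet
    x: np.ndarray
    y: np.ndarray

    @property
    def h(self) -> int:
        return self.vertices.shape[0]

    def coords(self) -> np.ndarray:
        """(h, 2) array of vertex coordinates in canonical order."""
        return np.column_stack([self.x, self.y])


def _prepare(points: PointSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort lexicographically by (x, y) and collapse exact duplicates.

    Returns (xs, ys, orig_idx) with xs strictly lexicographically
    increasing; orig_idx[i] is the smallest original index carrying that
    coordinate (lexsort is stable, so the first of each duplicate run is
    the smallest original index).
    """
    points.require_nonempty()
    order = np.lexsort((points.y, points.x))
    xs = points.x[order]
    ys = points.y[order]
    if xs.shape[0] > 1:
        first = np.ones(xs.shape[0], dtype=bool)
        first[1:] = (xs[1:] != xs[:-1]) | (ys[1:] != ys[:-1])
        order, xs, ys = order[first], xs[first], ys[first]
    return xs, ys, order


def _cross(ox, oy, ax, ay, bx, by):
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def _chain(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Andrew's monotone chain over lexicographically sorted unique points.

    Returns positions (into xs/ys) of the strict hull, CCW, starting at the
    lexicographic minimum.  Pops on orient <= 0 so collinear midpoints are
    excluded.
    """
    u = xs.shape[0]
    if u == 1:
        return [0]
    lower: list[int] = []
    for i in range(u):
        while len(lower) >= 2 and _cross(
            xs[lower[-2]], ys[lower[-2]], xs[lower[-1]], ys[lower[-1]], xs[i], ys[i]
        ) <= 0.0:
            lower.pop()
        lower.append(i)
    upper: list[int] = []
    for i in range(u - 1, -1, -1):
        while len(upper) >= 2 and _cross(
            xs[upper[-2]], ys[upper[-2]], xs[upper[-1]], ys[upper[-1]], xs[i], ys[i]
        ) <= 0.0:
            upper.pop()
        upper.append(i)
    return lower[:-1] + upper[:-1]


def _finish(pos, xs, ys, orig) -> HullPolygon:
    pos = np.asarray(pos, dtype=np.intp)
    return HullPolygon(orig[pos], xs[pos], ys[pos])


def monotone_chain_hull(points: PointSet) -> HullPolygon:
    """Strict convex hull by Andrew's monotone chain (O(n lg n))."""
    xs, ys, orig = _prepare(points)
    return _finish(_chain(xs, ys), xs, ys, orig)


# ---------------------------------------------------------------------------
# Chan's output-sensitive algorithm
# ---------------------------------------------------------------------------

_LINEAR_TANGENT_MAX = 48  # below this, a linear tangent scan beats the search


def _better(px, py, ux, uy, vx, vy) -> bool:
    """True if u is a more clockwise wrap candidate from p than v.

    Collinear candidates are ranked by distance (farther wins), which is
    what excludes collinear boundary midpoints from the strict hull.
    """
    cr = _cross(px, py, vx, vy, ux, uy)
    if cr < 0.0:
        return True
    if cr > 0.0:
        return False
    du = (ux - px) ** 2 + (uy - py) ** 2
    dv = (vx - px) ** 2 + (vy - py) ** 2
    return du > dv


def _tangent_linear(px, py, hx, hy, skip: int) -> int:
    best = -1
    for j in range(hx.shape[0]):
        if j == skip:
            continue
        if best < 0 or _better(px, py, hx[j], hy[j], hx[best], hy[best]):
            best = j
    return best


def _tangent_binary(px, py, hx, hy) -> int:
    """Most-clockwise vertex of a strictly convex CCW polygon seen from p.

    Binary search over the cyclic, unimodal "clockwiseness" ordering; the
    caller verifies local optimality and falls back to a linear scan, so a
    degenerate configuration (p collinear with a polygon edge) can never
    produce a wrong wrap step.
    """
    n = hx.shape[0]
    lo, hi = 0, n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        # does the sequence still improve moving from lo forward?
        lo_next_better = _better(
            px, py, hx[(lo + 1) % n], hy[(lo + 1) % n], hx[lo], hy[lo]
        )
        mid_next_better = _better(
            px, py, hx[(mid + 1) % n], hy[(mid + 1) % n], hx[mid], hy[mid]
        )
        mid_vs_lo = _better(px, py, hx[mid], hy[mid], hx[lo], hy[lo])
        if lo_next_better:
            if not mid_next_better and mid_vs_lo:
                hi = mid
            elif mid_next_better and mid_vs_lo:
                lo = mid
            else:
                hi = mid
        else:
            if mid_next_better:
                lo = mid
            else:
                if mid_vs_lo:
                    lo = mid
                else:
                    hi = mid
    return lo


def _tangent(px, py, hx, hy, skip: int) -> int:
    n = hx.shape[0]
    if n <= _LINEAR_TANGENT_MAX or skip >= 0:
        return _tangent_linear(px, py, hx, hy, skip)
    cand = _tangent_binary(px, py, hx, hy)
    prv, nxt = (cand - 1) % n, (cand + 1) % n
    if _better(px, py, hx[prv], hy[prv], hx[cand], hy[cand]) or _better(
        px, py, hx[nxt], hy[nxt], hx[cand], hy[cand]
    ):
        return _tangent_linear(px, py, hx, hy, skip)
    return cand


def chan_hull(points: PointSet) -> HullPolygon:
    """Strict convex hull by Chan's output-sensitive algorithm (O(n lg h)).

    Round t guesses h_t = min(n, 2^(2^t)) for the hull size, partitions the
    points into groups of that size, computes each group's sub-hull with the
    monotone chain, and gift-wraps over the sub-hulls taking at each step
    the most clockwise tangent candidate among groups.  If the wrap does not
    close within h_t steps the guess was too small and the round restarts
    with the guess squared.
    """
    xs, ys, orig = _prepare(points)
    u = xs.shape[0]
    if u <= 2:
        return _finish(list(range(u)), xs, ys, orig)
    t = 1
    while True:
        H = min(u, 2 ** (2**t))
        n_groups = (u + H - 1) // H
        sub: list[np.ndarray] = []
        for g in range(n_groups):
            pos = np.arange(g * H, min((g + 1) * H, u))
            local = _chain(xs[pos], ys[pos])
            sub.append(pos[np.asarray(local, dtype=np.intp)])
        sub_x = [xs[s] for s in sub]
        sub_y = [ys[s] for s in sub]
        start = 0  # global lexicographic minimum, certainly a hull vertex
        hull = [start]
        cur = start
        closed = False
        for _ in range(H):
            best = -1
            bx = by = 0.0
            for g in range(n_groups):
                # if the current point is a vertex of this sub-hull, skip it
                # as its own candidate; its CCW successor is the tangent
                skip = -1
                if sub[g].shape[0] and g == cur // H:
                    where = np.flatnonzero(sub[g] == cur)
                    if where.size:
                        skip = int(where[0])
                j = _tangent(xs[cur], ys[cur], sub_x[g], sub_y[g], skip)
                if j < 0:
                    continue
                cand = int(sub[g][j])
                cx, cy = xs[cand], ys[cand]
                if best < 0 or _better(xs[cur], ys[cur], cx, cy, bx, by):
                    best, bx, by = cand, cx, cy
            if best == start:
                closed = True
                break
            hull.append(best)
            cur = best
        if closed:
            return _finish(hull, xs, ys, orig)
        t += 1


# ---------------------------------------------------------------------------
# Jarvis march (independent oracle; shares no code with the algorithms above)
# ---------------------------------------------------------------------------


def jarvis_hull(points: PointSet) -> HullPolygon:
    """Strict convex hull by gift wrapping (O(nh) worst case).

    Deliberately implemented with its own deduplication and its own inlined
    cross products (vectorized over candidate points) so that agreement
    with the other hulls is evidence, not tautology.
    """
    if len(points) == 0:
        raise ValidationError("point set is empty")
    coords = np.unique(
        np.rec.fromarrays([points.x, points.y], names=["x", "y"]),
        return_index=True,
    )
    uniq, first_idx = coords
    ux = uniq["x"].astype(np.float64)
    uy = uniq["y"].astype(np.float64)
    m = ux.shape[0]
    if m == 1:
        return HullPolygon(first_idx.astype(np.intp), ux, uy)
    # np.unique sorted the records by (x, y): position 0 is the canonical start
    start = 0
    hull = [start]
    cur = start
    while True:
        cand = start if cur != start else 1
        while True:
            cross = (ux[cand] - ux[cur]) * (uy - uy[cur]) - (
                uy[cand] - uy[cur]
            ) * (ux - ux[cur])
            right = np.flatnonzero(cross < 0.0)
            if right.size:
                cand = int(right[np.argmin(cross[right])])
                continue
            # no point strictly right: pick the farthest collinear candidate
            on_line = np.flatnonzero(cross == 0.0)
            d2 = (ux[on_line] - ux[cur]) ** 2 + (uy[on_line] - uy[cur]) ** 2
            cand = int(on_line[np.argmax(d2)])
            break
        if cand == start:
            break
        hull.append(cand)
        cur = cand
        if len(hull) > m:  # cannot happen; guards against infinite wrap
            raise ValidationError("gift wrapping failed to close the hull")
    pos = np.asarray(hull, dtype=np.intp)
    return HullPolygon(first_idx[pos].astype(np.intp), ux[pos], uy[pos])
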