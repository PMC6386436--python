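"""Fence assembly and convexification.

The lower fence is the x-sorted polyline through the min-x endpoint, each
nonempty bin's minimum-y point, and the max-x endpoint; the upper fence
mirrors it with maximum-y points.  With all m bins nonempty each fence has
m + 2 points.  Convexification (one stack pass per side) drops the
non-convex fence points; the removals, merged with the empty-bin and
endpoint-duplicate flags, drive the prefix-sum rebin tables.

Each fence side is materialized as an m+2 slot array: slot 0 is the min-x
endpoint, slot j (1..m) is bin j's extreme point, slot m+1 is the max-x
endpoint.  Keeping removed/empty slots in place (instead of deleting them)
is what lets the rebinning rule index tables by the original uniform label.
The two sides are fully independent; processing order never matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinAssignment, BinExtremes, RebinTables, build_rebin_tables
from .geometry import Polyline, Side, convexify_polyline
from .pointset import PointSet

__all__ = ["FenceSide", "FencePair", "build_fences", "convexify_fences"]


@dataclass(frozen=True)
class FenceSide:
    """One fence: slot arrays, removal flags, and (after convexification)
    the surviving convex polyline plus its rebin tables."""

    side: Side
    slot_index: np.ndarray  # m+2 point indices; -1 where the slot is empty
    slot_x: np.ndarray  # m+2 projected abscissas (placeholders where empty)
    slot_y: np.ndarray
    removed: np.ndarray  # m+2 flags: empty slot, duplicate, or non-convex
    polyline: Polyline | None = None  # convexified fence (surviving slots)
    tables: RebinTables | None = None


@dataclass(frozen=True)
class FencePair:
    lower: FenceSide
    upper: FenceSide


def _build_side(
    points: PointSet,
    bins: BinAssignment,
    extreme_index: np.ndarray,
    empty: np.ndarray,
    endpoints: tuple[int, int],
    side: Side,
) -> FenceSide:
    m = bins.m
    imin, imax = endpoints
    slot_index = np.full(m + 2, -1, dtype=np.intp)
    slot_x = np.empty(m + 2, dtype=np.float64)
    slot_y = np.zeros(m + 2, dtype=np.float64)
    removed = np.zeros(m + 2, dtype=bool)

    slot_index[0] = imin
    slot_x[0], slot_y[0] = points.x[imin], points.y[imin]
    slot_index[m + 1] = imax
    slot_x[m + 1], slot_y[m + 1] = points.x[imax], points.y[imax]

    for j in range(1, m + 1):
        if empty[j - 1]:
            removed[j] = True
            slot_x[j] = bins.left_edge(j)  # placeholder; never read by rebin
        else:
            i = int(extreme_index[j - 1])
            slot_index[j] = i
            slot_x[j], slot_y[j] = points.x[i], points.y[i]

    # endpoint deduplication: a bin extreme that coincides with an endpoint
    # is flagged removed so each coordinate appears once in the polyline
    for j, end in ((1, 0), (m, m + 1)):
        if (
            not removed[j]
            and slot_x[j] == slot_x[end]
            and slot_y[j] == slot_y[end]
        ):
            removed[j] = True
    return FenceSide(side, slot_index, slot_x, slot_y, removed)


def build_fences(
    points: PointSet,
    bins: BinAssignment,
    extremes: BinExtremes,
    endpoints_lower: tuple[int, int],
    endpoints_upper: tuple[int, int],
) -> FencePair:
    """Assemble both fences (pre-convexification).

    ``endpoints_lower``/``endpoints_upper`` come from
    :func:`~hullprep.binning.find_x_extremes` with the matching tie rule,
    so a tied x-extreme can never sit strictly inside its own fence.
    """
    lower = _build_side(
        points, bins, extremes.min_y_index, extremes.empty, endpoints_lower, Side.LOWER
    )
    upper = _build_side(
        points, bins, extremes.max_y_index, extremes.empty, endpoints_upper, Side.UPPER
    )
    return FencePair(lower, upper)


def _convexify_side(side: FenceSide) -> FenceSide:
    alive = np.flatnonzero(~side.removed)
    poly = Polyline(
        side.slot_index[alive], side.slot_x[alive], side.slot_y[alive], side.side
    )
    dropped, convex = convexify_polyline(poly)
    removed = side.removed.copy()
    removed[alive[dropped]] = True
    tables = build_rebin_tables(side.slot_x, removed)
    return FenceSide(
        side.side, side.slot_index, side.slot_x, side.slot_y, removed, convex, tables
    )


def convexify_fences(pair: FencePair) -> FencePair:
    """Convexify both fences and build their rebin tables.

    Every surviving fence point is part of the reduced output set.
    """
    return FencePair(_convexify_side(pair.lower), _convexify_side(pair.upper))
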