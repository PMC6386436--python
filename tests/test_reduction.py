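"""End-to-end reduction: worked examples, degeneracies, hull preservation."""

import numpy as np
import pytest

from hullprep import (
    FAMILIES,
    PointSet,
    Side,
    ValidationError,
    choose_m,
    jarvis_hull,
    keep_points,
    make_fixture,
    random_instance,
    reduce_points,
)
from hullprep.geometry import Polyline


class TestKeepPoints:
    fence = Polyline(
        np.arange(4), np.array([0.0, 2, 8, 9]), np.array([5.0, 1, 0, 4]), Side.LOWER
    )

    def test_strictly_below_kept(self):
        pts = PointSet(np.array([5.0]), np.array([0.2]))
        assert keep_points(pts, np.array([2]), self.fence, Side.LOWER).tolist() == [0]

    def test_above_not_kept(self):
        pts = PointSet(np.array([5.0]), np.array([2.0]))
        assert keep_points(pts, np.array([2]), self.fence, Side.LOWER).size == 0

    def test_fence_vertex_not_kept_here(self):
        pts = PointSet(np.array([2.0]), np.array([1.0]))
        assert keep_points(pts, np.array([1]), self.fence, Side.LOWER).size == 0


class TestReducePoints:
    def test_square_plus_center(self, square_plus_center):
        result = reduce_points(square_plus_center, 2)
        assert result.indices.tolist() == [0, 1, 2, 3]
        assert result.s == 4 and result.n == 5
        assert result.reduction_factor == pytest.approx(0.2)

    def test_small_inputs_pass_through(self):
        pts = PointSet.from_pairs([(0, 0), (1, 0), (2, 0)])
        assert reduce_points(pts, 5).indices.tolist() == [0, 1, 2]

    def test_vertical_line_keeps_y_extremes(self):
        pts = make_fixture("vertical_line")  # five points, all x = 1
        result = reduce_points(pts, 4)
        assert pts.y[result.indices].tolist() == [
            pts.y.min(), pts.y.max()
        ]

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            reduce_points(PointSet(np.empty(0), np.empty(0)))
        with pytest.raises(ValidationError, match="row 1"):
            reduce_points(PointSet(np.array([0.0, np.nan, 1, 2]), np.zeros(4)))

    def test_m_larger_than_n_allowed(self, rng):
        pts = random_instance("uniform", 20, rng)
        result = reduce_points(pts, 500)
        assert result.m_used <= 20
        full = jarvis_hull(pts)
        assert np.array_equal(
            jarvis_hull(pts.take(result.indices)).coords(), full.coords()
        )

    def test_determinism(self, rng):
        pts = random_instance("gaussian", 1000, rng)
        a = reduce_points(pts, 7).indices
        b = reduce_points(pts, 7).indices
        assert np.array_equal(a, b)

    def test_stage_counters_sum_consistently(self, rng):
        pts = random_instance("uniform", 500, rng)
        r = reduce_points(pts, 10)
        assert r.s <= (
            r.fence_lower_kept + r.fence_upper_kept
            + r.outside_lower_kept + r.outside_upper_kept
        )
        assert r.s + r.discarded == r.n


def _hull_coords(points):
    return jarvis_hull(points).coords()


class TestHullPreservation:
    """The core contract: reducing never changes the strict hull."""

    @pytest.mark.parametrize("family", FAMILIES)
    def test_preserved_across_families_and_m(self, family, rng):
        for _ in range(12):
            n = int(rng.integers(4, 3000))
            pts = random_instance(family, n, rng)
            full = _hull_coords(pts)
            for m in (2, 3, 10, max(2, int(np.log2(n)))):
                result = reduce_points(pts, m)
                reduced = _hull_coords(pts.take(result.indices))
                assert np.array_equal(full, reduced), (family, n, m)

    def test_discards_inside_hull_of_kept(self, rng):
        for _ in range(10):
            pts = random_instance("uniform", int(rng.integers(20, 400)), rng)
            result = reduce_points(pts, 5)
            hull = jarvis_hull(pts.take(result.indices))
            dropped = np.setdiff1d(np.arange(len(pts)), result.indices)
            hx, hy = hull.x, hull.y
            for i in range(hull.h):
                j = (i + 1) % hull.h
                cross = (hx[j] - hx[i]) * (pts.y[dropped] - hy[i]) - (
                    hy[j] - hy[i]
                ) * (pts.x[dropped] - hx[i])
                assert (cross >= 0).all()

    def test_large_superellipse_reduction(self, rng):
        pts = random_instance("superellipse", 100_000, rng)
        result = reduce_points(pts, 10)
        assert result.reduction_factor >= 0.9
        assert np.array_equal(
            _hull_coords(pts.take(result.indices)), _hull_coords(pts)
        )


class TestChooseM:
    @pytest.mark.parametrize(
        "n,mode,expected",
        [
            (1_000_000, "default", 10),
            (1_000_000, "lg", 20),
            (64, "default", 6),
            (3, "default", 2),
            (1, "default", 1),  # clamped to n
        ],
    )
    def test_values(self, n, mode, expected):
        assert choose_m(n, mode) == expected

    def test_never_exceeds_n(self):
        for n in (1, 2, 3, 5, 1000):
            assert choose_m(n) <= n
            assert choose_m(n, "lg") <= n

    def test_bad_mode_rejected(self):
        with pytest.raises(ValidationError):
            choose_m(100, "sturges")
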