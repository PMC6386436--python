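"""Quantization, per-bin extremes, rebin tables, and the O(1) rebin rule."""

import numpy as np
import pytest

from hullprep import (
    BinAssignment,
    InternalConsistencyError,
    PointSet,
    Side,
    ValidationError,
    build_rebin_tables,
    find_x_extremes,
    per_bin_extremes,
    quantize_uniform,
    rebin,
)


class TestFindXExtremes:
    def test_basic(self):
        pts = PointSet.from_pairs([(2.3, 0), (9.1, 5), (5, 1)])
        assert find_x_extremes(pts) == (0, 1)

    def test_single_point(self):
        assert find_x_extremes(PointSet.from_pairs([(1, 1)])) == (0, 0)

    def test_tie_break_by_side(self):
        pts = PointSet.from_pairs([(0, 3), (0, -1), (7, 2)])
        assert find_x_extremes(pts, Side.LOWER)[0] == 1  # smaller y wins
        assert find_x_extremes(pts, Side.UPPER)[0] == 0  # larger y wins

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            find_x_extremes(PointSet(np.empty(0), np.empty(0)))


class TestQuantizeUniform:
    def test_worked_example_boundaries(self):
        # range [2.3, 9.1] with m = 4: interval size (9.1-2.3)/4 = 1.7
        pts = PointSet.from_pairs([(2.3, 0), (9.1, 0), (5.0, 0)])
        bins = quantize_uniform(pts, 4)
        assert bins.width == pytest.approx(1.7)
        assert bins.boundaries() == pytest.approx([2.3, 4.0, 5.7, 7.4, 9.1])
        assert bins.labels[2] == 2  # 5.0 lies in [4.0, 5.7)

    def test_xmax_clamped_into_last_bin(self):
        pts = PointSet.from_pairs([(2.3, 0), (9.1, 0)])
        assert quantize_uniform(pts, 4).labels[1] == 4

    def test_exhaustive_and_exclusive(self, rng):
        pts = PointSet(rng.uniform(-3, 7, 500), rng.uniform(0, 1, 500))
        for m in (1, 2, 7, 40):
            bins = quantize_uniform(pts, m)
            assert bins.labels.min() >= 1 and bins.labels.max() <= m
            # every label agrees with direct interval membership
            edges = bins.boundaries()
            expected = np.clip(np.searchsorted(edges, pts.x, side="right"), 1, m)
            assert np.array_equal(bins.labels, expected)

    def test_degenerate_vertical_signalled(self):
        with pytest.raises(ValidationError):
            quantize_uniform(PointSet.from_pairs([(1, 0), (1, 5)]), 3)


class TestPerBinExtremes:
    def test_extremes_and_empty_bins(self):
        pts = PointSet.from_pairs([(4, 6), (5, 1), (5.5, 3), (0, 2), (10, 2)])
        bins = quantize_uniform(pts, 5)
        ext = per_bin_extremes(pts, bins)
        b = bins.labels[0] - 1  # bin containing the 4..5.5 cluster
        assert ext.min_y_index[b] == 1 and ext.max_y_index[b] == 0
        assert ext.empty.sum() == 2  # two interior bins have no points
        assert (ext.min_y_index[ext.empty] == -1).all()

    def test_extremes_really_bound_all_y(self, rng):
        pts = PointSet(rng.normal(0, 2, 800), rng.normal(0, 2, 800))
        bins = quantize_uniform(pts, 13)
        ext = per_bin_extremes(pts, bins)
        for b in range(13):
            members = np.flatnonzero(bins.labels == b + 1)
            if ext.empty[b]:
                assert members.size == 0
                continue
            ys = pts.y[members]
            assert pts.y[ext.min_y_index[b]] == ys.min()
            assert pts.y[ext.max_y_index[b]] == ys.max()

    def test_y_tie_keeps_first_seen_index(self):
        pts = PointSet.from_pairs([(1, 0), (2, 0), (1.5, 5), (9, 1)])
        bins = quantize_uniform(pts, 2)
        ext = per_bin_extremes(pts, bins)
        assert ext.min_y_index[0] == 0  # (1,0) seen before (2,0)


class TestRebinTables:
    def test_prefix_sum_of_removals(self):
        # removals at 1-based positions 2 and 5 of seven slots
        tables = build_rebin_tables(
            np.arange(7.0), np.array([0, 1, 0, 0, 1, 0, 0], dtype=bool)
        )
        assert tables.s.tolist() == [0, 1, 1, 1, 2, 2, 2]

    def test_no_removals_all_zero(self):
        tables = build_rebin_tables(np.arange(5.0), np.zeros(5, dtype=bool))
        assert tables.s.tolist() == [0] * 5
        assert tables.n_segments == 4

    def test_running_count(self):
        c = np.array([0.0, 2.0, 4.0, 8.0, 9.0])
        removed = np.array([0, 0, 1, 0, 0], dtype=bool)
        tables = build_rebin_tables(c, removed)
        assert tables.s.tolist() == [0, 0, 1, 1, 1]
        assert tables.surviving_boundaries().tolist() == [0, 2, 8, 9]

    def test_flagged_endpoint_rejected(self):
        with pytest.raises(InternalConsistencyError):
            build_rebin_tables(np.arange(4.0), np.array([1, 0, 0, 0], dtype=bool))

    def test_unsorted_projection_rejected(self):
        with pytest.raises(InternalConsistencyError):
            build_rebin_tables(np.array([0.0, 3.0, 1.0]), np.zeros(3, dtype=bool))


def _tables_fig3():
    # six original bins -> a fence of 8 slots; convexification removed the
    # fence points at 1-based positions 2 and 5
    removed = np.zeros(8, dtype=bool)
    removed[[1, 4]] = True
    return build_rebin_tables(np.arange(8.0), removed)


class TestRebin:
    def test_six_bin_removal_example_both_branches(self):
        tables = _tables_fig3()
        pts = PointSet(np.array([4.5, 3.5]), np.zeros(2))
        bins = BinAssignment(np.array([4, 4]), 6, 0.0, 7.0, 7.0 / 6.0)
        new = rebin(pts, bins, tables)
        assert new[0] == 3  # x beyond C_5: 5 - S_5 = 5 - 2
        assert new[1] == 3  # x between C_4 and C_5: 4 - S_4 = 4 - 1

    def test_boundary_removal_small_case(self):
        c = np.array([0.0, 2.0, 4.0, 8.0, 9.0])
        removed = np.array([0, 0, 1, 0, 0], dtype=bool)
        tables = build_rebin_tables(c, removed)
        pts = PointSet(np.array([5.0, 3.5, 8.5]), np.zeros(3))
        bins = BinAssignment(np.array([2, 2, 3]), 3, 0.0, 9.0, 3.0)
        assert rebin(pts, bins, tables).tolist() == [2, 2, 3]

    def test_label_out_of_range_rejected(self):
        tables = _tables_fig3()
        pts = PointSet(np.array([1.0]), np.zeros(1))
        bins = BinAssignment(np.array([7]), 7, 0.0, 7.0, 1.0)
        with pytest.raises(InternalConsistencyError):
            rebin(pts, bins, tables)
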