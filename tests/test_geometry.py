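"""Bin polygons, spatial join, expansion and orphan filtering."""

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from hdassign.errors import DataError
from hdassign.geometry import (
    CellOutline,
    OverlapTable,
    build_bin_polygons,
    expand_outlines,
    filter_orphan_bins,
    spatial_join,
)

from conftest import brute_force_join, grid_from_array, random_convex_cell, square_cell


class TestBinPolygons:
    def test_unit_bin_footprint(self):
        grid = grid_from_array(np.zeros((1, 1, 1)))
        (poly,) = build_bin_polygons(grid)
        assert poly.equals(shapely.box(0, 0, 2, 2))
        assert poly.area == pytest.approx(4.0)

    def test_adjacent_bins_share_no_area(self):
        grid = grid_from_array(np.zeros((1, 2, 1)))
        a, b = build_bin_polygons(grid)
        assert a.intersection(b).area == 0.0

    def test_offset_origin(self):
        grid = grid_from_array(np.zeros((2, 2, 1)), origin=(10.0, 20.0))
        polys = build_bin_polygons(grid)
        # bin (row 1, col 1) is the last in row-major order
        assert polys[3].equals(shapely.box(12, 22, 14, 24))

    def test_footprints_tile_the_field(self):
        grid = grid_from_array(np.zeros((3, 4, 1)))
        polys = build_bin_polygons(grid)
        assert sum(p.area for p in polys) == pytest.approx(12 * 4.0)
        union = shapely.union_all(polys)
        assert union.area == pytest.approx(12 * 4.0)


class TestSpatialJoin:
    def test_partial_overlap_area(self):
        grid = grid_from_array(np.zeros((1, 1, 1)))
        cell = square_cell("A", 1, 1, 2)  # [1,3]^2 overlaps bin [0,2)^2 in [1,2)^2
        table = spatial_join(grid, [cell])
        assert table.n_records == 1
        assert table.records["area"].iloc[0] == pytest.approx(1.0)

    def test_edge_contact_is_not_overlap(self):
        grid = grid_from_array(np.zeros((1, 1, 1)))
        cell = square_cell("A", 2, 0, 2)  # touches bin along x=2 only
        assert spatial_join(grid, [cell]).n_records == 0

    def test_empty_cell_collection(self):
        grid = grid_from_array(np.zeros((2, 2, 1)))
        table = spatial_join(grid, [])
        assert table.n_records == 0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            R, C = rng.integers(3, 16), rng.integers(3, 16)
            grid = grid_from_array(np.zeros((R, C, 1)))
            field = (C * 2.0, R * 2.0)
            cells = [
                random_convex_cell(rng, f"c{i}", field) for i in range(rng.integers(1, 16))
            ]
            got = {
                (r.bin_id, r.cell_id, round(float(r.area), 9))
                for r in spatial_join(grid, cells).records.itertuples()
            }
            assert got == brute_force_join(grid, cells)

    def test_intersection_area_bounded_by_bin_area(self, dense_dataset):
        table = spatial_join(dense_dataset.grid, dense_dataset.truth.cells)
        s2 = dense_dataset.grid.bin_size ** 2
        assert (table.records["area"] <= s2 * (1 + 1e-9)).all()
        # mutually overlapping cells can jointly exceed the bin footprint,
        # but never by more than one bin area per overlapping cell
        grouped = table.records.groupby("bin_index")["area"]
        assert (grouped.sum() <= grouped.size() * s2 * (1 + 1e-6)).all()

    def test_per_bin_area_sum_bounded_for_disjoint_cells(self, sparse_dataset):
        """With non-overlapping cell outlines, a bin's intersection areas
        sum to at most the bin footprint."""
        table = spatial_join(sparse_dataset.grid, sparse_dataset.truth.cells)
        s2 = sparse_dataset.grid.bin_size ** 2
        per_bin = table.records.groupby("bin_index")["area"].sum()
        assert (per_bin <= s2 * (1 + 1e-6)).all()


class TestExpandOutlines:
    def test_zero_distance_is_identity(self):
        cells = [square_cell("A", 0, 0, 2), square_cell("B", 5, 5, 3)]
        out = expand_outlines(cells, 0.0)
        for a, b in zip(cells, out):
            assert a.polygon.equals(b.polygon)

    def test_mitre_expansion_of_square_is_square(self):
        cell = square_cell("A", 0, 0, 2)
        (out,) = expand_outlines([cell], 1.0)
        assert out.area == pytest.approx(16.0)
        assert out.polygon.equals(shapely.box(-1, -1, 3, 3))

    def test_expansion_monotone_in_distance(self):
        rng = np.random.default_rng(7)
        cells = [random_convex_cell(rng, i, (30, 30)) for i in range(6)]
        a1 = [c.area for c in expand_outlines(cells, 1.0)]
        a2 = [c.area for c in expand_outlines(cells, 2.5)]
        assert all(x2 >= x1 for x1, x2 in zip(a1, a2))

    def test_negative_distance_rejected(self):
        with pytest.raises(DataError):
            expand_outlines([square_cell("A", 0, 0, 2)], -0.5)


class TestOrphanFilter:
    def test_keeps_only_overlapping_bins(self):
        grid = grid_from_array(np.ones((3, 3, 1)))
        # one cell covering the four upper-left bins
        cell = square_cell("A", 0, 0, 3.5)
        table = spatial_join(grid, [cell])
        kept = filter_orphan_bins(grid, table)
        assert kept.n_bins == 4
        assert kept.total_counts == 4

    def test_identity_when_all_bins_overlap(self):
        grid = grid_from_array(np.ones((2, 2, 1)))
        cell = square_cell("A", -1, -1, 10)
        kept = filter_orphan_bins(grid, spatial_join(grid, [cell]))
        assert kept.n_bins == grid.n_bins
        assert list(kept.bin_ids) == list(grid.bin_ids)

    def test_no_overlaps_gives_empty_grid(self):
        grid = grid_from_array(np.ones((2, 2, 1)))
        kept = filter_orphan_bins(grid, spatial_join(grid, []))
        assert kept.n_bins == 0
        assert kept.total_counts == 0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_join_bruteforce_property(seed):
    """STRtree-backed join equals all-pairs intersection for any instance."""
    rng = np.random.default_rng(seed)
    R, C = rng.integers(2, 10), rng.integers(2, 10)
    grid = grid_from_array(np.zeros((R, C, 1)))
    cells = [
        random_convex_cell(rng, i, (C * 2.0, R * 2.0), r_max=4.0)
        for i in range(rng.integers(0, 8))
    ]
    got = {
        (r.bin_id, r.cell_id, round(float(r.area), 9))
        for r in spatial_join(grid, cells).records.itertuples()
    }
    assert got == brute_force_join(grid, cells)
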