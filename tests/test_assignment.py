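"""The four transcript imputation strategies and their contracts."""

import numpy as np
import pytest
import scipy.sparse as sp

from hdassign.assignment import (
    AssignmentConfig,
    STRATEGIES,
    assign,
    assign_naive,
    assign_weight_by_area,
    assign_weight_by_cluster,
    assign_weight_by_gene,
    largest_remainder_round,
)
from hdassign.errors import ConfigError, DataError
from hdassign.geometry import spatial_join

from conftest import grid_from_array, square_cell


def two_cell_shared_bin(counts_left, counts_shared, counts_right, split=0.5):
    """1x3 bin strip: left bin unique to A, middle shared, right unique to B.

    ``split`` sets A's share of the middle bin's area.
    """
    arr = np.zeros((1, 3, 1))
    arr[0, 0, 0] = counts_left
    arr[0, 1, 0] = counts_shared
    arr[0, 2, 0] = counts_right
    grid = grid_from_array(arr)
    xa = 2 + 2 * split  # A spans [0, xa], B spans [xa, 6]
    from shapely.geometry import Polygon

    from hdassign.geometry import CellOutline

    cells = [
        CellOutline("A", Polygon([(0, 0), (xa, 0), (xa, 2), (0, 2)])),
        CellOutline("B", Polygon([(xa, 0), (6, 0), (6, 2), (xa, 2)])),
    ]
    return grid, cells, spatial_join(grid, cells)


class TestNaive:
    def test_unique_bin_fully_credited(self):
        grid, cells, ov = two_cell_shared_bin(5, 0, 0)
        m = assign_naive(grid, ov, cells=cells)
        assert m.to_frame().loc["A", "G000"] == 5
        assert m.to_frame().loc["B", "G000"] == 0

    def test_shared_bin_discarded(self):
        grid, cells, ov = two_cell_shared_bin(0, 5, 0)
        m = assign_naive(grid, ov, cells=cells)
        assert m.total == 0

    def test_conservation_without_shared_bins(self):
        arr = np.zeros((1, 2, 2))
        arr[0, 0] = [3, 1]
        arr[0, 1] = [0, 2]
        grid = grid_from_array(arr)
        cells = [square_cell("A", 0, 0, 2), square_cell("B", 2.5, 0, 1.4)]
        ov = spatial_join(grid, cells)
        m = assign_naive(grid, ov, cells=cells)
        assert m.total == grid.total_counts
        assert np.allclose(m.values.toarray(), np.round(m.values.toarray()))


class TestWeightByArea:
    def test_proportional_split(self):
        grid, cells, ov = two_cell_shared_bin(0, 4, 0, split=0.75)
        m = assign_weight_by_area(grid, ov, cells=cells)
        f = m.to_frame()
        assert f.loc["A", "G000"] == pytest.approx(3.0)
        assert f.loc["B", "G000"] == pytest.approx(1.0)

    def test_equal_split_on_equal_areas(self):
        grid, cells, ov = two_cell_shared_bin(0, 4, 0, split=0.5)
        m = assign_weight_by_area(grid, ov, cells=cells)
        f = m.to_frame()
        assert f.loc["A", "G000"] == pytest.approx(2.0)
        assert f.loc["B", "G000"] == pytest.approx(2.0)

    def test_single_cell_bin_matches_naive(self):
        grid, cells, ov = two_cell_shared_bin(7, 0, 3)
        area = assign_weight_by_area(grid, ov, cells=cells).to_frame()
        naive = assign_naive(grid, ov, cells=cells).to_frame()
        assert np.allclose(area.to_numpy(), naive.to_numpy())


class TestWeightByGene:
    def test_profile_proportional_split(self):
        # unique-bin profiles A=2, B=1; shared bin carries 6 of the gene
        grid, cells, ov = two_cell_shared_bin(2, 6, 1)
        cfg = AssignmentConfig(strategy="weight_by_gene", pseudocount=0.0)
        f = assign_weight_by_gene(grid, ov, cfg=cfg, cells=cells).to_frame()
        assert f.loc["A", "G000"] == pytest.approx(2 + 4.0)
        assert f.loc["B", "G000"] == pytest.approx(1 + 2.0)

    def test_zero_profiles_fall_back_to_area(self):
        grid, cells, ov = two_cell_shared_bin(0, 6, 0, split=0.75)
        cfg = AssignmentConfig(strategy="weight_by_gene", pseudocount=0.0)
        f = assign_weight_by_gene(grid, ov, cfg=cfg, cells=cells).to_frame()
        assert f.loc["A", "G000"] == pytest.approx(4.5)
        assert f.loc["B", "G000"] == pytest.approx(1.5)

    def test_equal_profiles_fall_back_to_area(self):
        grid, cells, ov = two_cell_shared_bin(2, 6, 2, split=0.75)
        cfg = AssignmentConfig(strategy="weight_by_gene", pseudocount=1.0)
        f = assign_weight_by_gene(grid, ov, cfg=cfg, cells=cells).to_frame()
        assert f.loc["A", "G000"] == pytest.approx(2 + 4.5)
        assert f.loc["B", "G000"] == pytest.approx(2 + 1.5)

    def test_negative_pseudocount_rejected(self):
        with pytest.raises(ConfigError):
            AssignmentConfig(strategy="weight_by_gene", pseudocount=-1.0)


class TestWeightByCluster:
    def test_same_cluster_candidates_split_equally(self):
        grid, cells, ov = two_cell_shared_bin(2, 4, 2, split=0.75)
        cfg = AssignmentConfig(strategy="weight_by_cluster", n_clusters=1, seed=0)
        f = assign_weight_by_cluster(grid, ov, cfg=cfg, cells=cells).to_frame()
        # tied cluster means -> equal split despite unequal areas
        assert f.loc["A", "G000"] == pytest.approx(2 + 2.0)
        assert f.loc["B", "G000"] == pytest.approx(2 + 2.0)

    def test_deterministic_given_seed(self, dense_dataset):
        ds = dense_dataset
        ov = spatial_join(ds.grid, ds.truth.cells)
        cfg = AssignmentConfig(strategy="weight_by_cluster", n_clusters=4, seed=5)
        a = assign_weight_by_cluster(ds.grid, ov, cfg=cfg, cells=ds.truth.cells)
        b = assign_weight_by_cluster(ds.grid, ov, cfg=cfg, cells=ds.truth.cells)
        assert a.values.toarray().tobytes() == b.values.toarray().tobytes()

    def test_too_many_clusters_rejected(self):
        grid, cells, ov = two_cell_shared_bin(2, 4, 2)
        cfg = AssignmentConfig(strategy="weight_by_cluster", n_clusters=5)
        with pytest.raises(DataError, match="n_clusters"):
            assign_weight_by_cluster(grid, ov, cfg=cfg, cells=cells)


class TestCrossStrategyContracts:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_conservation(self, dense_dataset, strategy):
        """Weighted strategies keep every overlapping bin's mass; naive keeps
        exactly the unique-bin mass."""
        ds = dense_dataset
        ov = spatial_join(ds.grid, ds.truth.cells)
        m = assign(
            ds.grid, ov, AssignmentConfig(strategy=strategy, seed=0), cells=ds.truth.cells
        )
        degree = ov.bin_degree()
        if strategy == "naive":
            eligible = degree.index.to_numpy()[degree.to_numpy() == 1]
            assert m.total == pytest.approx(float(ds.grid.counts[eligible].sum()), abs=1e-9)
        else:
            eligible = degree.index.to_numpy()
            expected = float(ds.grid.counts[eligible].sum())
            assert m.total == pytest.approx(expected, rel=1e-6)

    def test_naive_total_bounded_by_weighted(self, dense_dataset):
        ds = dense_dataset
        ov = spatial_join(ds.grid, ds.truth.cells)
        naive = assign_naive(ds.grid, ov, cells=ds.truth.cells)
        area = assign_weight_by_area(ds.grid, ov, cells=ds.truth.cells)
        assert naive.total <= area.total

    def test_all_strategies_identical_without_shared_bins(self):
        grid, cells, ov = two_cell_shared_bin(5, 0, 3)
        cfg = lambda s: AssignmentConfig(strategy=s, n_clusters=2, seed=0)
        mats = [
            assign(grid, ov, cfg(s), cells=cells).values.toarray() for s in STRATEGIES
        ]
        for other in mats[1:]:
            assert np.array_equal(mats[0], other)

    def test_cells_without_bins_retained_and_flagged(self):
        grid = grid_from_array(np.ones((1, 1, 1)))
        cells = [square_cell("A", 0, 0, 2), square_cell("far", 50, 50, 2)]
        ov = spatial_join(grid, cells)
        m = assign_naive(grid, ov, cells=cells)
        assert list(m.cell_ids) == ["A", "far"]
        assert m.zero_bin_cells.tolist() == [False, True]


def test_largest_remainder_rounding_preserves_total():
    values = sp.csr_matrix(np.array([[0.4, 1.2], [2.4, 3.0]]))
    rounded = largest_remainder_round(values).toarray()
    assert rounded.sum() == round(values.sum())
    assert np.allclose(rounded, np.round(rounded))
    assert (rounded >= np.floor(values.toarray())).all()
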