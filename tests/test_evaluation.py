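"""Transcript-level and annotation-level metrics, overlap statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hdassign.assignment import CellByGeneMatrix
from hdassign.errors import DataError
from hdassign.evaluation import (
    annotation_metrics,
    overlap_statistics,
    transcript_assignment_metrics,
)
from hdassign.geometry import OverlapTable, spatial_join

from conftest import brute_force_join, grid_from_array, square_cell


def matrix_of(entries, genes=("GA",)):
    """CellByGeneMatrix from {cell: {gene: value}}."""
    cells = sorted(entries, key=str)
    genes = list(genes)
    values = np.zeros((len(cells), len(genes)))
    for i, c in enumerate(cells):
        for g, v in entries[c].items():
            values[i, genes.index(g)] = v
    return CellByGeneMatrix(
        cell_ids=np.array(cells, dtype=object),
        gene_names=np.array(genes, dtype=object),
        values=sp.csr_matrix(values),
        strategy="test",
    )


class TestTranscriptMetrics:
    def test_identity_scores_one(self):
        t = matrix_of({"A": {"GA": 3}, "B": {"GA": 5}})
        m = transcript_assignment_metrics(t, t)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_all_zero_prediction(self):
        truth = matrix_of({"A": {"GA": 3}})
        pred = matrix_of({"A": {"GA": 0}})
        m = transcript_assignment_metrics(pred, truth)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_hand_computed_mass_overlap(self):
        truth = matrix_of({"A": {"GA": 3}})
        pred = matrix_of({"A": {"GA": 2}, "B": {"GA": 2}})
        m = transcript_assignment_metrics(pred, truth)
        assert m.tp == pytest.approx(2.0)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(4 / 7)

    def test_disjoint_universes_rejected(self):
        truth = matrix_of({"A": {"GA": 3}})
        pred = matrix_of({"X": {"GA": 3}})
        with pytest.raises(DataError, match="cell ID"):
            transcript_assignment_metrics(pred, truth)

    def test_spurious_counts_never_raise_precision(self):
        truth = matrix_of({"A": {"GA": 3}, "B": {"GA": 2}})
        pred = matrix_of({"A": {"GA": 3}, "B": {"GA": 2}})
        base = transcript_assignment_metrics(pred, truth)
        rng = np.random.default_rng(0)
        for _ in range(10):
            noisy = matrix_of(
                {
                    "A": {"GA": 3 + rng.uniform(0, 4)},
                    "B": {"GA": 2 + rng.uniform(0, 4)},
                }
            )
            m = transcript_assignment_metrics(noisy, truth)
            assert m.precision <= base.precision + 1e-12

    def test_removing_true_mass_from_pred_never_raises_recall(self):
        truth = matrix_of({"A": {"GA": 5}})
        prev_recall = 1.0
        for kept in (5, 4, 2, 0.5, 0):
            m = transcript_assignment_metrics(matrix_of({"A": {"GA": kept}}), truth)
            assert m.recall <= prev_recall + 1e-12
            prev_recall = m.recall

    def test_per_cell_average_mode(self):
        truth = matrix_of({"A": {"GA": 4}, "B": {"GA": 4}})
        pred = matrix_of({"A": {"GA": 4}, "B": {"GA": 2}})
        pooled = transcript_assignment_metrics(pred, truth)
        averaged = transcript_assignment_metrics(pred, truth, per_cell_average=True)
        assert pooled.recall == pytest.approx(6 / 8)
        assert averaged.recall == pytest.approx((1.0 + 0.5) / 2)


class TestAnnotationMetrics:
    def test_all_correct(self):
        m = annotation_metrics(["T1", "T2", "T1"], ["T1", "T2", "T1"])
        assert m.accuracy == 1.0
        assert (m.per_class["f1"] == 1.0).all()

    def test_binary_contingency_arithmetic(self):
        # true A,A,B,B vs pred A,B,A,B: each cell of the 2x2 table is 1
        m = annotation_metrics(["A", "B", "A", "B"], ["A", "A", "B", "B"])
        assert m.accuracy == pytest.approx(0.5)
        assert m.per_class.loc["A", "f1"] == pytest.approx(0.5)
        assert m.per_class.loc["B", "f1"] == pytest.approx(0.5)
        assert m.confusion.to_numpy().tolist() == [[1, 1], [1, 1]]
        assert m.weighted_f1 == pytest.approx(0.5)

    def test_constant_prediction(self):
        m = annotation_metrics(["T1"] * 4, ["T1", "T1", "T2", "T2"])
        assert m.per_class.loc["T1", "recall"] == 1.0
        assert m.per_class.loc["T2", "recall"] == 0.0

    def test_confusion_row_sums_are_supports(self):
        true = ["A", "A", "B", "C", "C", "C"]
        pred = ["A", "B", "B", "C", "A", "C"]
        m = annotation_metrics(pred, true)
        row_sums = m.confusion.sum(axis=1)
        for cls in ("A", "B", "C"):
            assert row_sums[cls] == true.count(cls)
        assert m.accuracy == pytest.approx(np.trace(m.confusion.to_numpy()) / 6)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            annotation_metrics([], [])


class TestOverlapStatistics:
    def test_counting_example(self):
        # 10 bins: 4 single-cell, 2 shared by two cells, 4 orphan
        grid = grid_from_array(np.zeros((1, 10, 1)))
        rows = []
        for b in range(4):
            rows.append((b, grid.bin_ids[b], "A", 1.0))
        for b in (4, 5):
            rows.append((b, grid.bin_ids[b], "A", 0.5))
            rows.append((b, grid.bin_ids[b], "B", 0.5))
        table = OverlapTable(
            pd.DataFrame(rows, columns=["bin_index", "bin_id", "cell_id", "area"])
        )
        stats = overlap_statistics(table, grid)
        assert stats.n_bins_total == 10
        assert stats.n_bins_overlapping == 6
        assert stats.n_bins_shared == 2
        assert stats.shared_fraction == pytest.approx(1 / 3)

    def test_no_overlaps_fraction_zero(self):
        grid = grid_from_array(np.zeros((1, 4, 1)))
        stats = overlap_statistics(OverlapTable.empty(), grid)
        assert stats.n_bins_overlapping == 0
        assert stats.shared_fraction == 0.0

    def test_consistent_with_bruteforce_join(self):
        grid = grid_from_array(np.zeros((5, 5, 1)))
        cells = [square_cell("A", 1, 1, 4), square_cell("B", 4.5, 4.5, 4)]
        table = spatial_join(grid, cells)
        stats = overlap_statistics(table, grid)
        oracle = brute_force_join(grid, cells)
        oracle_bins = {b for b, _, _ in oracle}
        oracle_shared = {
            b for b in oracle_bins
            if len({c for bb, c, _ in oracle if bb == b}) >= 2
        }
        assert stats.n_bins_overlapping == len(oracle_bins)
        assert stats.n_bins_shared == len(oracle_shared)
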