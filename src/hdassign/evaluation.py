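"""Transcript-level and annotation-level scoring against ground truth.

Transcript-level metrics use a mass-overlap definition that handles
fractional predictions without per-molecule identity: for each (cell, gene)
pair the true-positive mass is ``min(pred, truth)``; predicted mass beyond
that is false positive, and unrecovered true mass is false negative.  For
integer matrices this reduces to per-molecule counting.  All 0/0 ratios are
defined as 0.

Annotation is scored as an ordinary multi-class classifier (accuracy,
per-class and support-weighted precision/recall/F1, confusion matrix) over
the union of true and predicted label sets; ``Unknown`` is a valid
predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .assignment import CellByGeneMatrix
from .errors import DataError
from .geometry import BinGrid, OverlapTable


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


@dataclass
class AssignmentMetrics:
    """Precision/recall/F1 over transcript mass."""

    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float
    mode: str = "whole_cell"

    @classmethod
    def from_counts(cls, tp: float, fp: float, fn: float, mode: str) -> "AssignmentMetrics":
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * p * r, p + r)
        return cls(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f1=f1, mode=mode)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class AnnotationMetrics:
    """Multi-class annotation scores with the full confusion matrix."""

    accuracy: float
    per_class: pd.DataFrame  # index class; columns precision, recall, f1, support
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    confusion: pd.DataFrame  # true x predicted

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


@dataclass
class OverlapStats:
    """How contested the bin lattice is: orphan / unique / shared counts."""

    n_bins_total: int
    n_bins_overlapping: int
    n_bins_shared: int
    shared_fraction: float
    bins_per_cell: pd.Series  # distinct bins per cell

    def summary(self) -> dict:
        bpc = self.bins_per_cell
        return {
            "n_bins_total": self.n_bins_total,
            "n_bins_overlapping": self.n_bins_overlapping,
            "n_bins_shared": self.n_bins_shared,
            "shared_fraction": self.shared_fraction,
            "bins_per_cell_min": int(bpc.min()) if len(bpc) else 0,
            "bins_per_cell_median": float(bpc.median()) if len(bpc) else 0.0,
            "bins_per_cell_max": int(bpc.max()) if len(bpc) else 0,
        }


def _align(
    pred: CellByGeneMatrix, truth: CellByGeneMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Outer-align two matrices on (cell, gene), filling absences with zero.

    Cell ids are compared as strings so that containers that round-trip ids
    through text (H5AD obs names) still align with integer-keyed truth.
    """
    pf = pred.to_frame()
    tf = truth.to_frame()
    pf.index = pf.index.map(str)
    tf.index = tf.index.map(str)
    if set(pf.index).isdisjoint(tf.index):
        raise DataError(
            "predicted and true matrices share no cell ids — "
            "likely a cell ID scheme mismatch"
        )
    cells = sorted(set(pf.index) | set(tf.index))
    genes = sorted(set(pred.gene_names) | set(truth.gene_names), key=str)
    pf = pf.reindex(index=cells, columns=genes, fill_value=0.0)
    tf = tf.reindex(index=cells, columns=genes, fill_value=0.0)
    return pf.to_numpy(dtype=float), tf.to_numpy(dtype=float)


def transcript_assignment_metrics(
    pred: CellByGeneMatrix,
    truth: CellByGeneMatrix,
    mode: Literal["whole_cell", "nucleus"] = "whole_cell",
    per_cell_average: bool = False,
) -> AssignmentMetrics:
    """Mass-overlap precision/recall/F1 of a predicted cell-by-gene matrix.

    ``truth`` should be the whole-cell tally for ``whole_cell`` mode and the
    nucleus-restricted tally for ``nucleus`` mode (see
    ``GroundTruthTranscripts.cell_matrix``).  With ``per_cell_average`` the
    precision/recall are computed per cell and averaged over cells with any
    true or predicted mass, rather than globally pooled.
    """
    P, T = _align(pred, truth)
    tp_cg = np.minimum(P, T)
    if per_cell_average:
        tp_c = tp_cg.sum(axis=1)
        p_c = P.sum(axis=1)
        t_c = T.sum(axis=1)
        active = (p_c > 0) | (t_c > 0)
        prec = np.where(p_c[active] > 0, tp_c[active] / np.maximum(p_c[active], 1e-300), 0.0)
        rec = np.where(t_c[active] > 0, tp_c[active] / np.maximum(t_c[active], 1e-300), 0.0)
        p = float(prec.mean()) if active.any() else 0.0
        r = float(rec.mean()) if active.any() else 0.0
        f1 = _safe_div(2 * p * r, p + r)
        tp = float(tp_cg.sum())
        return AssignmentMetrics(
            tp=tp, fp=float(P.sum() - tp), fn=float(T.sum() - tp),
            precision=p, recall=r, f1=f1, mode=mode,
        )
    tp = float(tp_cg.sum())
    fp = float(P.sum() - tp)
    fn = float(T.sum() - tp)
    return AssignmentMetrics.from_counts(tp, fp, fn, mode)


def annotation_metrics(
    pred_labels: np.ndarray | list,
    true_labels: np.ndarray | list,
) -> AnnotationMetrics:
    """Score predicted labels as a multi-class classifier."""
    pred = np.asarray(pred_labels, dtype=object)
    true = np.asarray(true_labels, dtype=object)
    if len(pred) == 0 or len(pred) != len(true):
        raise DataError(
            f"label arrays must be equal-length and non-empty "
            f"(got {len(pred)} vs {len(true)})"
        )
    classes = sorted(set(pred) | set(true), key=str)
    cm = _sk_confusion(true, pred, labels=classes)
    acc = float(np.trace(cm)) / float(cm.sum())
    prec, rec, f1, support = _sk_prfs(
        true, pred, labels=classes, average=None, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=pd.Index(classes, name="class"),
    )
    wprec, wrec, wf1, _ = _sk_prfs(
        true, pred, labels=classes, average="weighted", zero_division=0
    )
    confusion = pd.DataFrame(cm, index=pd.Index(classes, name="true"), columns=classes)
    return AnnotationMetrics(
        accuracy=acc,
        per_class=per_class,
        weighted_precision=float(wprec),
        weighted_recall=float(wrec),
        weighted_f1=float(wf1),
        confusion=confusion,
    )


def overlap_statistics(overlaps: OverlapTable, grid: BinGrid) -> OverlapStats:
    """Orphan / unique / shared bin counts and per-cell bin-count summary.

    ``shared_fraction`` is the proportion of *cell-intersecting* bins that
    touch two or more cells — the key difficulty parameter separating dense
    from sparse tissue (0 when no bin overlaps any cell).
    """
    degree = overlaps.bin_degree()
    n_overlapping = int(len(degree))
    n_shared = int((degree >= 2).sum())
    bins_per_cell = overlaps.records.groupby("cell_id")["bin_id"].nunique()
    return OverlapStats(
        n_bins_total=grid.n_bins,
        n_bins_overlapping=n_overlapping,
        n_bins_shared=n_shared,
        shared_fraction=_safe_div(n_shared, n_overlapping),
        bins_per_cell=bins_per_cell,
    )
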