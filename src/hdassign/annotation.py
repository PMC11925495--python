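"""Marker-score cell-type annotation.

A transparent, deterministic stand-in for external score-based annotators:
each cell is normalized to counts-per-total and log-transformed, every gene
is z-scored across cells, and each candidate type's score is the mean
z-score of its marker genes.  The cell is labeled with the arg-max type;
low-count cells and exact top-two ties are labeled ``Unknown``.  Users who
prefer an external annotator (probabilistic or classifier-based) can hand
the H5AD container off and write labels back into ``obs``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import CellByGeneMatrix
from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

UNKNOWN = "Unknown"

#: guard against zero standard deviation for constant genes
_Z_EPS = 1e-8


@dataclass
class MarkerSet:
    """Mapping from cell type to its marker gene symbols."""

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise DataError("MarkerSet needs at least 2 cell types")
        for t, genes in self.markers.items():
            if not genes:
                raise DataError(f"cell type {t!r} has no marker genes")

    @property
    def types(self) -> list[str]:
        return list(self.markers)

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerSet":
        """Load from CSV (columns cell_type, gene) or JSON ({type: [genes]})."""
        path = Path(path)
        if not path.exists():
            raise FormatError(f"marker file not found: {path}")
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
            return cls({t: list(g) for t, g in data.items()})
        df = pd.read_csv(path)
        required = {"cell_type", "gene"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"marker CSV must have columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        grouped = df.groupby("cell_type", sort=False)["gene"].apply(list)
        return cls(grouped.to_dict())

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.markers, indent=1))
        else:
            rows = [
                {"cell_type": t, "gene": g}
                for t, genes in self.markers.items()
                for g in genes
            ]
            pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class LabelMapping:
    """Fine-to-coarse label map (e.g. Goblet cells -> Epithelial).

    Unmapped fine labels fall through to ``default``; ``Unknown`` is never
    remapped.
    """

    mapping: dict[str, str]
    default: str = UNKNOWN

    @classmethod
    def from_file(cls, path: str | Path, default: str = UNKNOWN) -> "LabelMapping":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise FormatError("label map CSV needs two columns (fine, coarse)")
        fine, coarse = df.columns[:2]
        return cls(dict(zip(df[fine], df[coarse])), default=default)

    def apply(self, label: str) -> str:
        if label == UNKNOWN:
            return UNKNOWN
        return self.mapping.get(label, self.default)


@dataclass
class CellAnnotation:
    """Per-cell labels with the underlying type scores."""

    cell_ids: np.ndarray
    labels: np.ndarray
    scores: pd.DataFrame  # cells x types, mean marker z-scores
    confidence: np.ndarray  # top score minus runner-up

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.copy()
        df.insert(0, "label", self.labels)
        df["confidence"] = self.confidence
        return df


def score_cell_types(
    m: CellByGeneMatrix,
    markers: MarkerSet,
    min_counts: int = 5,
) -> CellAnnotation:
    """Label each cell with the arg-max marker z-score type.

    Cells whose total transcript estimate is below ``min_counts``, and cells
    whose top two type scores tie exactly, are labeled ``Unknown``.  Marker
    genes absent from the matrix's gene universe are dropped with a warning;
    a type loses its score only if *all* its markers are missing.
    """
    gene_index = {g: i for i, g in enumerate(m.gene_names)}
    marker_cols: dict[str, np.ndarray] = {}
    for t, genes in markers.markers.items():
        present = [gene_index[g] for g in genes if g in gene_index]
        absent = [g for g in genes if g not in gene_index]
        if absent:
            logger.warning(
                "type %s: %d/%d markers absent from gene universe",
                t,
                len(absent),
                len(genes),
            )
        if present:
            marker_cols[t] = np.array(present)
    if not marker_cols:
        raise DataError("no marker gene of any type is present in the matrix")

    X = m.values.toarray().astype(float)
    totals = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpt = np.where(totals[:, None] > 0, X / np.maximum(totals[:, None], 1e-300), 0.0)
    L = np.log1p(cpt)
    mu = L.mean(axis=0)
    sd = L.std(axis=0)  # population standard deviation
    Z = (L - mu) / (sd + _Z_EPS)

    scores = pd.DataFrame(
        {t: Z[:, cols].mean(axis=1) for t, cols in marker_cols.items()},
        index=pd.Index(m.cell_ids),
    )
    S = scores.to_numpy()
    order = np.sort(S, axis=1)
    top = order[:, -1]
    runner = order[:, -2] if S.shape[1] > 1 else np.full(len(S), -np.inf)
    confidence = top - runner
    labels = np.asarray(scores.columns.to_numpy()[np.argmax(S, axis=1)], dtype=object)
    labels[confidence == 0] = UNKNOWN
    labels[totals < min_counts] = UNKNOWN
    return CellAnnotation(
        cell_ids=np.asarray(m.cell_ids),
        labels=labels,
        scores=scores,
        confidence=confidence,
    )


def map_to_coarse_labels(a: CellAnnotation, lm: LabelMapping) -> CellAnnotation:
    """Replace fine labels with coarse classes; scores are preserved."""
    coarse = np.array([lm.apply(l) for l in a.labels], dtype=object)
    return CellAnnotation(
        cell_ids=a.cell_ids,
        labels=coarse,
        scores=a.scores,
        confidence=a.confidence,
    )
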