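"""Bin-to-cell transcript imputation.

Each 2 µm bin's gene counts must be credited to the cell(s) whose outline it
intersects.  Bins intersecting exactly one cell ("unique" bins) are
unambiguous and are summed into that cell under every strategy.  Bins
intersecting two or more cells ("shared" bins) are handled per strategy:

``naive``
    Shared bins are discarded.  High precision — a unique bin can only carry
    its own cell's transcripts plus ambient noise — but transcript mass in
    shared bins is lost, depressing recall in dense tissue.
``weight_by_area``
    Each shared bin's counts are split across its candidate cells in
    proportion to the polygon intersection area.
``weight_by_gene``
    Two passes: cell expression profiles are first built from unique bins
    only; each shared bin's counts are then split gene-by-gene in proportion
    to the candidates' (pseudocount-smoothed) profile mass for that gene.
    When every candidate's smoothed mass for a gene is identical the split
    falls back to area weights.
``weight_by_cluster``
    Like ``weight_by_gene`` but the reference profiles are cluster means:
    the unique-bin profiles are normalized, log-transformed, reduced by PCA
    and k-means clustered; each candidate contributes its cluster's mean
    profile.  Cells in the same cluster therefore tie and split a shared
    bin's gene equally; the area fallback applies only when the weights are
    undefined (all smoothed masses zero).

Weighted outputs are fractional; per-bin (area) and per-bin-per-gene
(gene/cluster) weights always sum to 1 over the candidate cells, so weighted
strategies conserve the transcript mass of every bin that overlaps at least
one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigError, DataError
from .geometry import BinGrid, CellOutline, OverlapTable

Strategy = Literal["naive", "weight_by_area", "weight_by_gene", "weight_by_cluster"]

STRATEGIES: tuple[str, ...] = (
    "naive",
    "weight_by_area",
    "weight_by_gene",
    "weight_by_cluster",
)


@dataclass
class AssignmentConfig:
    """Knobs for the weighted strategies.

    pseudocount
        Additive smoothing applied to profile masses in the gene- and
        cluster-weighted strategies.  Default 1.0 avoids degenerate
        all-to-one splits for genes unseen in unique bins.
    n_clusters
        Number of k-means clusters for ``weight_by_cluster``.
    seed
        Seed for PCA/k-means; fixes the output bit-for-bit.
    keep_fractional
        If False, weighted outputs are rounded per bin by largest remainder
        so each bin's integer mass is preserved.
    """

    strategy: Strategy = "weight_by_area"
    pseudocount: float = 1.0
    n_clusters: int = 4
    seed: int = 0
    keep_fractional: bool = True

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigError(
                f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}"
            )
        if self.pseudocount < 0:
            raise ConfigError(f"pseudocount must be >= 0, got {self.pseudocount}")
        if self.n_clusters < 1:
            raise ConfigError(f"n_clusters must be >= 1, got {self.n_clusters}")


@dataclass
class CellByGeneMatrix:
    """Per-cell transcript estimates with provenance.

    ``values`` is integer-valued for the naive strategy and fractional for
    the weighted ones.  Cells that received no bins are retained with
    all-zero rows and flagged in ``zero_bin_cells``.
    """

    cell_ids: np.ndarray
    gene_names: np.ndarray
    values: sp.csr_matrix
    strategy: str
    centroids: np.ndarray | None = None  # (n_cells, 2) µm
    n_bins: np.ndarray | None = None  # contributing bins per cell
    cell_types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.cell_ids), len(self.gene_names)):
            raise DataError("CellByGeneMatrix shape mismatch")
        if self.values.nnz and self.values.data.min() < -1e-12:
            raise DataError("negative values in cell-by-gene matrix")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @property
    def zero_bin_cells(self) -> np.ndarray:
        if self.n_bins is None:
            return np.asarray(self.values.sum(axis=1)).ravel() == 0
        return self.n_bins == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.cell_ids, columns=self.gene_names
        )


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------


def _cell_universe(
    overlaps: OverlapTable, cells: list[CellOutline] | None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Ordered cell ids (and centroids) for the output matrix.

    With an explicit cell collection the universe is every segmented cell in
    its given order — including cells that intersect no bin.  Without one,
    it is the sorted set of cells present in the overlap table.
    """
    if cells is not None:
        ids = np.array([c.cell_id for c in cells], dtype=object)
        if len(set(ids)) != len(ids):
            raise DataError("duplicate cell ids in cell collection")
        centroids = np.array([c.centroid for c in cells], dtype=float)
        return ids, centroids
    ids = np.array(sorted(overlaps.cell_ids), dtype=object)
    return ids, None


def _prepare(grid: BinGrid, overlaps: OverlapTable, cells):
    """Resolve overlap records against the (possibly filtered) grid."""
    cell_ids, centroids = _cell_universe(overlaps, cells)
    cell_pos = {cid: i for i, cid in enumerate(cell_ids)}
    rec = overlaps.records
    bin_pos_of_id = pd.Series(
        np.arange(grid.n_bins), index=pd.Index(grid.bin_ids)
    )
    bpos = bin_pos_of_id.reindex(rec["bin_id"]).to_numpy()
    present = ~pd.isna(bpos)
    rec = rec[present].copy()
    rec["bin_pos"] = bpos[present].astype(np.int64)
    missing = set(rec["cell_id"]) - set(cell_pos)
    if missing:
        raise DataError(
            f"overlap table references cells absent from the collection: "
            f"{sorted(map(str, missing))[:5]}"
        )
    rec["cell_pos"] = rec["cell_id"].map(cell_pos).to_numpy(dtype=np.int64)
    degree = rec.groupby("bin_pos")["cell_pos"].transform("size").to_numpy()
    return cell_ids, centroids, rec, degree


def _weights_to_matrix(
    grid: BinGrid,
    cell_ids: np.ndarray,
    bin_pos: np.ndarray,
    cell_pos: np.ndarray,
    weights: np.ndarray,
) -> sp.csr_matrix:
    """values = W @ counts for a (cells x bins) scalar weight matrix."""
    W = sp.csr_matrix(
        (weights, (cell_pos, bin_pos)), shape=(len(cell_ids), grid.n_bins)
    )
    return sp.csr_matrix(W @ grid.counts)


def _bins_per_cell(
    cell_ids: np.ndarray, cell_pos: np.ndarray
) -> np.ndarray:
    counts = np.bincount(cell_pos, minlength=len(cell_ids))
    return counts.astype(np.int64)


def largest_remainder_round(values: sp.csr_matrix) -> sp.csr_matrix:
    """Round a fractional matrix row-group-free: per matrix cell, largest
    remainder against the global floor, preserving the rounded total."""
    dense = values.toarray()
    floor = np.floor(dense)
    remainder = dense - floor
    deficit = int(round(dense.sum() - floor.sum()))
    if deficit > 0:
        flat = remainder.ravel()
        top = np.argpartition(flat, -deficit)[-deficit:]
        add = np.zeros_like(flat)
        add[top] = 1
        floor += add.reshape(dense.shape)
    return sp.csr_matrix(floor)


# ---------------------------------------------------------------------------
# strategies
# ---------------------------------------------------------------------------


def assign_naive(
    grid: BinGrid,
    overlaps: OverlapTable,
    cells: list[CellOutline] | None = None,
) -> CellByGeneMatrix:
    """Sum unique bins into their cell; discard every shared bin."""
    cell_ids, centroids, rec, degree = _prepare(grid, overlaps, cells)
    uniq = rec[degree == 1]
    values = _weights_to_matrix(
        grid,
        cell_ids,
        uniq["bin_pos"].to_numpy(),
        uniq["cell_pos"].to_numpy(),
        np.ones(len(uniq)),
    )
    return CellByGeneMatrix(
        cell_ids=cell_ids,
        gene_names=grid.gene_names,
        values=values,
        strategy="naive",
        centroids=centroids,
        n_bins=_bins_per_cell(cell_ids, uniq["cell_pos"].to_numpy()),
    )


def _area_weights(rec: pd.DataFrame) -> np.ndarray:
    total = rec.groupby("bin_pos")["area"].transform("sum").to_numpy()
    return rec["area"].to_numpy() / total


def assign_weight_by_area(
    grid: BinGrid,
    overlaps: OverlapTable,
    cells: list[CellOutline] | None = None,
    cfg: AssignmentConfig | None = None,
) -> CellByGeneMatrix:
    """Split each bin's counts in proportion to intersection area."""
    cell_ids, centroids, rec, _ = _prepare(grid, overlaps, cells)
    weights = _area_weights(rec)
    values = _weights_to_matrix(
        grid,
        cell_ids,
        rec["bin_pos"].to_numpy(),
        rec["cell_pos"].to_numpy(),
        weights,
    )
    if cfg is not None and not cfg.keep_fractional:
        values = largest_remainder_round(values)
    return CellByGeneMatrix(
        cell_ids=cell_ids,
        gene_names=grid.gene_names,
        values=values,
        strategy="weight_by_area",
        centroids=centroids,
        n_bins=_bins_per_cell(cell_ids, rec["cell_pos"].to_numpy()),
    )


def _profile_weighted(
    grid: BinGrid,
    cell_ids: np.ndarray,
    rec: pd.DataFrame,
    degree: np.ndarray,
    profiles: np.ndarray,
    pseudocount: float,
    tie_to_area: bool,
) -> sp.csr_matrix:
    """Split shared bins gene-by-gene in proportion to smoothed profile mass.

    ``profiles`` maps each cell position to its reference expression vector.
    ``tie_to_area`` selects the fallback when every candidate's smoothed
    mass for a gene is equal: area weights (gene strategy) or the equal
    split that normalization already yields (cluster strategy, where only an
    all-zero denominator triggers the area fallback).
    """
    uniq = rec[degree == 1]
    base = _weights_to_matrix(
        grid,
        cell_ids,
        uniq["bin_pos"].to_numpy(),
        uniq["cell_pos"].to_numpy(),
        np.ones(len(uniq)),
    )

    shared = rec[degree >= 2]
    counts = grid.counts.tocsr()
    area_w = _area_weights(rec)
    shared = shared.assign(area_weight=area_w[(degree >= 2)])

    acc_rows: list[np.ndarray] = []
    acc_cols: list[np.ndarray] = []
    acc_vals: list[np.ndarray] = []
    for bin_pos, group in shared.groupby("bin_pos", sort=True):
        row = counts.getrow(int(bin_pos))
        if row.nnz == 0:
            continue
        genes = row.indices
        x = row.data.astype(float)
        cand = group["cell_pos"].to_numpy()
        aw = group["area_weight"].to_numpy()
        mass = profiles[np.ix_(cand, genes)] + pseudocount  # (n_cand, n_genes_b)
        denom = mass.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = mass / denom
        tied = (mass.max(axis=0) - mass.min(axis=0)) <= 1e-12
        if tie_to_area:
            fallback = tied
        else:
            fallback = denom <= 0
            equal_split = tied & ~fallback
            if equal_split.any():
                w[:, equal_split] = 1.0 / len(cand)
        if fallback.any():
            w[:, fallback] = aw[:, None]
        contrib = w * x[None, :]  # (n_cand, n_genes_b)
        acc_rows.append(np.repeat(cand, len(genes)))
        acc_cols.append(np.tile(genes, len(cand)))
        acc_vals.append(contrib.ravel())
    if acc_rows:
        extra = sp.csr_matrix(
            (
                np.concatenate(acc_vals),
                (np.concatenate(acc_rows), np.concatenate(acc_cols)),
            ),
            shape=base.shape,
        )
        base = base + extra
    return sp.csr_matrix(base)


def _naive_profiles(
    grid: BinGrid, cell_ids: np.ndarray, rec: pd.DataFrame, degree: np.ndarray
) -> np.ndarray:
    uniq = rec[degree == 1]
    mat = _weights_to_matrix(
        grid,
        cell_ids,
        uniq["bin_pos"].to_numpy(),
        uniq["cell_pos"].to_numpy(),
        np.ones(len(uniq)),
    )
    return mat.toarray()


def assign_weight_by_gene(
    grid: BinGrid,
    overlaps: OverlapTable,
    cfg: AssignmentConfig | None = None,
    cells: list[CellOutline] | None = None,
) -> CellByGeneMatrix:
    """Split shared bins gene-wise by each candidate's unique-bin profile."""
    cfg = cfg or AssignmentConfig(strategy="weight_by_gene")
    if cfg.pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    cell_ids, centroids, rec, degree = _prepare(grid, overlaps, cells)
    profiles = _naive_profiles(grid, cell_ids, rec, degree)
    values = _profile_weighted(
        grid, cell_ids, rec, degree, profiles, cfg.pseudocount, tie_to_area=True
    )
    if not cfg.keep_fractional:
        values = largest_remainder_round(values)
    return CellByGeneMatrix(
        cell_ids=cell_ids,
        gene_names=grid.gene_names,
        values=values,
        strategy="weight_by_gene",
        centroids=centroids,
        n_bins=_bins_per_cell(cell_ids, rec["cell_pos"].to_numpy()),
    )


def cluster_cells(
    profiles: np.ndarray, n_clusters: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster cell profiles: counts-per-total, log1p, PCA, k-means.

    Returns (labels, cluster_means) where labels is -1 for cells with an
    all-zero profile (they are excluded from clustering) and cluster_means
    holds the mean *raw* profile of each cluster.
    """
    totals = profiles.sum(axis=1)
    nonzero = totals > 0
    if nonzero.sum() < n_clusters:
        raise DataError(
            f"only {int(nonzero.sum())} cells have a nonzero unique-bin "
            f"profile; reduce n_clusters below {n_clusters}"
        )
    X = profiles[nonzero] / totals[nonzero, None]
    X = np.log1p(X)
    n_comp = min(50, X.shape[1], X.shape[0])
    if n_comp < X.shape[1]:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    sub_labels = km.fit_predict(X)
    labels = np.full(len(profiles), -1, dtype=int)
    labels[nonzero] = sub_labels
    means = np.zeros((n_clusters, profiles.shape[1]))
    for k in range(n_clusters):
        members = labels == k
        if members.any():
            means[k] = profiles[members].mean(axis=0)
    return labels, means


def assign_weight_by_cluster(
    grid: BinGrid,
    overlaps: OverlapTable,
    cfg: AssignmentConfig | None = None,
    cells: list[CellOutline] | None = None,
) -> CellByGeneMatrix:
    """Split shared bins gene-wise by the candidates' cluster-mean profiles."""
    cfg = cfg or AssignmentConfig(strategy="weight_by_cluster")
    cell_ids, centroids, rec, degree = _prepare(grid, overlaps, cells)
    profiles = _naive_profiles(grid, cell_ids, rec, degree)
    labels, means = cluster_cells(profiles, cfg.n_clusters, cfg.seed)
    # reference profile of each cell = its cluster's mean; zero for
    # unclustered (all-zero-profile) cells
    ref = np.zeros_like(profiles)
    clustered = labels >= 0
    ref[clustered] = means[labels[clustered]]
    values = _profile_weighted(
        grid, cell_ids, rec, degree, ref, cfg.pseudocount, tie_to_area=False
    )
    if not cfg.keep_fractional:
        values = largest_remainder_round(values)
    return CellByGeneMatrix(
        cell_ids=cell_ids,
        gene_names=grid.gene_names,
        values=values,
        strategy="weight_by_cluster",
        centroids=centroids,
        n_bins=_bins_per_cell(cell_ids, rec["cell_pos"].to_numpy()),
    )


def assign(
    grid: BinGrid,
    overlaps: OverlapTable,
    cfg: AssignmentConfig,
    cells: list[CellOutline] | None = None,
) -> CellByGeneMatrix:
    """Dispatch on ``cfg.strategy``."""
    if cfg.strategy == "naive":
        return assign_naive(grid, overlaps, cells=cells)
    if cfg.strategy == "weight_by_area":
        return assign_weight_by_area(grid, overlaps, cells=cells, cfg=cfg)
    if cfg.strategy == "weight_by_gene":
        return assign_weight_by_gene(grid, overlaps, cfg=cfg, cells=cells)
    if cfg.strategy == "weight_by_cluster":
        return assign_weight_by_cluster(grid, overlaps, cfg=cfg, cells=cells)
    raise ConfigError(f"unknown strategy {cfg.strategy!r}")
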