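"""Geometric core: the 2 µm bin lattice, cell outlines, and their overlaps.

Coordinate convention
---------------------
All coordinates are in micrometres, origin at the tissue's upper-left corner,
x increasing rightwards and y downwards (image convention).  Bin ``(r, c)``
occupies the half-open square ``[x0 + c*s, x0 + (c+1)*s) x [y0 + r*s,
y0 + (r+1)*s)`` where ``s`` is the bin size.  Because the squares are
half-open, bin footprints tile the plane: two bins never share interior
points, and a transcript point on a shared edge belongs to exactly one bin.

Overlap between a bin and a cell means *positive intersection area* — pure
edge or vertex contact does not count.  Intersection areas below
``AREA_EPS`` (1e-9 µm²) are treated as zero to guard against sliver
artifacts of polygon repair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .errors import DataError

logger = logging.getLogger(__name__)

#: intersection areas below this many µm² are treated as zero
AREA_EPS = 1e-9

DEFAULT_BIN_SIZE = 2.0


def format_bin_id(row: int, col: int, bin_size: float = DEFAULT_BIN_SIZE) -> str:
    """10x-style barcode for the bin at grid position (row, col)."""
    um = int(round(bin_size))
    return f"s_{um:03d}um_{row:05d}_{col:05d}-1"


@dataclass
class BinGrid:
    """A regular lattice of square capture bins with sparse gene counts.

    Parameters
    ----------
    counts
        Sparse non-negative matrix, bins x genes, in the same order as
        ``bin_ids`` / ``rows`` / ``cols``.
    gene_names
        Ordered gene symbols (matrix columns).
    bin_ids
        Ordered bin identifiers (matrix rows).
    rows, cols
        Grid indices of each bin.
    origin
        (x, y) µm of the lattice corner; bin (0, 0) has its upper-left corner
        here.
    bin_size
        Side length of a bin in µm (2 for Visium HD).
    """

    counts: sp.csr_matrix
    gene_names: np.ndarray
    bin_ids: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    bin_size: float = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.bin_ids = np.asarray(self.bin_ids, dtype=object)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.bin_size <= 0:
            raise DataError(f"bin_size must be positive, got {self.bin_size}")
        n, g = self.counts.shape
        if not (len(self.bin_ids) == len(self.rows) == len(self.cols) == n):
            raise DataError(
                f"bin metadata length mismatch: counts has {n} rows, "
                f"{len(self.bin_ids)} bin_ids, {len(self.rows)} rows, "
                f"{len(self.cols)} cols"
            )
        if len(self.gene_names) != g:
            raise DataError(
                f"{len(self.gene_names)} gene names for {g} matrix columns"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("negative counts in bin matrix")

    # -- basic properties ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def n_rows(self) -> int:
        return int(self.rows.max()) + 1 if self.n_bins else 0

    @property
    def n_cols(self) -> int:
        return int(self.cols.max()) + 1 if self.n_bins else 0

    # -- manipulation -------------------------------------------------------

    def canonicalized(self) -> "BinGrid":
        """Return a copy with bins sorted row-major by grid index."""
        order = np.lexsort((self.cols, self.rows))
        return self.subset(order)

    def subset(self, index: np.ndarray) -> "BinGrid":
        """Restrict to the given bin positions (bool mask or index array)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            counts=self.counts[index],
            bin_ids=self.bin_ids[index],
            rows=self.rows[index],
            cols=self.cols[index],
        )

    def bin_corners(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-left (x, y) corner of each bin, in µm."""
        x0 = self.origin[0] + self.cols * self.bin_size
        y0 = self.origin[1] + self.rows * self.bin_size
        return x0, y0


@dataclass
class CellOutline:
    """A segmented cell: identifier plus simple polygon in µm."""

    cell_id: object
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            fixed = shapely.make_valid(self.polygon)
            if fixed.geom_type == "MultiPolygon":
                fixed = max(fixed.geoms, key=lambda g: g.area)
            elif fixed.geom_type == "GeometryCollection":
                polys = [g for g in fixed.geoms if isinstance(g, Polygon)]
                if not polys:
                    raise DataError(f"cell {self.cell_id}: cannot repair outline")
                fixed = max(polys, key=lambda g: g.area)
            logger.warning("cell %s: invalid polygon repaired", self.cell_id)
            self.polygon = fixed
        # normalize ring orientation (exterior CCW)
        self.polygon = shapely.geometry.polygon.orient(self.polygon)
        if self.polygon.area <= 0:
            raise DataError(f"cell {self.cell_id}: outline has zero area")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class OverlapTable:
    """(bin, cell, intersection area) triples from the spatial join.

    ``records`` has columns ``bin_index`` (position in the source grid),
    ``bin_id``, ``cell_id`` and ``area`` (µm²); every area is positive.
    """

    records: pd.DataFrame
    bin_size: float = DEFAULT_BIN_SIZE

    _COLUMNS = ("bin_index", "bin_id", "cell_id", "area")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.records.columns)
        if missing:
            raise DataError(f"OverlapTable records missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)

    @classmethod
    def empty(cls, bin_size: float = DEFAULT_BIN_SIZE) -> "OverlapTable":
        df = pd.DataFrame(
            {
                "bin_index": pd.Series(dtype=np.int64),
                "bin_id": pd.Series(dtype=object),
                "cell_id": pd.Series(dtype=object),
                "area": pd.Series(dtype=float),
            }
        )
        return cls(df, bin_size=bin_size)

    def validate(self) -> None:
        a = self.records["area"].to_numpy()
        if len(a) and a.min() <= 0:
            raise DataError("OverlapTable contains non-positive intersection areas")
        cap = self.bin_size**2 * (1 + 1e-9)
        if len(a) and a.max() > cap:
            raise DataError("intersection area exceeds bin footprint")
        per_bin = self.records.groupby("bin_index")["area"].sum()
        # equality allowed when overlapping cells jointly cover a bin
        if len(per_bin) and per_bin.max() > cap * (1 + 1e-6):
            pass  # overlapping input cells may over-cover a bin; not an error

    # -- indices ------------------------------------------------------------

    def cells_of_bin(self) -> dict:
        """bin_id -> list of overlapping cell_ids."""
        return self.records.groupby("bin_id")["cell_id"].apply(list).to_dict()

    def bins_of_cell(self) -> dict:
        """cell_id -> list of overlapping bin_ids."""
        return self.records.groupby("cell_id")["bin_id"].apply(list).to_dict()

    def bin_degree(self) -> pd.Series:
        """Number of overlapping cells per bin_index."""
        return self.records.groupby("bin_index").size()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.records["cell_id"].unique()

    @property
    def n_records(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_bin_polygons(grid: BinGrid) -> np.ndarray:
    """Closed-box shapely polygons for each bin footprint.

    The half-open tiling convention is enforced downstream by the
    positive-area overlap predicate, so closed boxes are safe here: two
    adjacent closed boxes intersect only in a zero-area edge.
    """
    x0, y0 = grid.bin_corners()
    s = grid.bin_size
    return shapely.box(x0, y0, x0 + s, y0 + s)


def spatial_join(grid: BinGrid, cells: list[CellOutline]) -> OverlapTable:
    """All (bin, cell) pairs with positive intersection area.

    Uses an STRtree bulk-loaded on the cell polygons as a candidate filter;
    every candidate pair is verified by an exact polygon intersection, so the
    result is identical to the brute-force all-pairs join.
    """
    if not cells:
        return OverlapTable.empty(bin_size=grid.bin_size)
    bin_geoms = build_bin_polygons(grid)
    cell_geoms = np.array([c.polygon for c in cells], dtype=object)
    tree = shapely.STRtree(cell_geoms)
    bi, ci = tree.query(bin_geoms, predicate="intersects")
    if len(bi) == 0:
        return OverlapTable.empty(bin_size=grid.bin_size)
    areas = shapely.area(shapely.intersection(bin_geoms[bi], cell_geoms[ci]))
    keep = areas > AREA_EPS
    bi, ci, areas = bi[keep], ci[keep], areas[keep]
    cell_ids = np.array([c.cell_id for c in cells], dtype=object)
    df = pd.DataFrame(
        {
            "bin_index": bi.astype(np.int64),
            "bin_id": grid.bin_ids[bi],
            "cell_id": cell_ids[ci],
            "area": areas,
        }
    )
    df = df.sort_values(["bin_index", "cell_id"], kind="stable").reset_index(drop=True)
    table = OverlapTable(df, bin_size=grid.bin_size)
    table.validate()
    return table


def expand_outlines(cells: list[CellOutline], distance: float) -> list[CellOutline]:
    """Dilate each outline outward by ``distance`` µm with mitre joins.

    Distance 0 returns the cells unchanged.  Expanded outlines may mutually
    overlap; the weighted assignment strategies arbitrate shared territory,
    so no clipping is performed here.
    """
    if distance < 0:
        raise DataError(f"expansion distance must be >= 0, got {distance}")
    if distance == 0:
        return list(cells)
    out = []
    for c in cells:
        poly = c.polygon.buffer(distance, join_style="mitre")
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        out.append(CellOutline(cell_id=c.cell_id, polygon=poly))
    return out


def filter_orphan_bins(grid: BinGrid, overlaps: OverlapTable) -> BinGrid:
    """Drop bins that intersect no cell outline.

    Logs how many bins and how much transcript mass were removed, mirroring
    the pipeline's per-stage diagnostics.
    """
    keep = np.zeros(grid.n_bins, dtype=bool)
    if overlaps.n_records:
        keep[overlaps.records["bin_index"].unique()] = True
    removed = int((~keep).sum())
    removed_counts = float(grid.counts[~keep].sum()) if removed else 0.0
    if keep.sum() == 0:
        logger.warning("no bins intersect any cell outline; grid is now empty")
    logger.info(
        "orphan-bin filter: removed %d of %d bins (%.0f transcripts)",
        removed,
        grid.n_bins,
        removed_counts,
    )
    return grid.subset(keep)
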