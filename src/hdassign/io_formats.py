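"""On-disk formats: MTX bin counts, GeoJSON outlines, label masks, H5AD.

Layout of a bin-counts directory (Space-Ranger-like)::

    matrix.mtx        sparse bins x genes counts (MatrixMarket)
    barcodes.tsv      one bin identifier per matrix row
    features.tsv      one gene symbol per matrix column
    tissue_positions.csv | .parquet
                      per-bin table: barcode, in_tissue, array_row,
                      array_col, pxl_row_in_fullres, pxl_col_in_fullres

Bin identifiers follow the 10x-style ``s_002um_{row:05d}_{col:05d}-1``
pattern with a plain ``{row}_{col}`` fallback; the parser is pluggable for
other dialects.  Physical coordinates are derived from the array indices
times the bin size unless pixel coordinates plus a µm-per-pixel scale are
supplied.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from scipy.io import mmread, mmwrite
from shapely.geometry import Polygon, mapping, shape
from skimage.measure import label as _cc_label

import anndata as ad

from .annotation import CellAnnotation
from .assignment import CellByGeneMatrix
from .errors import ConsistencyError, DataError, FormatError
from .geometry import BinGrid, CellOutline, format_bin_id

logger = logging.getLogger(__name__)

_TENX_BARCODE = re.compile(r"^s_(\d{3})um_(\d{5})_(\d{5})(-\d+)?$")
_PLAIN_BARCODE = re.compile(r"^(\d+)_(\d+)$")


def parse_barcode(barcode: str) -> tuple[int, int]:
    """Grid (row, col) encoded in a bin barcode.

    Accepts the 10x ``s_002um_00012_00034-1`` dialect and a plain
    ``12_34`` fallback.
    """
    m = _TENX_BARCODE.match(barcode)
    if m:
        return int(m.group(2)), int(m.group(3))
    m = _PLAIN_BARCODE.match(barcode)
    if m:
        return int(m.group(1)), int(m.group(2))
    raise FormatError(f"cannot parse grid position from barcode {barcode!r}")


def _find(dir: Path, stems: list[str]) -> Path:
    for stem in stems:
        p = dir / stem
        if p.exists():
            return p
    raise FormatError(
        f"missing file in {dir}: expected one of {stems}"
    )


_POSITION_COLUMNS = {
    "pxl_row": ("pxl_row_in_fullres", "pxl_row"),
    "pxl_col": ("pxl_col_in_fullres", "pxl_col"),
}


def read_positions(path: Path) -> pd.DataFrame:
    """Bin-position table from CSV or Parquet.

    Requires columns barcode, array_row, array_col; in_tissue and pixel
    coordinates are optional.
    """
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    required = {"barcode", "array_row", "array_col"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path.name}: positions need columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    for canon, options in _POSITION_COLUMNS.items():
        for opt in options:
            if opt in df.columns:
                df[canon] = df[opt]
                break
    return df


def read_visium_hd_counts(
    dir: str | Path,
    bin_size: float = 2.0,
    microns_per_pixel: float | None = None,
    barcode_parser: Callable[[str], tuple[int, int]] = parse_barcode,
) -> BinGrid:
    """Read an MTX + barcodes + features + positions directory as a BinGrid.

    The returned grid is canonicalized to row-major bin order and its total
    count equals the MTX sum.  When ``microns_per_pixel`` is given and pixel
    coordinates are present, the lattice origin is estimated from the pixel
    frame; otherwise physical coordinates are array indices times bin size.
    """
    dir = Path(dir)
    matrix_path = _find(dir, ["matrix.mtx"])
    barcodes_path = _find(dir, ["barcodes.tsv", "barcodes.txt"])
    features_path = _find(dir, ["features.tsv", "features.txt", "genes.tsv"])
    positions_path = _find(
        dir, ["tissue_positions.csv", "tissue_positions.parquet", "positions.csv"]
    )

    counts = sp.csr_matrix(mmread(matrix_path))
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).to_numpy()
    features_df = pd.read_csv(features_path, header=None, sep="\t")
    features = features_df[features_df.columns[0]].astype(str).to_numpy()
    if counts.shape[0] != len(barcodes):
        raise ConsistencyError(
            f"matrix has {counts.shape[0]} rows but {len(barcodes)} barcodes"
        )
    if counts.shape[1] != len(features):
        raise ConsistencyError(
            f"matrix has {counts.shape[1]} columns but {len(features)} features"
        )
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{matrix_path.name}: negative counts")

    pos = read_positions(positions_path)
    dup = pos["barcode"][pos["barcode"].duplicated()]
    if len(dup):
        raise ConsistencyError(
            f"barcodes duplicated in positions: {sorted(set(dup))[:5]}"
        )
    pos = pos.set_index("barcode")
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} barcodes absent from positions, e.g. {missing[:5]}"
        )
    pos = pos.loc[barcodes]
    rows = pos["array_row"].to_numpy(dtype=np.int64)
    cols = pos["array_col"].to_numpy(dtype=np.int64)

    origin = (0.0, 0.0)
    if microns_per_pixel is not None and "pxl_col" in pos.columns:
        ox = np.median(pos["pxl_col"].to_numpy() * microns_per_pixel - cols * bin_size)
        oy = np.median(pos["pxl_row"].to_numpy() * microns_per_pixel - rows * bin_size)
        origin = (float(ox), float(oy))

    grid = BinGrid(
        counts=counts,
        gene_names=features,
        bin_ids=barcodes,
        rows=rows,
        cols=cols,
        origin=origin,
        bin_size=bin_size,
    )
    return grid.canonicalized()


def write_visium_hd_counts(grid: BinGrid, dir: str | Path) -> None:
    """Write a BinGrid back to the MTX + TSV + positions layout."""
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    counts = grid.counts
    if np.allclose(counts.data, np.round(counts.data)):
        counts = counts.astype(np.int64)
    mmwrite(dir / "matrix.mtx", sp.coo_matrix(counts))
    pd.Series(grid.bin_ids).to_csv(dir / "barcodes.tsv", index=False, header=False)
    pd.Series(grid.gene_names).to_csv(dir / "features.tsv", index=False, header=False)
    s = grid.bin_size
    pd.DataFrame(
        {
            "barcode": grid.bin_ids,
            "in_tissue": 1,
            "array_row": grid.rows,
            "array_col": grid.cols,
            "pxl_row_in_fullres": grid.origin[1] + grid.rows * s,
            "pxl_col_in_fullres": grid.origin[0] + grid.cols * s,
        }
    ).to_csv(dir / "tissue_positions.csv", index=False)


# ---------------------------------------------------------------------------
# cell outlines
# ---------------------------------------------------------------------------


def read_cell_polygons(path: str | Path) -> list[CellOutline]:
    """Cell outlines from a GeoJSON FeatureCollection (coordinates in µm).

    Each feature must carry a unique ``id`` (feature id or an ``id`` /
    ``cell_id`` property).  Invalid polygons are repaired with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"outline file not found: {path}")
    data = json.loads(path.read_text())
    feats = data.get("features")
    if data.get("type") != "FeatureCollection" or feats is None:
        raise FormatError(f"{path.name}: not a GeoJSON FeatureCollection")
    outlines: list[CellOutline] = []
    seen: set = set()
    dupes: set = set()
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        cid = feat.get("id", props.get("id", props.get("cell_id", i)))
        if cid in seen:
            dupes.add(cid)
        seen.add(cid)
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            raise FormatError(
                f"{path.name}: feature {cid!r} is {geom.geom_type}, not Polygon"
            )
        outlines.append(CellOutline(cell_id=cid, polygon=geom))
    if dupes:
        raise ConsistencyError(
            f"{path.name}: duplicate cell ids {sorted(map(str, dupes))[:5]}"
        )
    return outlines


def write_cell_polygons(cells: list[CellOutline], path: str | Path) -> None:
    """Write outlines as a GeoJSON FeatureCollection."""
    feats = [
        {
            "type": "Feature",
            "id": c.cell_id,
            "properties": {"id": c.cell_id},
            "geometry": mapping(c.polygon),
        }
        for c in cells
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def mask_to_polygons(labels: np.ndarray, pixel_size: float = 1.0) -> list[CellOutline]:
    """Convert an integer label mask to per-cell polygons.

    Pixel (i, j) is treated as the square [j, j+1) x [i, i+1) in pixel units
    before scaling by ``pixel_size``, so a label's polygon area equals its
    pixel count times ``pixel_size**2`` exactly.  If a label's pixels are
    disconnected, the largest connected component is kept with a warning.
    An all-zero mask yields an empty list.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise DataError(f"label mask must be 2-D, got shape {labels.shape}")
    if labels.size and labels.min() < 0:
        raise DataError("label mask has negative labels")
    if pixel_size <= 0:
        raise DataError(f"pixel_size must be positive, got {pixel_size}")
    outlines: list[CellOutline] = []
    for k in np.unique(labels):
        if k == 0:
            continue
        mask = labels == k
        comps, n_comps = _cc_label(mask, connectivity=1, return_num=True)
        if n_comps > 1:
            sizes = np.bincount(comps.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            logger.warning(
                "label %s: %d disconnected components, keeping largest", k, n_comps
            )
            mask = comps == keep
        ii, jj = np.nonzero(mask)
        boxes = shapely.box(
            jj * pixel_size,
            ii * pixel_size,
            (jj + 1) * pixel_size,
            (ii + 1) * pixel_size,
        )
        poly = shapely.union_all(boxes)
        if poly.geom_type == "MultiPolygon":  # diagonal-only contact
            poly = max(poly.geoms, key=lambda g: g.area)
        outlines.append(CellOutline(cell_id=int(k), polygon=poly))
    return outlines


# ---------------------------------------------------------------------------
# cell-by-gene containers
# ---------------------------------------------------------------------------


def to_anndata(m: CellByGeneMatrix, annotation: CellAnnotation | None = None):
    """Wrap a cell-by-gene matrix in an AnnData container.

    Cells are observations, genes are variables, centroids live in
    ``obsm['spatial']`` and the assignment strategy in ``uns``.
    """
    obs = pd.DataFrame(index=pd.Index([str(c) for c in m.cell_ids], name="cell_id"))
    if m.n_bins is not None:
        obs["n_bins"] = m.n_bins
    if m.cell_types is not None:
        obs["cell_type"] = m.cell_types
    if annotation is not None:
        obs["cell_type"] = annotation.labels
        obs["annotation_confidence"] = annotation.confidence
    var = pd.DataFrame(index=pd.Index([str(g) for g in m.gene_names], name="gene"))
    adata = ad.AnnData(X=sp.csr_matrix(m.values), obs=obs, var=var)
    if m.centroids is not None:
        adata.obsm["spatial"] = np.asarray(m.centroids, dtype=float)
    adata.uns["assignment_strategy"] = m.strategy
    return adata


def write_cell_matrix(
    m: CellByGeneMatrix,
    path: str | Path,
    annotation: CellAnnotation | None = None,
) -> None:
    """Write the matrix as H5AD; a read-back recovers values exactly."""
    to_anndata(m, annotation).write_h5ad(Path(path))


def read_cell_matrix(path: str | Path) -> CellByGeneMatrix:
    """Read an H5AD container written by :func:`write_cell_matrix`."""
    adata = ad.read_h5ad(Path(path))
    return CellByGeneMatrix(
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        gene_names=adata.var_names.to_numpy(dtype=object),
        values=sp.csr_matrix(adata.X),
        strategy=str(adata.uns.get("assignment_strategy", "unknown")),
        centroids=adata.obsm.get("spatial"),
        n_bins=adata.obs["n_bins"].to_numpy() if "n_bins" in adata.obs else None,
        cell_types=(
            adata.obs["cell_type"].to_numpy(dtype=object)
            if "cell_type" in adata.obs
            else None
        ),
    )


def export_visualization_table(
    m: CellByGeneMatrix,
    path: str | Path,
    annotation: CellAnnotation | None = None,
) -> None:
    """Flat CSV for viewers: one row per cell (id, x, y, cell_type, total)."""
    if annotation is not None:
        types = annotation.labels
    elif m.cell_types is not None:
        types = m.cell_types
    else:
        types = np.array(["NA"] * m.n_cells, dtype=object)
    if m.centroids is None:
        raise DataError("matrix has no centroids; cannot export coordinates")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    pd.DataFrame(
        {
            "id": m.cell_ids,
            "x": m.centroids[:, 0],
            "y": m.centroids[:, 1],
            "cell_type": types,
            "total_counts": totals,
        }
    ).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# transcript tables / synthetic dataset layout
# ---------------------------------------------------------------------------


def write_transcripts(gt, path: str | Path) -> None:
    """Transcript point table: x, y, gene, cell_id (-1 = extracellular)."""
    pd.DataFrame(
        {
            "x": gt.x,
            "y": gt.y,
            "gene": np.asarray(gt.gene_names)[gt.gene_index],
            "cell_id": gt.cell_of_origin,
        }
    ).to_csv(Path(path), index=False)


def read_ground_truth(
    transcripts_path: str | Path,
    cells_path: str | Path | None = None,
    nuclei_path: str | Path | None = None,
):
    """Load a transcript table (plus optional outlines) as ground truth.

    This is also the ingestion path for real imaging-platform exports
    (e.g. a Xenium transcript CSV with cell assignments): columns
    x, y, gene, cell_id with -1 (or empty) for extracellular points.
    """
    from .synthetic import NOISE_CELL, GroundTruthTranscripts

    df = pd.read_csv(transcripts_path)
    required = {"x", "y", "gene", "cell_id"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"transcript table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    genes = pd.Categorical(df["gene"].astype(str))
    cell_ids = df["cell_id"].fillna(NOISE_CELL).to_numpy()
    cells = read_cell_polygons(cells_path) if cells_path else []
    nuclei = read_cell_polygons(nuclei_path) if nuclei_path else []
    return GroundTruthTranscripts(
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        gene_index=genes.codes.astype(np.int64),
        cell_of_origin=cell_ids,
        cells=cells,
        nuclei=nuclei,
        cell_types=np.array([None] * len(cells), dtype=object),
        gene_names=np.asarray(genes.categories, dtype=object),
        type_markers={},
    )


def write_synthetic_dataset(ds, dir: str | Path) -> None:
    """Serialize a SyntheticDataset to the on-disk layouts.

    Writes the bin-counts directory, whole-cell and nucleus GeoJSON,
    transcript CSV, marker CSV, per-cell type CSV and a JSON config echo.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    write_visium_hd_counts(ds.grid, dir / "binned")
    write_cell_polygons(ds.truth.cells, dir / "cells.geojson")
    write_cell_polygons(ds.truth.nuclei, dir / "nuclei.geojson")
    write_transcripts(ds.truth, dir / "transcripts.csv")
    ds.truth.marker_set().to_file(dir / "markers.csv")
    pd.DataFrame(
        {"cell_id": ds.truth.cell_ids, "cell_type": ds.truth.cell_types}
    ).to_csv(dir / "cell_types.csv", index=False)
    (dir / "config.json").write_text(json.dumps(asdict(ds.config), indent=1))
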