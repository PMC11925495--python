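"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
import shapely
from shapely.geometry import Polygon

from hdassign.geometry import BinGrid, CellOutline, build_bin_polygons, format_bin_id


def grid_from_array(arr, origin=(0.0, 0.0), bin_size=2.0) -> BinGrid:
    """BinGrid from a dense (n_rows, n_cols, n_genes) count array."""
    arr = np.asarray(arr)
    R, C, G = arr.shape
    rr, cc = np.divmod(np.arange(R * C), C)
    return BinGrid(
        counts=sp.csr_matrix(arr.reshape(R * C, G)),
        gene_names=np.array([f"G{i:03d}" for i in range(G)], dtype=object),
        bin_ids=np.array([format_bin_id(r, c) for r, c in zip(rr, cc)], dtype=object),
        rows=rr,
        cols=cc,
        origin=origin,
        bin_size=bin_size,
    )


def square_cell(cell_id, x0, y0, side) -> CellOutline:
    return CellOutline(
        cell_id=cell_id,
        polygon=Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]),
    )


def brute_force_join(grid: BinGrid, cells) -> set:
    """All-pairs intersection oracle: {(bin_id, cell_id, rounded area)}."""
    bin_geoms = build_bin_polygons(grid)
    out = set()
    if not len(cells):
        return out
    cell_geoms = np.array([c.polygon for c in cells], dtype=object)
    nb, nc = len(bin_geoms), len(cell_geoms)
    bg = np.repeat(bin_geoms, nc)
    cg = np.tile(cell_geoms, nb)
    areas = shapely.area(shapely.intersection(bg, cg))
    for k in np.flatnonzero(areas > 1e-9):
        b, c = divmod(k, nc)
        out.add((grid.bin_ids[b], cells[c].cell_id, round(float(areas[k]), 9)))
    return out


def random_convex_cell(rng, cell_id, field, r_max=6.0) -> CellOutline:
    """Convex hull of random points in a disk — an arbitrary convex cell."""
    cx = rng.uniform(0, field[0])
    cy = rng.uniform(0, field[1])
    r = rng.uniform(1.0, r_max)
    n = rng.integers(5, 12)
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = r * np.sqrt(rng.uniform(0, 1, n))
    pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    hull = shapely.MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":  # degenerate draw; use a small box
        hull = shapely.box(cx, cy, cx + 1.0, cy + 1.0)
    return CellOutline(cell_id=cell_id, polygon=hull)


@pytest.fixture(scope="session")
def dense_dataset():
    """One mid-size dense tissue reused across tests (seed 11)."""
    from hdassign.synthetic import dense_preset, make_dataset

    return make_dataset(dense_preset(seed=11, n_cells=120, field_size=(120.0, 120.0)))


@pytest.fixture(scope="session")
def sparse_dataset():
    """One sparse tissue reused across tests (seed 11)."""
    from hdassign.synthetic import make_dataset, sparse_preset

    return make_dataset(sparse_preset(seed=11, n_cells=12, field_size=(360.0, 360.0)))
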