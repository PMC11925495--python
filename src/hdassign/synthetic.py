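"""Ground-truth tissue simulator and its degradation to a 2 µm bin grid.

The simulator emulates the two benchmark regimes used to stress bin-to-cell
assignment:

* **dense** — small, tightly packed cells (image-based-platform-like tissue
  of ~4–5 µm radius cells) whose outlines abut and interdigitate, so a
  substantial fraction (~1/4) of the cell-intersecting bins touch more than
  one cell.  This is the regime where the choice of imputation strategy
  matters.
* **sparse** — large, well-separated fibroblast-like cells (~16–26 µm
  radius, centers at least 2.5 x the maximum radius apart) where each cell
  covers hundreds of bins and almost no bin touches two cells.

Each cell draws a type; expression is a two-rate program (marker genes of
the cell's type at an elevated rate, every gene at a small baseline rate);
per-cell transcript totals are uniform in a configured range and individual
transcripts are placed uniformly inside the cell polygon.  Extracellular
noise transcripts are placed uniformly over the field with uniform random
genes.  Degradation to a Visium-HD-like observation simply tallies
transcript points into half-open 2 µm grid squares — exactly the geometry
module's bin convention, so the simulated grid and the simulated outlines
live in one coordinate frame with no registration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import scipy.sparse as sp
import shapely
from shapely import affinity
from shapely.geometry import Polygon

from .annotation import MarkerSet
from .assignment import CellByGeneMatrix
from .errors import ConfigError, DataError
from .geometry import BinGrid, CellOutline, format_bin_id

NOISE_CELL = -1  # true_cell_id of extracellular points


@dataclass
class TissueSimConfig:
    """Parameters of one simulated tissue.

    field_size
        (width, height) of the tissue in µm; the bin lattice covers it
        exactly.
    packing
        "dense": cell centers may be as close as
        ``spacing_factor * (r_i + r_j)`` so outlines abut and overlap;
        "sparse": centers at least ``2.5 * max radius`` apart so outlines
        are disjoint.  ``min_spacing`` overrides both when set.
    expression
        Marker genes of a cell's type fire at ``marker_rate``; every gene
        fires at ``baseline_rate``; a cell's transcript total is uniform in
        ``transcripts_per_cell`` and genes are multinomial in the rate
        vector.
    noise_fraction
        Fraction of all transcript points that are extracellular noise.
    nucleus_fraction
        Linear scale of the nucleus polygon relative to the whole cell.
    """

    field_size: tuple[float, float] = (160.0, 160.0)
    n_cells: int = 220
    cell_radius: tuple[float, float] = (3.5, 5.5)
    packing: Literal["dense", "sparse"] = "dense"
    spacing_factor: float = 0.70
    min_spacing: float | None = None
    n_genes: int = 60
    n_cell_types: int = 4
    n_markers_per_type: int = 8
    marker_rate: float = 6.0
    baseline_rate: float = 0.25
    transcripts_per_cell: tuple[int, int] = (150, 300)
    noise_fraction: float = 0.05
    nucleus_fraction: float = 0.6
    bin_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size) <= 0 or self.bin_size <= 0:
            raise ConfigError("field_size and bin_size must be positive")
        if not (0 <= self.noise_fraction < 1):
            raise ConfigError("noise_fraction must be in [0, 1)")
        if not (0 < self.nucleus_fraction <= 1):
            raise ConfigError("nucleus_fraction must be in (0, 1]")
        if self.cell_radius[0] <= 0 or self.cell_radius[1] < self.cell_radius[0]:
            raise ConfigError("cell_radius must be an increasing positive range")
        if 2 * self.cell_radius[1] > min(self.field_size):
            raise ConfigError("cell radius exceeds the field")
        if self.n_cell_types * self.n_markers_per_type > self.n_genes:
            raise ConfigError("not enough genes for disjoint marker programs")


def dense_preset(seed: int = 0, **overrides) -> TissueSimConfig:
    """Tightly packed small-cell tissue; ~1/4 of overlapping bins shared."""
    return TissueSimConfig(seed=seed, **overrides)


def sparse_preset(seed: int = 0, **overrides) -> TissueSimConfig:
    """Large well-separated cells, each covering hundreds of bins."""
    defaults = dict(
        field_size=(560.0, 560.0),
        n_cells=30,
        cell_radius=(16.0, 26.0),
        packing="sparse",
        transcripts_per_cell=(300, 600),
        noise_fraction=0.03,
    )
    defaults.update(overrides)
    return TissueSimConfig(seed=seed, **defaults)


@dataclass
class GroundTruthTranscripts:
    """Simulated transcript points with their true cell of origin."""

    x: np.ndarray
    y: np.ndarray
    gene_index: np.ndarray
    cell_of_origin: np.ndarray  # NOISE_CELL for extracellular
    cells: list[CellOutline]
    nuclei: list[CellOutline]
    cell_types: np.ndarray  # type label per cell, aligned with `cells`
    gene_names: np.ndarray
    type_markers: dict[str, list[str]]

    @property
    def n_points(self) -> int:
        return len(self.x)

    @property
    def cell_ids(self) -> np.ndarray:
        """Cell universe: outline ids, or the ids seen in the point table
        when no outlines were supplied (transcript-table ingestion)."""
        if self.cells:
            return np.array([c.cell_id for c in self.cells], dtype=object)
        intra = self.cell_of_origin != NOISE_CELL
        return np.array(sorted(set(self.cell_of_origin[intra])), dtype=object)

    def marker_set(self) -> MarkerSet:
        return MarkerSet({t: list(g) for t, g in self.type_markers.items()})

    def cell_matrix(
        self, region: Literal["whole_cell", "nucleus"] = "whole_cell"
    ) -> CellByGeneMatrix:
        """True cell-by-gene tally of intracellular transcript points.

        In nucleus mode only points inside their own cell's nucleus polygon
        are tallied — the reference for nucleus-level evaluation.
        """
        ids = self.cell_ids
        pos = {cid: i for i, cid in enumerate(ids)}
        intra = self.cell_of_origin != NOISE_CELL
        px, py = self.x[intra], self.y[intra]
        genes = self.gene_index[intra]
        owners = self.cell_of_origin[intra]
        if region == "nucleus":
            if not self.nuclei:
                raise DataError("nucleus-mode truth requires nucleus outlines")
            keep = np.zeros(len(px), dtype=bool)
            for nuc in self.nuclei:
                mine = owners == nuc.cell_id
                if mine.any():
                    keep[mine] = shapely.contains_xy(nuc.polygon, px[mine], py[mine])
            px, py, genes, owners = px[keep], py[keep], genes[keep], owners[keep]
        elif region != "whole_cell":
            raise ConfigError(f"unknown region {region!r}")
        rows = np.array([pos[o] for o in owners], dtype=np.int64)
        values = sp.csr_matrix(
            (np.ones(len(rows)), (rows, genes)),
            shape=(len(ids), len(self.gene_names)),
        )
        if self.cells:
            centroids = np.array([c.centroid for c in self.cells], dtype=float)
            types = self.cell_types.copy() if len(self.cell_types) else None
        else:
            centroids = np.zeros((len(ids), 2))
            intra_all = self.cell_of_origin != NOISE_CELL
            for i, cid in enumerate(ids):
                mine = self.cell_of_origin[intra_all] == cid
                centroids[i] = (
                    self.x[intra_all][mine].mean(),
                    self.y[intra_all][mine].mean(),
                )
            types = None
        return CellByGeneMatrix(
            cell_ids=ids,
            gene_names=self.gene_names,
            values=values,
            strategy=f"ground_truth_{region}",
            centroids=centroids,
            cell_types=types,
        )


@dataclass
class SyntheticDataset:
    """A degraded observation paired with its generating ground truth."""

    grid: BinGrid
    truth: GroundTruthTranscripts
    config: TissueSimConfig

    @property
    def true_matrix(self) -> CellByGeneMatrix:
        return self.truth.cell_matrix("whole_cell")


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

_N_VERTICES = 28


def _cell_polygon(rng: np.random.Generator, cx: float, cy: float, r: float) -> Polygon:
    """Star-shaped cell outline: perturbed ellipse with radial noise."""
    theta = np.linspace(0, 2 * np.pi, _N_VERTICES, endpoint=False)
    u = rng.uniform(0.88, 1.14)  # axis ratio
    phi = rng.uniform(0, np.pi)
    # ellipse radius at angle theta - phi, axes (r*u, r/u)
    a, b = r * u, r / u
    t = theta - phi
    radial = a * b / np.sqrt((b * np.cos(t)) ** 2 + (a * np.sin(t)) ** 2)
    radial = radial * rng.uniform(0.92, 1.08, size=_N_VERTICES)
    xs = cx + radial * np.cos(theta)
    ys = cy + radial * np.sin(theta)
    return Polygon(np.column_stack([xs, ys]))


def _place_cells(
    rng: np.random.Generator, cfg: TissueSimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement honoring the regime's spacing rule."""
    w, h = cfg.field_size
    r_lo, r_hi = cfg.cell_radius
    centers = np.empty((0, 2))
    radii = np.empty(0)
    attempts = 0
    max_attempts = 2000 * cfg.n_cells
    while len(radii) < cfg.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise DataError(
                f"could not place {cfg.n_cells} cells in a "
                f"{w:.0f}x{h:.0f} µm field after {max_attempts} attempts; "
                "reduce n_cells or enlarge the field"
            )
        r = rng.uniform(r_lo, r_hi)
        # radial noise can reach ~1.24 r; keep outlines fully in-field
        margin = 1.25 * r
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if len(radii):
            d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
            if cfg.min_spacing is not None:
                limit = np.full(len(radii), cfg.min_spacing)
            elif cfg.packing == "sparse":
                limit = np.full(len(radii), 2.5 * r_hi)
            else:
                limit = cfg.spacing_factor * (radii + r)
            if (d < limit).any():
                continue
        centers = np.vstack([centers, [cx, cy]])
        radii = np.append(radii, r)
    return centers, radii


def _points_in_polygon(
    rng: np.random.Generator, poly: Polygon, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample inside a polygon by rejection from its bounding box."""
    if n == 0:
        return np.empty(0), np.empty(0)
    minx, miny, maxx, maxy = poly.bounds
    xs, ys = [], []
    remaining = n
    while remaining > 0:
        batch = max(64, int(remaining / max(poly.area / ((maxx - minx) * (maxy - miny)), 0.05)) + 8)
        px = rng.uniform(minx, maxx, size=batch)
        py = rng.uniform(miny, maxy, size=batch)
        inside = shapely.contains_xy(poly, px, py)
        take = min(int(inside.sum()), remaining)
        xs.append(px[inside][:take])
        ys.append(py[inside][:take])
        remaining -= take
    return np.concatenate(xs), np.concatenate(ys)


def simulate_tissue(cfg: TissueSimConfig) -> GroundTruthTranscripts:
    """Generate cells, nuclei, types and transcript points for one tissue."""
    rng = np.random.default_rng(cfg.seed)
    centers, radii = _place_cells(rng, cfg)

    gene_names = np.array([f"G{i:03d}" for i in range(cfg.n_genes)], dtype=object)
    type_names = [f"type_{t}" for t in range(cfg.n_cell_types)]
    type_markers = {
        type_names[t]: [
            gene_names[t * cfg.n_markers_per_type + k]
            for k in range(cfg.n_markers_per_type)
        ]
        for t in range(cfg.n_cell_types)
    }
    rates = np.full((cfg.n_cell_types, cfg.n_genes), cfg.baseline_rate)
    for t in range(cfg.n_cell_types):
        lo = t * cfg.n_markers_per_type
        rates[t, lo : lo + cfg.n_markers_per_type] = cfg.marker_rate
    probs = rates / rates.sum(axis=1, keepdims=True)

    cells: list[CellOutline] = []
    nuclei: list[CellOutline] = []
    cell_types = []
    xs, ys, genes, owners = [], [], [], []
    t_lo, t_hi = cfg.transcripts_per_cell
    for i in range(cfg.n_cells):
        cid = i + 1
        poly = _cell_polygon(rng, centers[i, 0], centers[i, 1], radii[i])
        cells.append(CellOutline(cell_id=cid, polygon=poly))
        nuc = affinity.scale(
            poly, xfact=cfg.nucleus_fraction, yfact=cfg.nucleus_fraction,
            origin="centroid",
        )
        nuclei.append(CellOutline(cell_id=cid, polygon=nuc))
        t = int(rng.integers(cfg.n_cell_types))
        cell_types.append(type_names[t])
        total = int(rng.integers(t_lo, t_hi + 1))
        g = rng.choice(cfg.n_genes, size=total, p=probs[t])
        px, py = _points_in_polygon(rng, poly, total)
        xs.append(px)
        ys.append(py)
        genes.append(g)
        owners.append(np.full(total, cid))

    n_intra = int(sum(len(a) for a in xs))
    f = cfg.noise_fraction
    n_noise = int(round(n_intra * f / (1 - f))) if f > 0 else 0
    if n_noise:
        xs.append(rng.uniform(0, cfg.field_size[0], size=n_noise))
        ys.append(rng.uniform(0, cfg.field_size[1], size=n_noise))
        genes.append(rng.integers(cfg.n_genes, size=n_noise))
        owners.append(np.full(n_noise, NOISE_CELL))

    return GroundTruthTranscripts(
        x=np.concatenate(xs) if xs else np.empty(0),
        y=np.concatenate(ys) if ys else np.empty(0),
        gene_index=np.concatenate(genes).astype(np.int64) if genes else np.empty(0, int),
        cell_of_origin=np.concatenate(owners).astype(np.int64) if owners else np.empty(0, int),
        cells=cells,
        nuclei=nuclei,
        cell_types=np.array(cell_types, dtype=object),
        gene_names=gene_names,
        type_markers=type_markers,
    )


def binify_transcripts(
    gt: GroundTruthTranscripts,
    bin_size: float = 2.0,
    field_size: tuple[float, float] | None = None,
) -> BinGrid:
    """Tally transcript points into half-open bin squares.

    Point (x, y) lands in bin (row, col) = (floor(y/s), floor(x/s)); points
    outside the field are dropped.  The returned grid contains *every*
    lattice bin covering the field, including empty ones, mirroring an
    in-tissue capture array.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive")
    if field_size is None:
        w = float(np.max(gt.x)) if gt.n_points else bin_size
        h = float(np.max(gt.y)) if gt.n_points else bin_size
    else:
        w, h = field_size
    n_cols = max(1, int(np.ceil(w / bin_size)))
    n_rows = max(1, int(np.ceil(h / bin_size)))
    n_genes = len(gt.gene_names)

    cols = np.floor(gt.x / bin_size).astype(np.int64)
    rows = np.floor(gt.y / bin_size).astype(np.int64)
    in_field = (cols >= 0) & (cols < n_cols) & (rows >= 0) & (rows < n_rows)
    flat = rows[in_field] * n_cols + cols[in_field]
    counts = sp.csr_matrix(
        (
            np.ones(int(in_field.sum())),
            (flat, gt.gene_index[in_field]),
        ),
        shape=(n_rows * n_cols, n_genes),
        dtype=np.int64,
    )
    rr, cc = np.divmod(np.arange(n_rows * n_cols, dtype=np.int64), n_cols)
    bin_ids = np.array(
        [format_bin_id(r, c, bin_size) for r, c in zip(rr, cc)], dtype=object
    )
    return BinGrid(
        counts=counts,
        gene_names=gt.gene_names,
        bin_ids=bin_ids,
        rows=rr,
        cols=cc,
        origin=(0.0, 0.0),
        bin_size=bin_size,
    )


def make_dataset(cfg: TissueSimConfig) -> SyntheticDataset:
    """Simulate a tissue and its degraded bin-grid observation."""
    truth = simulate_tissue(cfg)
    grid = binify_transcripts(truth, bin_size=cfg.bin_size, field_size=cfg.field_size)
    return SyntheticDataset(grid=grid, truth=truth, config=cfg)
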