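# Methods

## Problem setting

Sequencing-based spatial transcriptomics on a high-definition grid captures
transcripts in 2 × 2 µm bins — below cell size, but not aligned with cells.
Given a segmented cell outline for every cell in the tissue, each bin falls
into one of three classes: *orphan* (intersects no outline; discarded),
*unique* (intersects exactly one cell), or *shared* (intersects two or
more). Producing a single-cell expression matrix therefore requires a rule
for distributing each shared bin's counts among the cells it touches. This
package implements four such rules, a geometric core, a marker-score
annotator, a ground-truth simulator, and transcript-level evaluation.

## Geometry

Coordinates are in µm, image convention (origin upper-left, y downward).
Bin `(r, c)` is the half-open square `[c·s, (c+1)·s) × [r·s, (r+1)·s)`
offset by the lattice origin, with `s` the bin size (default 2 µm).
Half-open tiling makes the bin footprints a partition of the plane, so a
boundary point belongs to exactly one bin and adjacent bins never produce
spurious overlaps.

A bin *overlaps* a cell iff the polygon intersection has positive area;
edge/vertex contact does not count, and areas below 1e-9 µm² are treated as
zero to suppress repair slivers. The spatial join bulk-loads an STRtree on
the cell polygons and verifies every candidate pair with an exact
intersection, so its output is identical to the brute-force all-pairs join
(asserted in tests on hundreds of random instances).

Outline expansion (for nucleus-only segmentations) dilates polygons with
mitre joins, which keeps analytic oracles exact (a square grows to a
square); the default expansion is 0 (off) since the appropriate distance
depends on the segmentation being nuclear vs whole-cell. Expanded outlines
may overlap; no clipping is performed — the weighted strategies already
arbitrate shared territory.

Label masks are converted to polygons by treating pixel `(i, j)` as the
square `[j, j+1) × [i, i+1)` and unioning the squares, so polygon area
equals pixel count × pixel-size² exactly (verified against a pixel-count
oracle); a disconnected label keeps its largest component with a warning.

## Imputation strategies

Let `x_b` be bin `b`'s count vector and `C(b)` its candidate cells.

* **naive** — unique bins are summed into their cell; shared bins are
  dropped. Since a transcript can only occupy a bin that intersects its
  cell of origin, a unique bin carries only its own cell's transcripts plus
  ambient noise: precision is maximal, recall falls with the shared-bin
  fraction.
* **weight_by_area** — shared bin `b` is split with weights
  `w(c|b) = area(b ∩ c) / Σ_{c'∈C(b)} area(b ∩ c')`.
* **weight_by_gene** — two passes. Pass 1 builds each cell's reference
  profile `p_c` from its unique bins (the naive matrix). Pass 2 splits each
  shared bin per gene: `w(c|b,g) ∝ p_c[g] + α` normalized over `C(b)`,
  with pseudocount `α` (default 1.0, avoiding degenerate all-to-one splits
  for genes unseen in unique bins). If every candidate's smoothed mass for
  a gene is equal — including the all-zero case at `α = 0` — the gene falls
  back to area weights, since the profiles then carry no signal.
* **weight_by_cluster** — reference profiles are replaced by cluster means:
  naive profiles are normalized to counts-per-total, log1p-transformed,
  reduced by PCA (≤50 components) and k-means clustered with a fixed seed
  (deterministic; Leiden was deliberately avoided to keep the stage
  dependency-light and bit-reproducible). Candidates in the same cluster
  have tied means and split the gene equally — this is the intended tie
  semantics here, unlike the gene strategy, because tied *cluster* means
  are an informative statement that the candidates are the same kind of
  cell, not an absence of signal; the area fallback applies only when the
  weights are undefined (all smoothed masses zero).

Per-bin (area) and per-bin-per-gene (gene/cluster) weights sum to 1 over
candidates, so every weighted strategy conserves the transcript mass of
bins with ≥1 overlap exactly; the naive total equals the unique-bin total.
With zero shared bins all four strategies coincide element-wise. Fractional
outputs are kept as reals by default; a deterministic largest-remainder
rounding is available for integer-only consumers. Exact weight ties split
equally with no index-order preference, and cells that end with zero
contributing bins are retained as all-zero rows (flagged) so the cell
universe survives into evaluation. No post-assignment normalization is
applied.

## Annotation

The built-in annotator is a transparent score scheme, not a re-implementation
of any external tool: counts-per-total normalization, log1p, per-gene
z-score across cells (population SD, ε = 1e-8 guard for constant genes),
type score = mean z of the type's markers, label = arg-max. Cells below
`min_counts` total transcripts (default 5 — per-cell totals on 2 µm grids
are low, so some floor is needed) or with an exact top-two tie are labeled
`Unknown`. A fine→coarse label map (e.g. Goblet → Epithelial) with a
default class supports comparison against pathologist-level labels;
`Unknown` is never remapped. External annotators can be substituted via the
H5AD hand-off: run the pipeline without markers, annotate the container,
and write labels into `obs`.

## Synthetic tissue

The generator produces the two regimes that bracket the difficulty of
bin-to-cell assignment:

| preset | cells | radius (µm) | field (µm) | packing | shared-bin fraction |
|--------|-------|-------------|------------|---------|---------------------|
| dense  | 220   | 3.5–5.5     | 160 × 160  | centers ≥ 0.70·(r_i+r_j) | ≈ 0.25 (median) |
| sparse | 30    | 16–26       | 560 × 560  | centers ≥ 2.5·r_max      | ≈ 0 |

Cells are placed by dart-throwing; shapes are star-shaped perturbed
ellipses (28 vertices, axis ratio 0.88–1.14, radial noise ±8%); the nucleus
is the cell scaled by 0.6 about its centroid. Each cell draws a type
uniformly from 4 types; each type owns a disjoint block of 8 marker genes
(of 60) firing at rate 6.0 vs baseline 0.25; a cell's transcript total is
uniform in 150–300 (dense) or 300–600 (sparse), genes multinomial in the
type's rate vector, and points uniform inside the polygon. Extracellular
noise (5% of points dense, 3% sparse) is uniform over the field with
uniform genes. The dense spacing factor 0.70 was chosen so the median
shared-bin fraction sits near one quarter, the regime where strategy choice
matters; the sparse spacing rule makes outlines strictly disjoint, so its
shared fraction is essentially zero and each cell covers roughly 230–580
bins. Binning is the same half-open floor rule as the geometry module, so
simulated outlines and the simulated grid share one coordinate frame with
no registration step.

What the simulator does *not* model: segmentation error (truth outlines are
the assignment outlines), spatial expression gradients, cell-cycle or
doublet effects, platform noise (optical crowding, diffusion), or realistic
gene-count distributions. Passing tests on this tissue therefore establish
the correctness and the qualitative regime behavior of the algorithms, not
their absolute accuracy on real tissue, where segmentation quality
dominates. Real imaging-platform exports (a transcript table with x, y,
gene, cell id) can be ingested through the same ground-truth type for
benchmarking on real data.

## Evaluation

Transcript-level truth is the per-(cell, gene) tally of simulated points
(whole-cell mode) or of points inside their own cell's nucleus (nucleus
mode). Predictions are scored by mass overlap: `TP = Σ min(pred, truth)`
per (cell, gene), `FP = Σ pred − TP`, `FN = Σ truth − TP` — the multiset
intersection, which reduces to per-molecule counting for integer matrices
and handles fractional predictions without per-molecule identity. Metrics
are globally pooled by default; a per-cell-averaged variant is available
behind a flag. All 0/0 ratios are 0. Annotation is scored as a multi-class
classifier over the union of label sets, with support-weighted averages.

## Numerical and design notes

* Determinism: one seed flows from the pipeline config into every
  stochastic component (simulation, k-means); repeated runs are
  byte-identical.
* Conservation is checked on every pipeline run against the active
  strategy's contract and recorded in the manifest; a violation aborts.
* A completed run (same config hash, outputs present) is skipped unless
  forced; this whole-run resume replaces finer per-stage caching, which is
  not worth its complexity at the problem sizes the package targets.
* Degenerate inputs: empty cell collections, all-zero masks, all-orphan
  grids and 0-cell matrices are all legal and produce empty (not error)
  results; packing infeasibility and cluster counts exceeding the nonzero
  cell count are hard errors with remediation hints.
* Problem sizes in the test and acceptance runs (≈6 400-bin dense fields
  over 10 seeds, ≈78 000-bin sparse fields over 3 seeds) were chosen as the
  smallest at which the regime statistics are stable across seeds.

## Known limitations

* The gene- and cluster-weighted strategies inherit any bias in the
  unique-bin profiles; cells with few unique bins contribute noisy
  references.
* The annotator is intentionally simple; it assumes roughly balanced
  populations (z-scores across cells) and marker programs that are
  expressed, not merely enriched.
* No statistical comparison between strategies (CIs, tests) is provided;
  the evaluation reports point metrics per seed.
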