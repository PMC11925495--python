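# hdassign

Bin-to-cell transcript assignment for high-definition spatial
transcriptomics.

Sequencing-based spatial platforms now capture transcripts on a continuous
lattice of 2 × 2 µm bins — finer than a cell, but not aligned with cells.
Turning that lattice into a single-cell expression matrix requires deciding
what to do with bins whose footprint intersects more than one segmented
cell. `hdassign` is a small pipeline for exactly that step, aimed at
computational biologists working with Visium HD-style data who already have
cell outlines (from StarDist or any other segmenter) and want per-cell
transcript estimates they can hand to standard single-cell tooling.

Given a bin-by-gene count matrix and cell outlines (GeoJSON polygons or a
label mask), the package:

1. represents bins and cells as polygons and runs an exact spatial join
   (an STRtree is used only as a candidate filter);
2. removes orphan bins and converts bin counts to a cell-by-gene matrix
   under one of four imputation strategies for shared bins —
   **naive** (drop shared bins; weights nothing, loses mass),
   **weight_by_area** (split by intersection area:
   w(c|b) = area(b∩c) / Σ_{c'} area(b∩c')),
   **weight_by_gene** (split per gene by each candidate's unique-bin
   expression profile, pseudocount-smoothed), and
   **weight_by_cluster** (like weight_by_gene but using k-means
   cluster-mean profiles);
3. optionally annotates cells by marker z-score and writes an H5AD
   container (plus a flat CSV for viewers).

A ground-truth tissue simulator and transcript-level precision/recall
evaluation are included, so every strategy can be benchmarked end to end
without any external data: truth is the per-(cell, gene) tally of simulated
transcript points, and predictions are scored by mass overlap
(TP = Σ min(pred, truth)).

## Worked example

Simulate a dense tissue (220 tightly packed cells of radius 3.5–5.5 µm in a
160 × 160 µm field), run the pipeline on it, and score the result:

```sh
hdassign simulate --preset dense --seed 1 --out demo/
cat > demo.yaml <<EOF
counts_dir: demo/binned
cells: demo/cells.geojson
markers: demo/markers.csv
truth_transcripts: demo/transcripts.csv
output_dir: demo/out
strategy: weight_by_area
seed: 1
EOF
hdassign run --config demo.yaml
```

The run prints its diagnostics (abridged):

```json
{
 "n_bins_read": 6400,
 "n_cells": 220,
 "n_bins_overlapping": 4546,
 "n_bins_shared": 1056,
 "shared_fraction": 0.2322921249450066,
 "n_bins_orphan_removed": 1854,
 "conservation": {"expected_total": 51862.0, "assigned_total": 51862.0, "pass": true},
 "assignment_metrics": {"precision": 0.897, "recall": 0.929, "f1": 0.913}
}
```

Read it as: of the 6 400 bins in the field, 4 546 intersect at least one
cell and 23.2% of those touch two or more cells — the regime where the
choice of strategy matters. Area weighting reassigned all eligible
transcript mass (the conservation check) and recovered the true per-cell
counts with F1 ≈ 0.91; on the same tissue the naive strategy scores higher
precision (≈ 0.97, unique bins carry almost no foreign transcripts) but
recall only ≈ 0.70, because the transcripts in shared bins are discarded.
On the sparse preset (large, well-separated cells, each covering hundreds
of bins) all four strategies are near-exact (precision ≥ 0.99, recall
≈ 1.0), so the naive strategy is the cheap, safe choice there.

The output `demo/out/cells.h5ad` is a standard AnnData container (cells ×
genes, centroids in `obsm["spatial"]`, labels in `obs["cell_type"]`) ready
for downstream spatial statistics; `demo/out/cells.csv` is a flat per-cell
table for viewers.

The same pipeline runs on real data: point `counts_dir` at a Space
Ranger-style 2 µm directory (`matrix.mtx`, `barcodes.tsv`, `features.tsv`,
`tissue_positions.csv` or `.parquet`) and `cells`/`mask` at your
segmentation. Nucleus-only segmentations can be dilated with
`expansion_um` before the join.

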