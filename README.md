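# spatialniche

Spatial-niche analysis for segmented multiplexed-imaging cell tables and
Visium-style spot matrices:

- **Neighborhoods** — per-cell k-nearest-neighbor windows (default k = 100,
  Euclidean pixel distance, per sample) summarized as cell-type proportion
  vectors.
- **Communities** — per-sample k-means over-clustering of the composition
  vectors (default K = 30), merging into spatial communities (manual map or
  automatic average-linkage agglomeration on centroid correlation distance,
  default 10 communities), and cell-type enrichment scores
  E(community, type) = p(type | community) / p(type), where 1 means no
  enrichment.
- **Spatial statistics** — shortest distance from query cells to each target
  cell type with pixel→µm calibration (default 2.65 px/µm), pooled distance
  summaries and densities, community composition percentages, and the
  tie-corrected Kruskal-Wallis test.
- **Signatures** — gene-module scoring with expression-bin-matched control
  genes (defaults: 24 bins, 100 controls per signature gene) on
  log1p-CP10K-normalized counts, and the percentage of signature-high spots
  (top 10th percentile by default) per spatial cluster.
- **Synthetic tissue** — Poisson-placed cells in planted regions (disk /
  annulus / band / background geometry with override order, Dirichlet type
  mixtures) and negative-binomial spot counts with a planted signature
  uplift, providing ground truth for recovery tests.

## CLI

Every subcommand accepts `--config FILE` (INI, `key = value` sections),
`--seed N` (overrides all stage seeds), and `--out DIR`, and writes a
`manifest.ini` reproducing its configuration.

```sh
# plant the five-region preset (or --preset null) and write cells.csv + truth.csv
spatialniche simulate --preset bcc --seed 1 --out out/sim --with-spots

# composition vectors (k defaults to 100)
spatialniche neighborhoods --cells out/sim/cells.csv --seed 1 --out out/nb

# micro-cluster (K=30), auto-merge (default 10 communities; or --merge-map FILE),
# write per-cell assignment and per-sample enrichment matrices
spatialniche communities --cells out/sim/cells.csv \
    --compositions out/nb/compositions.csv --n-communities 5 --seed 1 --out out/comm

# nearest-type distances in px and µm (γ defaults to 2.65 px/µm)
spatialniche distances --cells out/sim/cells.csv --query-types BIT,BST \
    --targets Macrophage,Neutrophil --out out/dist

# module scores and per-cluster percentage of signature-high spots
spatialniche score --matrix out/sim/spots.mtx --genes out/sim/spots.genes.txt \
    --spots out/sim/spots.spots.csv --clusters out/sim/spots.clusters.csv \
    --signature signature.txt --seed 1 --out out/score

# composition summary + Kruskal-Wallis across communities
spatialniche report --cells out/sim/cells.csv \
    --assignment out/comm/assignment.csv --out out/report
```

## File formats

- Cell tables: headered CSV/TSV with configurable column names (defaults
  `sample_id, cell_id, x, y, cell_type`); coordinates in pixels, image
  convention (origin top-left).
- Spot matrices: MatrixMarket `.mtx` (genes × spots) or dense CSV, with a
  gene list (one symbol per line) and a `spot_id, x, y` sidecar; optional
  `spot_id, cluster` sidecar.
- Signatures: one gene symbol per line.

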