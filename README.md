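# lsgi — local spatial gradient inference for spatial transcriptomics

Tissues organize transcriptional phenotypes along spatial gradients: tumor
cores shade into their microenvironment, hypoxia decays away from necrotic
centers, developmental programs run along body axes.  `lsgi` finds such
gradients de novo in spatial transcriptomics data — where they are, which
direction they run, and how they relate to each other and to tumor/normal
tissue architecture — for analysts working with Visium-style spot data or
single-cell-resolution targeted panels.

## Method

Given N units (cells or spots) with coordinates and a non-negative N×K
feature matrix (NMF program loadings, or raw gene counts in single-gene
mode), the tissue is tiled with P = ⌊N/S⌋ grid points placed by balanced
spatial clustering (default S = 5); the window at each grid point is its
Q = 25 nearest units, so each unit sits in Q/S = 5 overlapping windows on
average.  In every window and for every feature j, ordinary least squares
fits

```
F_j ~ β_0 + β_x·x + β_y·y
```

R² scores how much of the feature's local variation position explains, and
the unit vector along (β_x, β_y) points toward increasing activity — the
local gradient direction.  Fits with R² ≥ 0.6 count as gradients, and a
feature is retained if it bears gradients in at least 5% of grid points.
Downstream, the package computes the asymmetric program-to-program distance
D(F_A, F_B) = mean over A's grid points of the distance to B's nearest grid
point, per-window tumor ratios with low/boundary/core clustering, founder-based
meta-program clustering of top-50-gene signatures across samples,
delta-Shannon compositional entropy, and hypergeometric gene-set annotation
with cross-program specificity.  A synthetic-scene generator with planted
gradients and coordinate-shuffled nulls calibrates the window size and R²
cutoff.  See `docs/methods.md` for the full account.

## Worked example

`examples/01_simulate_and_infer.py` simulates a 900-spot lattice where 100
of 500 genes carry planted expression gradients (negative-binomial counts,
mean 1, dispersion 0.5), aggregates genes into 5 gradated and 5 random
lists, scores list activity per cell, and runs gradient inference on the
scores:

```
scene: 900 spots × 500 genes (100 with planted gradients, 10 gene lists)
grid: 180 windows of 25 spots (each spot in ~5 windows)
fraction of windows called gradient (R² ≥ 0.3): 0.080 for gradated lists
  vs 0.023 for random lists — planted list-level gradients stand out
  against list-score noise
retained features (gradients in ≥5% of grids): ['gradated_01',
  'gradated_02', 'gradated_03', 'gradated_04', 'gradated_05']
```

All five planted lists are retained and none of the random ones: windows
covering the planted direction reach the R² cutoff in well over 5% of the
180 grid points, while spatially random lists only produce scattered chance
fits.  The other examples cover the asymmetric gradient distance
(`02_gradient_distances.py`), meta-program clustering with entropy and
annotation (`03_meta_programs.py`), and the window-size calibration against
shuffled nulls (`04_calibration.py`).

A thin CLI mirrors the library:

```
lsgi simulate --spec spec.yaml --out-dir scene/
lsgi run --coords scene/coords.tsv --features scene/counts.tsv \
         --mode genes --r2-cutoff 0.3 --out-dir results/
lsgi metaprog --signatures sigs.tsv --out mp.tsv
```

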