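# Methods

## The model

Spatial transcriptomics assigns each measured unit (a cell, or a multi-cell
spot) a 2-D position and an expression readout.  Many tissue processes —
tumor invasion fronts, hypoxia, developmental axes — manifest as *gradients*:
a transcriptional phenotype that increases smoothly along some direction over
a local stretch of tissue.  This package detects such gradients without any
prior on where they occur, which direction they run, or whether they are
monotone across the whole tissue.

The unit of analysis is an overlapping spatial window.  Given N units, the
tissue is partitioned into P = ⌊N/S⌋ equal-size spatial clusters (default
S = 5); each cluster's centroid becomes a *grid point*, and the window at a
grid point is its Q nearest units (default Q = 25).  Each unit therefore
falls in Q/S = 5 windows on average, so adjacent windows share members and
the inferred gradient field varies smoothly.

Within every window and for every feature j (an NMF program's cell loadings,
or a single gene's raw counts), ordinary least squares fits

    F_j = β_0 + β_x·x + β_y·y + ε

The unadjusted coefficient of determination R² measures how much of the
feature's local variation position explains; (β_x, β_y), normalized, is the
direction of increasing activity.  A window×feature fit with R² at or above a
cutoff counts as a gradient (default 0.6 — slightly more than half the local
signal explained by position), and a feature is *retained* only if it shows
gradients in at least max(1, ⌊0.05·P⌋) grid points, which suppresses
isolated one-window flukes.

### Parameters

| parameter | default | meaning |
|---|---|---|
| S | 5 | units per spatial cluster; P = ⌊N/S⌋ grid points |
| Q | 25 | window size (units per local regression) |
| r2_cutoff | 0.6 | minimum R² for a window×feature gradient call |
| min_grid_frac | 0.05 | fraction of grid points a feature must show gradients in |

Q controls resolution vs. robustness: small windows see fine structure but a
3-parameter regression on few points overfits noise — the calibration study
below quantifies this.  For sparse targeted panels (single-gene mode on raw
counts), Q = 20 with r2_cutoff = 0.3 is the recommended setting; counts are
deliberately not normalized before fitting.

Coordinates are used exactly as given — no centering or rescaling — so all
reported distances are Euclidean in the input units.

### Numerical choices

- Windows are solved by minimum-norm least squares (`numpy.linalg.lstsq`),
  vectorized over all K features per window.  A rank-deficient (collinear)
  window is fit on its identifiable 1-D subspace and reports that fit's R²;
  the direction then lies along the line of points.
- Constant-response windows are defined to have R² = 0 and zero slopes (not
  NaN), so filtering logic never meets missing values.
- Grid placement uses balanced k-means: k-means++ initialization, then
  capacity-constrained assignment (capacity ⌈N/P⌉, units claimed in globally
  ascending unit-to-centroid distance order) alternated with centroid
  updates until convergence, assignment cycling, or 50 iterations.  Only the
  centroids are consumed downstream; the role of the balancing is to make
  grid points tile the tissue at uniform density.
- k-nearest-neighbor window membership is computed from exact pairwise
  distances with ties broken by ascending unit index, so lattice data (where
  boundary ties are common) yields identical windows on every run and
  platform.  Q > N is capped at N with a warning.

## Downstream analyses

**Gradient proximity.**  The directed distance from gradient A to gradient B
is the mean, over grid points where A is retained, of the Euclidean distance
to B's nearest retained grid point.  It is deliberately asymmetric: a
confined gradient lying inside a tissue-wide one is close to it, not vice
versa.  Heatmaps display ln(d + ε) with ε = half the smallest nonzero
distance; the transform is plot-layer only.

**Tumor-ratio association.**  Given per-unit tumor/normal labels (supplied
as input from any aneuploidy caller), each window's tumor ratio is the
fraction of its members labeled tumor; a retained feature's score is the
unweighted mean over its gradient-bearing windows.  Features are grouped
into k = 3 tumor-ratio clusters (TRC) by exact 1-D k-means (dynamic
programming over the sorted values, optimal within-cluster sum of squares);
labels are ordered by cluster mean, so 1 ≈ normal tissue, 2 ≈ the
tumor–microenvironment boundary, 3 ≈ tumor core.  A 1-D k-means was chosen
for this step because it is deterministic, exactly optimal, and produces the
intended low/medium/high tranches.

**Meta-programs.**  Per-sample programs are summarized by their top-50 genes
by loading.  Clustering is founder-based: the founder is the program with
the most partners sharing >20 of 50 genes, requiring ≥2 partners; the
cluster then repeatedly absorbs the remaining program with the highest
overlap (≥20) to the current merged signature, re-deriving the 50-gene
signature after every merge, until nothing qualifies; the process repeats on
the remainder, and leftover programs form the "Unclustered" group.  The
merged signature ranks genes by (number of member programs carrying the
gene, descending; mean within-program loading rank, ascending; gene name) —
the count-then-mean-rank rule is this package's concrete choice for
combining "appearance in the top 50" with loading information.  All ties
break by ascending program id, making the procedure deterministic under
input reordering.

**Compositional entropy.**  Whether a meta-program draws from one tumor type
(or study) is scored by Shannon entropy of its member-category fractions,
H = −Σ p ln p (natural log; the maximum is ln C for C categories), compared
with the mean entropy under global permutations of category labels across
all programs (default 10 shuffles, seeded).  The reported delta is
shuffled_mean − real, so *larger delta = more category-specific*; a
`flip_sign` flag yields the opposite convention (real − shuffled), since
both orientations appear in the literature describing this quantity.

**Functional annotation.**  Gene-set enrichment of a signature is the
upper-tail hypergeometric probability of the observed overlap, BH-adjusted
across gene sets within each program (the standard scope of enrichment
tools), with E = −log₁₀(adjusted p) (base configurable).  The specificity
of set i for program p is E_ip minus the mean E of the same set over the
other programs.  A meta-program's annotation keeps the top 40 sets by
adjusted p, then the top 5 of those by specificity.

## The synthetic-data generator

Scenes emulate a count-level spatial simulation: spots on a regular square
lattice; 400 patterned + 2000 random genes by default; negative-binomial
counts with mean 1 and dispersion 0.5 (var = μ + φμ², the common
overdispersion convention — simulators differ here, so φ is explicit); no
dropout by default.  A patterned gene's mean varies linearly along a planted
unit direction, running from (1−slope)·μ clipped at zero to (1+slope)·μ;
the default slope of 2 plants a strong pattern — absent on one side, 3× the
baseline on the other — the kind of contrast hand-drawn simulator patterns
exhibit.  Shallower patterns at these count depths are statistically
invisible to any window size, which makes them useless for calibration.
Radial patterns (mean decaying with distance from a focus) are available via
`pattern_kind="radial"`.

Patterned genes are grouped into 30 gradated gene lists *sharing one planted
direction per list*, so a list's aggregate signal carries a coherent
gradient; 30 random lists are same-size draws from the unpatterned genes.
Per-cell list activity uses a rank-recovery surrogate score: the fraction of
the list found among the cell's top-5% expressed genes, normalized by its
maximum attainable value (ties in the count ranking are broken by a fixed
pseudorandom gene order so column order confers no advantage; zero-count
genes never count as top).  This is a deliberate, documented stand-in for
AUC-style pathway scoring, not a reimplementation of it.

All randomness flows from one seed through named `SeedSequence` children
(directions, counts, list draws, dropout), so equal specs reproduce
bit-identical scenes.

**Calibration.**  `shuffle_coordinates` permutes positions while leaving
the count matrix untouched — every per-gene marginal is exactly preserved,
all spatial signal is destroyed.  `calibration_sweep` fits all windows at
several Q on a scene and its shuffled twin and tabulates per-gene max-R²
quantiles and the fraction of fits above each cutoff.  On shuffled scenes
the fraction of fits with R² ≥ 0.4 is ~16% at Q = 10 but < 0.5% at Q = 25:
three-parameter fits on 10 points routinely reach moderate R² by chance,
while 25-point windows do not — the basis for the default Q and the
0.4–0.6 cutoff range.

**What the generator does not emulate.**  Real tissues have irregular spot
geometry, segmentation noise, cell-type mosaics, spatially correlated
library-size variation, and dropout; the lattice scenes have none of these.
Passing calibration here shows the windowed regression and its thresholds
behave correctly on idealized count data with known truth — it does not
certify performance on any real platform.

## Problem sizes used in the shipped checks

Tests and the acceptance script run desk-scale instances: grid identities on
1,000–1,237 units; OLS oracle comparisons on 100 random 25-point windows;
the shuffle-null calibration on a 2,000-spot scene with 250 genes; entropy
permutation oracles on 6-program pools; enrichment enumeration on 10-gene
universes.  These sizes make every check exactly or exhaustively verifiable;
the implementation itself is vectorized and handles the 10³–10⁴-unit,
10²–10³-feature scale of typical datasets in seconds.

## Known limitations

- Gradients are locally linear by construction; radial or curved structure
  is detected piecewise as windows of differing directions, not as a single
  object.
- R² filtering has no per-fit p-value; the calibration sweep is the
  error-control instrument.
- The balanced clustering is a heuristic (greedy capacity assignment), not
  an exact equal-size partition optimizer; only centroid placement matters
  downstream.
- Single-gene mode inherits count sparsity: at mean ≈ 1 per spot, per-gene
  windows carry little information and the lower cutoff (0.3) trades false
  positives for sensitivity.
- 3-D coordinates are not supported.
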