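# Methods

## Box-counting dimension

For a binary mask `M` and box side `ε`, `N(ε)` counts the cells of an
`ε`-pixel grid (anchored at the mask origin unless a grid offset is given)
that contain at least one foreground pixel; partial cells at the right and
bottom edges count as cells.  The dimension is the least-squares slope of
`log N(ε)` against `log(1/ε)` over a finite schedule of box sides.  On a
raster the `ε → 0` limit is unreachable, so the default schedule is dyadic
(`2, 4, …, side/2`); the smallest box is 2 px because at `ε = 1` the count
saturates at the pixel count and only adds noise to the slope.  A ternary
schedule (`3, 9, …, side/3`) is provided because exactly self-similar
base-3 fixtures (the Sierpinski carpet) give perfectly collinear log–log
points on it.  The schedule is always recorded with the estimate: `D_b` is a
schedule-dependent quantity.

Degenerate regressions (all counts equal, e.g. a single foreground pixel)
return `D_b = 0` with `R² = 1` — the constant model fits exactly — rather
than raising.

Two counting modes exist.  The default counts all foreground pixels of the
cleaned mask (area/mass box counting).  `margin_only` counts only the inner
morphological gradient (mask minus its erosion), for boundary-complexity
analyses.  The two modes answer different questions and give different
values on filled shapes (a filled disk is ~2 in area mode, ~1 in margin
mode).

### Numerical behaviour of the estimator

* Axis-aligned filled rectangles give `D_b = 2` and axis-aligned 1-px lines
  give `D_b = 1` to machine precision on dyadic schedules with aligned
  grids; the level-5 carpet gives `log 8 / log 3` exactly on the ternary
  schedule.
* Grid-offset sensitivity: on schedules that are *not* aligned with a
  fixture's self-similar lattice (the generic case), shifting the counting
  grid moves the carpet's estimate by well under 0.05.  On the ternary
  schedule the zero offset is special — it is exactly lattice-aligned — and
  offsets perturb the smallest scales by up to ~0.08.  Offset averaging is
  available but off by default.
* Thin diagonal structures (the Koch curve rasterized at 1-px stroke) are
  the hardest case: the level-6 curve on a 729-px canvas estimates within
  0.1 of `log 4 / log 3 ≈ 1.2619` on the ternary schedule, biased high by
  stroke thickness at the finest scale.

## Imaging pipeline

Photographs are ingested as 8-bit grayscale at 512×512 (luminance
conversion; bilinear resize without aspect preservation, applied *before*
binarization so thin structures are not aliased).  Binarization defaults to
Otsu's between-class-variance threshold — parameter-free and standard for
lesion masks — with a fixed-threshold mode for reproducibility experiments.
The lesion is assumed darker than the surrounding skin (`invert` flips
this).  Background elimination retains the largest 8-connected component
(ties break to the earliest component in row-major order, which is the
deterministic labelling order) and fills interior holes by default so that
area-style box counting is stable against specular highlights.  Hole
filling must be disabled when the object's interior holes *are* its
structure — the end-to-end validation on rendered Sierpinski-carpet
photographs runs with `fill_holes=False` for exactly this reason.

## Grouping and statistics

The twelve-diagnosis vocabulary is closed.  The benign/malignant mapping
places squamous cell carcinoma in the malignant group: that is the only
assignment under which the published per-diagnosis cohort sizes reproduce
the published malignant total (10,220), and integer arithmetic wins over
prose.  The Breslow-graded lesions belong to the melanoma group (again
required by the published total, 6035 = 5858 + 4 + 150 + 14 + 9); a config
override exists for the squamous-cell assignment.

Two-group comparisons use the two-sided Mann–Whitney U test; three or more
groups use Kruskal–Wallis followed by Dunn's rank-sum z comparisons (with
tie correction and Bonferroni adjustment) against a designated reference
group.  Dunn's test is implemented in-package as the standard mean-rank
z statistic.  Median confidence intervals use the distribution-free binomial
order-statistic method.

ROC curves sweep the sorted distinct FD values with a strictly-greater
classification rule.  The AUC is trapezoidal over the (FPR, TPR) polyline —
tied FPR points are ordered by TPR so tie plateaus are traversed diagonally,
which makes the trapezoidal area equal the Mann–Whitney identity
`AUC = U/(n₁·n₂)` exactly (the package computes both and tests assert
agreement to 1e-9).

The decision rule is two-stage and strict: malignant iff
`FD > t_malignant`, then (for malignant calls only) melanoma iff
`FD > t_melanoma = 1.755`, the published melanoma-group median used as the
published cutoff.  No benign/malignant cutoff was published, so
`t_malignant` defaults to 1.74 — the malignant-group median, mirroring the
same construction — and is a plain config value.  Stage-2 operating
characteristics are evaluated on the records stage 1 sent forward.

## Clustering

Features are `(dx_code, fd)` with `dx_code` the lexicographic-rank integer
code of the diagnosis (or of a coarser group label).  Because the two
columns live on incommensurate scales, the package standardizes both by
default; `scaling="none"` reproduces the raw-scale behaviour of the
original analysis, which encoded labels with integer codes and clustered
the raw values.  Silhouette values depend strongly on this choice (on the
default synthetic cohort: ≈ 0.63 standardized vs ≈ 0.91 raw for the
benign/malignant encoding at k = 2), so the scaling mode is always recorded.
The clustering-regime validation runs in the raw-scale mode, since that is
the regime of the published silhouette (≈ 0.79–0.89).

"Iterated" K-means is interpreted as 100 random restarts (greedy k-means++
seeding per restart, seeded RNG), keeping the lowest-inertia solution, with
Lloyd iterated to convergence (tol 1e-6, max 300 sweeps) inside each
restart — the common semantics of the tooling involved, and the stronger
guarantee.  Silhouette uses the Euclidean mean-silhouette coefficient.

Including an encoded *label* as a clustering feature leaks the
classification into the features; the cluster report and CLI flag this
prominently, and `fd_only` clusters on FD alone.  PCA always standardizes
its columns (correlation-structure decomposition) and rejects zero-variance
columns.

## Synthetic data

Fractal rasters: the carpet and triangle by digit arithmetic (exact pixel
counts `8^L` and `3^L`), the Koch curve by segment recursion rasterized at
1-px stroke on a `3^L`-px baseline, plus filled squares/disks, 1-px lines
and a smoothed-noise random blob.  Rendered "photographs" place foreground
and background intensities (defaults 30/220) under Gaussian noise; the
generator refuses configurations where the intensity gap is ≤ 4 noise SDs,
guaranteeing ≥ 99% pixel recovery after re-binarization.

Cohorts draw per-class FD values from normals truncated to (1, 2), centered
on the published per-class medians where those were printed: melanoma
classes 1.755, nevus (the bulk of the non-melanoma group) 1.651, atypical
melanocytic proliferation 1.636, Breslow 3 1.859.  The seven classes
without published medians were fixed once at plausible values consistent
with the published group medians (verrucous 1.64, vascular 1.63,
neurofibroma 1.65, squamous cell carcinoma 1.69, basal cell carcinoma 1.70,
Breslow 1 1.78, Breslow 2 1.82), chosen so the malignant-group mixture
median lands near the published 1.74.  The default spread (SD 0.08 for
every class) puts neighbouring classes in the heavily-overlapping regime in
which a single FD threshold attains high sensitivity at modest specificity.
The default cohort uses the twelve published class sizes scaled by 1/10
(tiny classes floored at 1 record) — 3,929 records, a desk-scale run.

What the synthetic cohort does *not* emulate: real dermoscopic image
content (hair, rulers, gel bubbles, illumination), the true per-class FD
distribution shape (only medians were published; normality and the common
SD are modelling choices), and inter-class correlation structure.  Passing
tests therefore validate the *computations* — counting, fitting, grouping
arithmetic, test statistics, the ROC identity, the clustering machinery —
and the qualitative regimes, not the archive-dependent headline numbers
(AUC 0.67, sensitivity ≈ 72%, silhouettes 0.58–0.89), which require the
original curated image cohort.

## Problem sizes

Validation runs use desk-scale inputs chosen to exercise every code path:
512×512 rasters for the imaging pipeline, the level-5 carpet (243×243) and
level-6 Koch curve (729-px baseline) for the estimator, 200 random 64×64
masks for the counting oracle, 100 seeded replicates of n = 200-per-group
null comparisons for type-I calibration, n = 2000 per class for the null
AUC, n = 5000 per class for median recovery, and 100 seeds of the
3,929-record default cohort for the clustering regime.
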