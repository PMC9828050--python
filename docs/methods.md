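# Methods

This note documents the models, conventions, and design choices behind
`arborclass`: what is computed, under which assumptions, and what the
bundled synthetic populations do and do not demonstrate.

## Arbor model and branch decomposition

A reconstruction is a forest of SWC tracing points. Analysis operates on
the **arbor**: all non-soma nodes. Two conventions anchor everything that
is measured "from the cell body":

- A soma traced with several type-1 points (a contour) is collapsed to a
  single reference point at its centroid; every non-soma child of any soma
  node starts a stem.
- A minority of curated reconstructions (glia especially) have no soma at
  all. These are legal: the first root node of each tree serves as the
  distance reference, and validation does not flag the missing soma.

A **branch** is a maximal unbranched path from a stem start or bifurcation
to the next bifurcation or termination. Branches partition the non-soma
segments exactly once, so the branch path lengths sum to the total cable
length (asserted to 1e-9 relative in the tests). A branch's **terminal
degree** is the number of tips in the subtree hanging from its end node;
terminal branches have terminal degree 1, internal branches > 1.

## The 19 morphometric features

Counts (stems, bifurcations, branches, fragmentation, maximum branch
order), extents (width, height, maximum Euclidean and path distance from
the reference point), cable quantities (total length, surface, volume,
mean diameter), and scale-free descriptors (mean branch contraction,
partition asymmetry, Rall's ratio `pk_classic`, local and remote
bifurcation amplitudes, fractal dimension). Soma surface and depth are
deliberately not computed: the former is not an arbor property and the
latter is unreliable perpendicular to the imaging plane in much published
data.

Numerical conventions, fixed for reproducibility:

- **Width/height** are the 97.5th minus 2.5th percentile of the literal X
  and Y coordinates, with linear interpolation between order statistics
  (the numpy default); no re-orientation of the cell is applied.
- **Surface/volume** model each segment as a truncated cone on the traced
  radii; zero radii give zero surface/volume with a logged warning.
- **Diameter** is the plain mean of 2·radius over non-soma tracing points
  (compartment-weighted).
- **Partition asymmetry** averages |n₁−n₂|/(n₁+n₂) over bifurcations,
  where n₁, n₂ are daughter-subtree termination counts. The denominator is
  deliberately n₁+n₂, not the (n₁+n₂−2) variant found elsewhere.
- **Fractal dimension** is the mean over branches (≥ 3 tracing points) of
  the regression slope of log₁₀ path distance on log₁₀ Euclidean distance
  of each point from the branch start; a perfectly straight branch gives
  exactly 1. The inverse orientation is a documented alternative some
  tools use; this package implements the path-on-Euclidean orientation.
- **Multifurcations** (k > 2 children) count as (k−1) bifurcations in the
  counts — so `n_branch` = bifurcations + terminations by definition —
  while angle, Rall and asymmetry terms use the first two children with a
  logged warning. Note that for such nodes `n_branch` exceeds the number
  of decomposed maximal unbranched paths (which is what ABEL's NB uses);
  the two coincide on binary trees, which is the overwhelmingly common
  case.
- Cells without bifurcations keep a rectangular feature row: the
  bifurcation-dependent features are set to 0 and listed in the vector's
  `missing` field rather than dropping the cell.

**Scale correction.** Files traced in pixels are fixed by a single
user-supplied multiplicative factor applied to the size features: width,
height, total length, total surface, total volume, maximum Euclidean
distance, maximum path distance. Applying a linear factor to surface (μm²)
and volume (μm³) is approximate — exact correction would need factor² and
factor³ — but matches how such per-archive corrections are applied to
published morphometric tables, so the literal list is kept and the
approximation documented here. Automatic pixel-vs-μm detection is out of
scope; factors come from the label table.

## ABEL

`ABEL = Σ (contraction × branch path length) / NB`, algebraically the mean
per-branch Euclidean length. The implementation computes the product form
and the tests verify the identity against the direct geometric route to
1e-12. ABEL is invariant under rigid motions and scales linearly with
coordinates.

Terminal and internal ABEL are the same mean restricted by terminal
degree. The terminal/internal ratio is undefined for single-branch-order
cells (no internal branches); such cells are flagged and excluded from
ratio summaries.

**Subsampled ABEL** mirrors estimating the biomarker from a handful of
branches instead of a full tracing: repeated sets of N branch lengths are
drawn without replacement (default 100 sets) and the mean and sd over set
means are reported. The estimator is unbiased for the full-arbor ABEL, and
its spread shrinks with N — both asserted as properties. When a cell has
fewer than the requested N branches the caller caps N at NB.

## Classifiers

**Threshold.** Candidates are the midpoints between adjacent sorted unique
values plus sentinels beyond the extremes; both polarities are scored
exhaustively and accuracy is computed from integer counts, so the result
is exactly the best achievable single cut (verified against an O(n²)
oracle). Ties go to the smallest threshold, then to the glia-below
polarity. A value exactly at the threshold is assigned to the side above
the cut. With identical class distributions the scan degenerates to an
extreme sentinel at accuracy 0.5, which is the honest answer.

**Linear boundary.** `A = slope·H + intercept` in the (height, ABEL)
plane, scored by training accuracy. The default optimizer is a
deterministic coarse-to-fine grid search (41×41 grid, 4 refinement
levels) over configurable bounds (default slope ∈ [−2, 2], intercept ∈
[−50, 200] μm — wide enough to contain any plausible boundary for both
real and synthetic scales); a seeded particle swarm is available as
`method="swarm"`. In both modes the best ABEL-only threshold is evaluated
as an explicit slope-0 candidate, so the boundary never reports lower
training accuracy than the univariate cut (nesting). Accuracy is piecewise
constant in (slope, intercept), so any optimizer only needs to land in the
optimal cell; the grid default is preferred precisely because it is
deterministic and testable.

**PCA + supervised learning.** Features are z-scored with the sample
(n−1) standard deviation, matching standard statistical-package behavior;
constant columns are dropped with a warning. PCA keeps the smallest k
components whose cumulative explained variance reaches the retention
threshold (default 0.95). Component signs are fixed by making each
component's largest-magnitude loading positive. The three classifiers —
KNN (K = 5, Euclidean), radial-kernel SVM, random forest (500 trees, 5
features per split) — run under repeated stratified k-fold CV (default 10
folds × 10 repeats; stratification guarantees both classes in every
training fold at small n). Neurons are the positive class for
sensitivity. AUC is computed on pooled test-fold scores by the rank
statistic (deterministic and threshold-free); the per-fold mean is also
reported for comparison.

## Synthetic populations

The generator grows rooted binary trees: a Bernoulli continue/terminate
draw per branch (capped by maximum branch order) sets the topology;
branch Euclidean lengths are lognormal; contractions are Beta; daughter
directions are symmetric about the parent direction at a Gaussian
amplitude; terminal branches are lengthened by a configurable factor r.
Tortuosity is injected by perpendicular sinusoidal-plus-noise displacement
of interior points with the amplitude solved numerically (Brent's method)
so the realized contraction equals the sampled value exactly — parameter
recovery is therefore exact per branch, not approximate.

Preset parameters (chosen once, as population-level contrasts a
morphologist would recognize from curated databases):

| parameter | neuron_like | glia_like |
|---|---|---|
| stems | 3–5 | 4–6 |
| bifurcation probability / max order | 0.6 / 5 | 0.75 / 6 |
| branch length lognormal | ln 32 μm, σ 0.45 | ln 6.3 μm, σ 0.40 |
| contraction Beta (mean) | 18, 2 (0.90) | 12, 3 (0.80) |
| terminal/internal ratio r | 2 | 1 |
| bifurcation amplitude | 40° ± 10° | 70° ± 15° |

These put the expected glia/neuron ABEL ratio near 0.13 (≈ 6.8 μm vs ≈ 54
μm), neuron terminal/internal ratio near 2 and glia near 1, and make glia
bushier (≈ 160 vs ≈ 40 branches per cell) with wider bifurcation angles —
the qualitative structure that separates the classes in real data.

**What the synthetic data does not emulate:** real reconstructions'
measurement noise, software-specific tracing artifacts, multifurcations,
axons, soma contours of realistic shape, metadata-correlated heterogeneity
(species, region, age), or the heavy overlap near the decision boundary
that produces the few-percent error rates seen on real repositories. The
presets are deliberately well separated, so classifier accuracies near
100% on synthetic populations demonstrate that the pipeline is correct and
deterministic — not that any particular accuracy would be attained on real
cells, and published real-data accuracies depend on the specific curated
dataset and cannot be reproduced from synthetic arbors.

## Problem sizes

The test suite and the acceptance script use 200 cells per class for
population-level checks (medians and means of per-cell statistics are
stable to a few percent at that size), 10-fold CV with 2 repeats, 100
subsample sets per estimate, and 60–200 seeds for estimator bias/spread
checks. These sizes are the package's own defaults for desk-scale
validation; all are configurable.

## Known limitations

- SWC dialects with headers encoding units or with non-standard columns
  are not auto-detected; only the 7-column format is parsed.
- Surface/volume scale correction is linear by design (see above).
- The fractal-dimension orientation and the partition-asymmetry
  denominator follow the literal definitions above; tools using the
  alternative conventions will differ on those two features.
- The six-class subtype problem (microglia/astrocyte/oligodendrocyte,
  principal/inter/sensory neuron) is not special-cased; `run_cv` accepts
  more than two label levels as a generic hook (accuracy only — the
  binary metrics come back NaN), but no subtype-specific analysis is
  provided.
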