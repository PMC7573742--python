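# Methods

## Scope and design

The package implements a two-level multivariate lesion-symptom mapping
pipeline — voxel-based (SVR-VLSM) and connectome-based (SVR-CLSM) — with
Monte-Carlo permutation inference, plus disconnectome construction from
lesion geometry, maximum-weight connected-subgraph extraction, and a
seed-node screening procedure. Real stroke cohorts of this kind cannot be
publicly archived, so the package pairs the analysis code with a seeded
synthetic-study generator and validates the pipeline by *properties*
(calibration, planted-effect recovery, closed-form oracles) rather than by
reproducing any particular published map. A 57-row behavioral table from
the motivating cohort ships as a fixture and anchors the behavior-level
statistics (tool-use/imitation r = 0.41; right/left grip r = 0.48 over the
41 complete pairs; demographic means).

## Behavioral preparation

Both analyses use OLS residual scores with an intercept: tool-use
hand-posture errors regressed on meaningless-imitation errors (and, for
the edge analysis, additionally on total lesion volume); right-hand grip
regressed on left-hand grip (grip trials are averaged per hand first).
Negative residuals mean worse-than-predicted primary performance, the tail
all thresholds address. Grip analyses use pairwise-complete rows only; no
imputation. A constant regressor is absorbed by the intercept (residuals
remain the centered outcome); mutually collinear regressors raise an error
naming an offender, because the fitted coefficients — though not the
residuals — would be arbitrary.

## The SVR engine

* **Model.** Epsilon-insensitive SVR; Gaussian kernel
  K(x,y) = exp(−‖x−y‖²/σ²) with kernel scale σ = 1 by default (the
  `fitrsvm` KernelScale convention), box constraint C = 1, epsilon tube
  0.1·sd(target). The target is standardized before fitting
  (configurable), which makes the epsilon default and the kernel scale
  comparable across analyses. C and epsilon defaults are package choices,
  exposed in `SvrConfig`.
* **Back-projection.** Feature weights are the linear sensitivity map
  w = Xᵀα over support vectors. For the linear kernel this is the primal
  weight vector; for the Gaussian kernel it is the convention of published
  SVR-LSM implementations, chosen for reproducibility and
  kernel-agnosticism rather than as an exact nonlinear gradient.
* **Cross-validation.** Subjects are partitioned into 5 seeded folds; each
  fold map is fitted on the complementary 80% and the final map is the
  mean of the five. Folds with fewer than two subjects are refused.
* **Permutation inference.** The (already residualized) behavioral vector
  is shuffled across subjects; nuisance regressions are *not* re-run
  inside the loop. The fold assignment is re-randomized per permutation so
  the null variance includes fold variance. Features are z-scored against
  the null mean and sample SD; features with zero null SD get z = 0 and a
  degenerate flag. Implementation note: the Gram matrix depends only on
  the features, which permutations never touch, so it is computed once and
  every fold/permutation fit runs on a precomputed-kernel slice; the
  fold-averaged map is recovered as Xᵀā from the averaged dual vector.
  This keeps 10,000-iteration runs tractable without changing the
  estimator.

## Voxel-level analysis

Voxels lesioned in at least 10% of subjects are included, with the count
threshold floor(0.10·n) (5 of 57, 4 of 41), clamped to at least 1.
Lesion-size leverage is removed by dTLVC: each subject's binary lesion
vector is scaled by 1/√(lesion volume), i.e. to unit Euclidean norm. The
scaling uses the subject's total lesion volume before column masking. The
z-map is thresholded strictly at z < −1.65 (one-tailed 5%), components are
formed under 26-connectivity (configurable: 6/18/26), and components below
the extent criterion are dropped. At full 1 mm³ resolution the criterion
is 500 contiguous voxels; for toy grids it is rescaled by grid volume
against a nominal 1.7·10⁶-voxel adult brain, with a floor of 5
(32³ → 10 voxels). Cluster peaks are the most negative z; centers of mass
are unweighted voxel-coordinate means. Surviving clusters are intersected
with the parcellation to produce per-(cluster, node) rows; this table also
defines the "localizer" region set passed to the edge analysis.

## Disconnectome and edge-level analysis

For node pair (i, j) and reference subject r, the loss is the path
probability mass inside the lesion over the pair's total path mass; the
pair value is the mean of per-reference losses (averaging over ratios, not
pooled probabilities — the alternative pooling is not implemented). Values
live in [0, 1] with zero diagonal; pairs with no reference connectivity
are flagged unconnected and excluded rather than imputed as zero-variance
columns. Edge matrices vectorize the upper triangle in fixed lexicographic
order, serialized in file headers. An edge counts as "lesioned" for the
10% rule when its disconnection is strictly positive (`--edge-min-disconnect`
exposes a floor for sensitivity checks). Before the SVR, edge columns are
residualized on three factors: cumulative disconnection of the localizer
regions (sum over unique edges touching the region set), total lesion
volume, and months post-stroke. The permutation z-matrix, strict −1.65
threshold and |z| edge weights follow the engine conventions.

The maximally disconnected subgraph is defined as the connected subgraph
of significant edges maximizing total |z|. Because all weights are
positive, any connected subgraph can be extended within its component
without losing weight, so the exact optimum is the full edge set of the
best-scoring component; the exact solver exploits this and is verified
against exhaustive enumeration. A greedy solver (expand from the heaviest
edge) is retained for very large graphs and differs only when the single
heaviest edge sits in a minor component. `auto` uses the exact solver up
to 15 nodes.

## Seed-node screening

Three sequential criteria filter remote nodes against a chosen seed node:
(1) less than 1% of the remote node's voxels are lesioned in any subject
(read as: fraction of node voxels with overlap count ≥ 1; a
subject-weighted variant is exposed as an option); (2) the seed-remote
residual disconnection column correlates negatively with the behavioral
residual at one-tailed p < 0.05 (at n = 57 the boundary is r = −0.2205,
hence the conventional "r < −0.22" phrasing); (3) the correlation lies
below z = −1.96 under a permutation null for that edge. The criteria form
a pure conjunction; all diagnostic rows are retained. The source
description of criterion 2 prints the inequality as "P > 0.05", which
contradicts the accompanying r bound at n = 57; it is treated as a
misprint and implemented as p < 0.05, noted in the report header.

## Synthetic studies

* **Parcellation.** Default 32³ grid, 12 nodes: centroids by
  farthest-point sampling, blobs grown by seeded round-robin
  face-connected accretion to ~90% fill. Blobs are connected by
  construction.
* **Reference atlas.** Per node pair and reference subject (default 20
  reference subjects at desk scale), the rasterized centroid-to-centroid
  line is bowed laterally by a sinusoidal displacement with Gaussian
  amplitude (sd 1 voxel) — a cartoon of between-subject tract
  variability. Visitation weights peak at the chain core and are
  normalized to 1.
* **Lesions.** One 26-connected blob per subject grown by random accretion
  inside a hemisphere-like territory (the low-x half of the grid).
  Volumes are drawn log-normally in mm³-equivalents (log-mean 10.694,
  log-SD 1.215, clipped to the observed 337–303,310 range) and mapped to
  voxels by the ratio of territory size to a nominal 600,000 mm³
  hemisphere; at 32³ the median lesion is ≈1,200 voxels.
* **Behavior.** Primary score = baseline − voxel-load effect − edge
  -disconnection effect − volume-severity effect − N(0, 0.08); control
  score analogous with a distinct shared region. The five planted roles
  (target, shared, motor, two edge endpoints) are assigned to the five
  largest in-territory nodes and are deliberately distinct: if the control
  score loaded on the target region itself, residualizing the primary on
  the control would cancel the planted voxel effect. The volume-severity
  channel (score decreasing in the lesioned grid fraction) is what makes
  the tool-use/imitation pair reliably positively correlated across
  geometries — bigger strokes impair both tasks, the same confound the
  real analyses remove by volume control; effect sizes (0.9 primary, 1.1
  control) were calibrated once so the mean correlation across seeded
  studies is ≈0.45, bracketing the observed 0.41. Grip scores share a
  per-subject latent strength factor (sd 7) plus a motor-region load
  effect; months post-stroke, age, education and gender are drawn
  independently to match the cohort's marginals (months is a nuisance
  covariate, not a modeled effect).

### What the generator does and does not emulate

It reproduces contiguous single-hemisphere lesions with heavy-tailed
volumes, spatially autocorrelated lesion coverage, volume-driven score
correlations, and disconnection that is a deterministic functional of
lesion geometry. It does not emulate vascular-territory lesion shapes,
right-hemisphere or interhemispheric disconnection, diffusion signal or
registration error, or item-level behavioral structure. Passing tests
therefore demonstrate that the machinery is calibrated and can recover
effects under the stated generative assumptions — not that any particular
anatomical claim about real cohorts is reproduced.

## Validation experiments

* **Calibration.** On 20 null cohorts (n = 57, no planted effects, 500
  permutations) the pooled fraction of features with z < −1.65 is ≈5% for
  voxels. The edge-level fraction runs slightly low (≈3–5%): the true
  statistic is computed between vectors that were both residualized
  against lesion volume, while permutation breaks that orthogonality and
  inflates the null SD — a mild, known conservatism of the
  shuffle-outside-the-nuisance scheme, which is implemented as specified.
* **Recovery.** Each channel is validated on noise-free single-channel
  cohorts, one fresh geometry per seed: a voxel-only planted effect must
  put the top VLSM cluster at Dice > 0.5 against the planted region, and
  an edge-only planted effect pushed through the full pipeline (localizer,
  nuisance regression, CLSM) must rank the planted edge among the three
  most negative z-scores, each in at least 16 of 20 seeds (measured: 16–17
  and 19 of 20). The channels are not mixed in one score: a voxel effect
  smears the z-map along the planted edge's path corridor, and an edge's
  disconnection can be nearly collinear with region load plus lesion
  volume, making a combined planting unidentifiable on some geometries —
  an identifiability limit of the design, not of the estimator. Recovery
  runs use 200 permutations; calibration uses 500; the full-scale default
  remains 10,000.
* **Oracles.** The exact subgraph solver is checked against exhaustive
  enumeration on random ≤6-node graphs; the disconnection formula against
  a hand-computed case (loss 0.7) at 1e-12 and against monotonicity under
  lesion dilation on 1,000 random lesions; OLS residualization against
  normal-equation solutions at 1e-9; and the screening procedure against a
  constructed borderline edge with sample r exactly −0.24 at n = 57, which
  passes the correlation screen (p ≈ 0.036) but fails the permutation
  criterion (z ≈ −1.8 > −1.96), the canonical near-miss pattern.

## Numerical choices and degenerate inputs

Strict inequalities at every threshold (z < −1.65, z < −1.96, r-screen
p < 0.05, disconnection > 0 for edge coverage). Coverage thresholds use
floor(fraction·n) clamped to ≥1. Permutation SDs use ddof = 1; zero-SD
features are flagged, not dropped silently. Cluster ties are ordered by
(peak z, size). Degenerate path endpoints (identical centroids) collapse
to a single voxel with probability 1. Empty lesion rows are an error in
dTLVC (the subject has no information in the matrix). All seeds are
threaded through `numpy.random.default_rng`; every pipeline stage is a
pure function of (data, config, seed), and output manifests record seeds
and a config hash sufficient to re-create every artifact byte-for-byte.

## Problem sizes

Desk-scale defaults — 32³ grid, 12 nodes, 57 subjects, 20 reference
subjects, 500-permutation calibration and 200-permutation recovery runs —
were chosen so the full validation suite completes in minutes on a single
CPU while leaving every statistical property measurable; the 10,000
-iteration default applies when the package is run on full-resolution
data.

## Known limitations

Back-projected Gaussian-kernel weights are a linear sensitivity
approximation; the cluster-extent rescaling for toy grids is a convenience
with no inferential guarantee; the edge permutation null is mildly
conservative (above); the greedy subgraph solver is not exact; and the
synthetic generator's simplifications listed above bound what the test
suite can say about real data.
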