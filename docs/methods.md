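# Methods

This note documents the models and procedures implemented in `scpredict`,
the assumptions behind the synthetic-data generator, the numerical choices,
and the design decisions taken where the problem left room for them. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Connectome construction

A structural connectome is built from three ingredients: a parcellation
label volume (integer labels 1..R on a voxel grid, 0 = background), a set
of streamlines (ordered voxel paths), and optionally scalar maps (FA, MD)
on the same grid.

- A streamline is assigned to the unordered region pair of its two endpoint
  voxels. Interior voxels never reassign a streamline; endpoint-only
  assignment is assumed.
- Streamlines with either endpoint in background are discarded (with a
  logged count). Streamlines beginning and ending in the same region would
  contribute only to the diagonal, which is defined as zero
  (self-connections removed).
- **NOS weighting**: entry (i, j) is the raw count of streamlines assigned
  to {i, j}. No normalization by region size is applied: with a common
  parcellation across subjects, every instance of a given edge feature is
  on the same scale, which is what matters for between-subject prediction.
- **FA/MD weighting**: per streamline, the mean of the scalar over the
  *distinct* voxels the path visits (a revisited voxel counts once — paths
  rarely revisit voxels in practice, but the rule must be fixed); per edge,
  the mean of those per-streamline means. Pairs with no streamline get 0,
  not a missing-value marker, because downstream code treats the SC as a
  dense feature matrix.
- Unordered pairs are pooled *before* counting/averaging, so symmetry holds
  by construction rather than by post-hoc symmetrization.

## Feature classes and normalization

Four feature classes map a subject's R×R connectome to a feature vector:

| class        | features                                   | selection cases          |
|--------------|--------------------------------------------|--------------------------|
| whole-brain  | upper triangle, R(R−1)/2 edges             | 1                        |
| corr         | k edges most correlated with the target    | k grid (19 cases)        |
| pca          | first k principal components               | k grid (19 cases)        |
| rcp          | one row of the SC (length R, self-entry 0) | R cases (one per region) |

The fixed k grid is {1, 2, 3, 4, 5, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90,
100, 150, 200} plus the region count R appended as the 19th case (when R
coincides with a fixed grid value the duplicate is evaluated once). Values
are capped at the available feature count; for PCA also at the smallest
inner-training-set size minus one (the PCA rank bound).

Order of operations, fit on training subjects only:

- NOS features are log10-transformed first (values > 0 only; zeros stay 0;
  log10(1) = 0 collides with untouched zeros, which on integer counts only
  merges the 0- and 1-streamline bins).
- Min–max normalization uses ONE global (train_min, train_max) pair over
  all entries of the training feature matrix — not per column. A
  per-feature variant exists behind a flag (`per_feature=True`), but the
  global pair is the default. Training values land in [0, 1]; test values
  outside the training range are *not* clipped (clipping would discard
  information; the transform is a pure affine map).
- For the PCA class the normalizer is fit on the full vectorized SC of the
  training set *before* the PCA is fit; for whole-brain/corr/rcp the
  features are extracted/selected first and the normalizer is fit on the
  selected training columns only.
- Edge ranking in the corr class uses *absolute* correlation (negatively
  correlated edges are equally informative for a linear model); a signed
  variant is available (`ranking="signed"`). Ties break by ascending edge
  index; constant edges get correlation 0 rather than an error.

Leakage-freedom is an enforced invariant: mutating test-set connectomes or
targets leaves every fitted transformer (min/max pair, selected edge
indices, PCA basis) bit-identical. The test suite checks this directly.

## Ridge regression and cross-validation

The model minimizes Σ_i (y_i − β'x_i − b)² + α‖β‖² with an unpenalized
intercept. Centering X and y by training means decouples b; β solves
(Xc'Xc + αI)β = Xc'yc and b = ȳ − x̄'β. Features receive no standardization
beyond the min–max normalization above — deliberately, since that is the
pipeline's only stated scaling. At α = 0 with collinear features the solve
raises, or returns the minimum-norm solution behind a documented flag
(`singular="lstsq"`).

Inside the inner loop the same closed form is evaluated for the whole α
grid from a single eigendecomposition (`ridge_predict_path`), using the
primal form (eigh of Xc'Xc) when features ≤ samples and the dual form
(eigh of XcXc') otherwise; the two coincide for α > 0 and the path is
tested to agree with the estimator to 1e−7.

Nested 5-fold cross-validation: the outer loop estimates out-of-sample
accuracy as the Pearson correlation between predicted and observed targets
per test fold, averaged over the 5 folds into a single prediction result.
The inner loop (5 folds of the outer-training subjects; the inner fold
count is assumed equal to the outer) evaluates every (feature case, α)
combination and picks the one maximizing mean inner-fold Pearson r — chosen
to match the outer metric; negative MSE is available via `scoring`.
Hyperparameter ties break toward larger α (the conservative choice), then
the smaller/earlier feature parameter. The α grid is
{0.001, 0.01, 1, 10, 50, 100, 500, 1000, 5000, 10000}.

Degenerate Pearson correlations (a constant vector, possible under extreme
shrinkage or after zeroing negative map voxels) are defined as 0 with a
degeneracy flag, so fold averages stay defined.

The procedure is repeated over independent random splits (100 by default).
Fold assignments are a pure function of (n_subjects, master seed): each
repeat draws its own child generator seeded by (master seed, repeat index),
so extending the number of repeats never perturbs earlier repeats, and two
pipelines run on the same subjects with the same master seed consume
identical folds. Folds are plain random partitions with sizes differing by
at most one; no stratification by target is applied. Subject groups of
different sizes (mixed/female/male) generate group-specific schemes from
the shared master seed.

The permutation baseline reuses the split scheme unchanged and shuffles the
target-to-subject assignment once per repeat (child seed per repeat), which
preserves the target's marginal distribution while destroying any real
association.

## Post-hoc vs. in-loop feature selection (the optimism audit)

For feature classes with multiple selection cases, two protocols are
compared on identical data and identical splits:

- **A (post-hoc)**: run one accuracy distribution per case, then keep the
  case with the largest repeat-mean. Because the case is chosen on the very
  test results being reported, this is an optimistic upper bound, and it is
  flagged as such in all outputs.
- **B (in-loop)**: the selection case is a hyperparameter optimized in the
  inner CV loop together with α.

The audit reports mean(A) − mean(B) with a percentile-bootstrap confidence
interval (2,000 resamples, seeded) over the 100 repeat-level paired
differences. On null data the gap is positive — the expected value of a
maximum over many noisy case means exceeds the typical case — while a
signal concentrated in a single RCP shrinks the gap, since both protocols
then agree on the informative case. This is the package's central
reproducible phenomenon, exercised in the acceptance tests.

## Prediction brain maps

For the RCP class, each region's repeat-mean accuracy is assigned to all
voxels of that region, giving a single-parcellation map; maps from several
parcellations of one grid are averaged voxelwise (unweighted; a voxel
covered by only some parcellations averages over the maps in which it is
assigned). Background voxels stay unassigned and are excluded from all
statistics. Maps are compared by Pearson correlation over assigned voxels,
optionally after setting negative values in *both* maps to zero (the
variant restricting the comparison to successfully predicting regions).
Volumes are kept volumetric (plain-text arrays or NIfTI); surface
projection is out of scope.

## Synthetic data generator

The generator emulates the statistical properties a real cohort presents
to this pipeline, not the physics that produced them:

- **Parcellation**: multi-source BFS growth from random seed voxels inside
  an ellipsoid "brain" mask — connected regions, every foreground voxel
  labelled. A stand-in for real atlases; real label volumes can be supplied
  as input instead.
- **Scalar maps**: FA ~ Beta(4,4) in [0,1]; MD a decreasing affine function
  of FA plus noise (physically, both derive from the same diffusion-tensor
  eigenvalues, hence the strong voxelwise anticorrelation).
- **Streamlines**: straight-line rasterized segments between random
  labelled voxels. Curvature is irrelevant to every computation in scope
  (endpoint assignment and per-voxel averaging), so none is simulated.
- **Connectomes**: log10(NOS) per edge = edge-level population mean
  (sd √0.7·σ) + subject deviation (sd √0.3·σ), rounded to integers — a
  rounded log-normal marginal, right-skewed, with weak edges dropping to 0.
  Default log10 mean 1.0, sd 0.8 (typical edges ~10 streamlines, range
  roughly 1–1000 — a realistic spread for cortical parcellations at desk
  scale). FA and MD edge weights share a latent factor with weight
  `fa_md_coupling` (default 0.95, matching the near-unity correlation
  between microstructural weightings observed in real connectomes); both
  carry edge-level structure so the population has principal components.
  Absent edges are 0 in all three weightings.
- **Cohort**: per trait, 12 Likert items in 0..4 with subject-level
  response probabilities Beta(4,4), summed after reversing a fixed,
  arbitrary reversal mask (items 2, 5, 8, 11 of each trait — the real
  inventory's keying is not public here, so one documented choice is
  fixed). Totals are integers in [0, 48]. Cognition is continuous,
  mean 100, sd 15. Balanced cohorts have exactly equal sex counts.
  Default sizes mirror a mixed group of 426 (213/213) and single-sex
  groups of 278, but every test and example sets its own desk-scale n.
- **Planted signal**: a random-weight linear combination of chosen
  upper-triangle edge values, standardized; the target is
  √r²·signal + √(1−r²)·noise. The signal is planted on the
  log10-transformed NOS edges — the same transform the pipeline applies —
  so `effect_r2` is interpretable as the linear ceiling of what the model
  can recover (accuracy ceiling √r²). Trait targets are mapped affinely
  (sample range onto [0, 48], which preserves correlations exactly) and
  rounded to integers, preserving the measurement granularity of the
  questionnaire scale; cognition stays continuous.

Every generator is a pure function of its arguments including the seed.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: realistic fiber geometry and tract topology, spatial
autocorrelation of microstructure along tracts, family structure or
heritability, confound structure (age, motion), non-linear brain–behavior
relationships, and test–retest unreliability of questionnaire scores.
Results on synthetic data validate the *machinery* (leakage-freedom,
calibration, selection-bias quantification, signal recovery), not any
neuroscientific claim.

## Calibration properties and problem sizes

With no planted signal the prediction-accuracy distribution is centered
near zero, but an individual dataset's repeat-mean carries a dataset-level
offset: with K features ≈ n subjects, the realized whole-sample feature–
target correlations are nonzero at the 1/√n scale, the training folds fit
them, and the test folds hold the complementary deviations. This offset
does not shrink with more splits (they reuse the same data). The null-
calibration check therefore pools the five exchangeable null trait targets
of one cohort, which shrinks the offset's standard error by √5 while
leaving the study conditions (n = 200, R = 20, NOS, whole-brain, 100
splits) unchanged. The permutation baseline does not have this issue: each
repeat re-rolls the target assignment, so its mean concentrates tightly
around zero.

Problem sizes used by the test suite and the acceptance script (chosen as
desk-scale study conditions): null calibration n = 200, R = 20, 100 splits;
planted-signal recovery n = 300, R = 10, effect_r2 ∈ {0, 0.1, 0.25, 0.5},
25 splits (100 for the permutation contrast); optimism audit n = 200,
R = 50 (50 RCP cases), 25 splits; cognition-vs-trait contrast n = 200,
R = 20, planted cognition R² = 0.2, 25 splits; map-family construction
n = 60, R = 5, 3 splits across all 45 (trait × weighting × group)
conditions.

## Known limitations

- The inner-loop grid search is exhaustive; for very large feature grids
  (fine parcellations' RCP classes) protocol B grows linearly in R.
- `best_of_selection` reports the nominal case list after deduplication;
  when R coincides with a fixed k-grid value the duplicate case is
  evaluated once.
- The CLI's sweep runner executes pipelines serially; large sweeps are
  expected to be driven programmatically.
- Pearson r is the only outer metric, matching the benchmarking design it
  implements; MSE/R² reporting would need a thin extension.
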