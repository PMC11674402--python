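# Methods

## Model and quantities

A cohort is N subjects, each with a p×p empirical FC matrix (eFC, a Pearson
correlation matrix: symmetric, unit diagonal, positive semidefinite), a
predicted FC matrix (pFC), and optionally a sparse nonnegative structural
connectome (SC).  Subjects carry cross-validation fold labels 1..K; every
fold-aware computation treats a subject's fold as their *test* fold and its
complement as the training set.

The cross-subject similarity matrix r has r_ij = s(pFC_i, eFC_j) under a
measure s.  Intra-individual similarity is r_intra(i) = r_ii; inter-individual
similarity is r_inter(i) = Σ_{j≠i} r_ij / (N−1) (or the within-fold analogue
on the fold's n×n submatrix).  Predictions are individual-specific when
r_intra systematically exceeds r_inter (is smaller, for distances).

### Similarity measures

*Pearson*: both matrices' strict upper triangles (length p(p−1)/2; the
diagonal is a constant and carries no information) are vectorized and
correlated.  A masked variant restricts the correlation to the nonzero
off-diagonal pattern of the prediction, the convention for comparing sparse
SC against dense eFC; it requires at least 3 selected entries.

*LERM*: d(A, B) = ||Log(A) − Log(B)||_F with Log the matrix logarithm,
computed by symmetric eigendecomposition.  Correlation matrices can be
numerically singular and predicted matrices need not be positive definite,
so inputs pass through an eigenvalue floor first: eigenvalues below
`floor × max(λ_max, 1)` are raised to that level (default floor 1e−6,
exposed as a parameter).  The affine-invariant metric is deliberately not
provided; its matrix inversions are prohibitive at realistic p and it adds
no tested capability here.

### Identifiability tests

*Naive t*: one-tailed one-sample t on d_i = r_intra(i) − r_inter(i)
(sign-flipped for distance measures), df = N−1; Cohen's d = mean(d)/sd(d).
The test treats the d_i as independent, which cross-validated predictions
violate.

*Fold-constrained permutation*: columns of r are permuted independently
within folds only, never across folds, so the null distribution preserves
between-fold dependence; the t statistic above serves as a pivotal quantity.
The p value uses the add-one estimator (1 + #{t_perm ≥ t_obs})/(1 + n_perm),
which cannot return 0, and is reported with a normal-approximation binomial
95% interval.

*Corrected resampled t* (model vs benchmark): per fold k, the n×n fold
submatrix yields δ(k) = r_intra(k) − r_inter(k); s_k = f(δ_model(k) −
δ_benchmark(k)) with f the median by default (the per-subject differences
are skewed; the mean is available).  t = mean(s)/sqrt((1/K + n_test/n_train)
σ̂²), df = K−1, where σ̂² is the unbiased variance of s_1..s_K.  The
(1/K + n_test/n_train) factor inflates the naive 1/K standard error for the
overlap between training sets of different folds.  Swapping model and
benchmark negates t exactly.

*Per-fold bootstrap*: the n paired differences in each fold are resampled
with replacement (default 10,000 draws); the 5th percentile of the bootstrap
f(·) distribution is a one-sided 95% lower bound, and a fold counts as
significant when that bound exceeds zero.  Percentile bounds are used rather
than BCa: at fold sizes of interest the difference is smaller than
Monte-Carlo noise, and percentile bounds are exactly reproducible under a
seed.

*Percent improvement* of the model over a reference is
(r_model − r_reference)/r_model × 100, conventionally applied to mean
intra-individual similarities.  Note this normalizes by the *model's* mean:
printed means of 0.547 (model) and 0.477 (noise benchmark) give ≈ 12.8%, not
the ≈ 9% a reader might expect from other normalizations; the formula is
implemented exactly as stated here.

*Differential identifiability* — mean(r_ii) − mean of all off-diagonal r_ij —
is provided as a descriptive convenience only, without a test: it is a
two-sample contrast whose independence assumptions cross-validated
predictions do not satisfy.

### Benchmarks and standardization

The *group-mean* benchmark substitutes each subject's prediction with the
elementwise mean eFC over the subject's training complement (diagonal set
to 1).  The *noisy-mean* benchmark adds zero-mean Gaussian noise per
upper-triangle element with the training-set elementwise standard deviation
(unbiased, n−1), mirrored to keep symmetry and left unclipped so the
matched-variance property is exact.  Both use no test-fold information:
perturbing any test subject's eFC leaves their fold's benchmark unchanged.

Fold-respecting z-scoring standardizes each off-diagonal element across
participants using training-complement moments; elements whose training sd
is below 1e−12 map to 0, as does the diagonal.  Each modality is z-scored
with its own moments (eFC with eFC moments, pFC with pFC moments); moments
from another stack can be supplied where a shared reference scale is wanted.

A structural note on benchmark behavior: the naive test applied to these
benchmarks is far more conservative than its nominal level.  Benchmark
similarity values vary almost entirely with the *reference* subject (column
effects), and column effects cancel exactly in mean(d) while inflating
sd(d_i); additionally r_inter averages over training subjects whose eFC sits
inside the benchmark mean, biasing the gap slightly negative, at order
1/n_train.  Both effects are inherent to training-mean benchmarks, and the
acceptance checks assert the absence of *anti*-conservatism (no spurious
individual effects, no leakage) rather than exact nominal calibration.

### Matching

The Hungarian algorithm (scipy's linear_sum_assignment) solves the optimal
one-to-one prediction-to-reference assignment on the negated similarity
matrix (distances are used as costs directly); the number of fixed points —
the trace of the binary assignment matrix — counts correct matches.  Chance
matching permutes similarity columns uniformly before solving; the expected
number of fixed points of a uniform random permutation is 1, so chance
accuracy is 100/n %.  The accuracy curve draws, for each subset size
n = 2..n_max (default 20), M subsets (default 2,500) without replacement
within a uniformly chosen fold — subsets never straddle folds — and compares
model and chance per-subset percent correct with an equal-variance two-sample
t test (df = 2M − 2), Benjamini–Hochberg-adjusted across subset sizes at an
FDR of 5%.  Matching accuracy is invariant to any strictly increasing
transform of the similarities; ties are resolved by the solver's
deterministic behavior on a fixed subject order.

## Synthetic cohorts

Each covariance component is a random factor model A·Aᵀ + I with factor rank
p//4 by default (realistic eigenvalue decay; exposed as `factor_rank`).  With
a group component Σ_G and per-subject individual components Σ_i:

- eFC_i = sample correlation of t draws from N(0, (1−α)Σ_G + αΣ_i);
- pFC_i = sample correlation of an independent set of draws with the
  individual part replaced by βΣ_i + (1−β)Σ̃_i, Σ̃_i a fresh nuisance
  component;
- SC_i scores edges by the subject's latent covariance plus Gaussian noise of
  scale `sc_noise`, keeps the top `sc_density` fraction of upper-triangle
  edges, and rank-transforms surviving weights to a normal shape (shifted
  positive), mirroring how streamline counts are conventionally resampled;
- folds are assigned in contiguous blocks of near-equal size.

Correlation matrices are realized through latent samples rather than by
perturbing a template, so symmetry, unit diagonal and positive
semidefiniteness hold structurally, and t_samples > p makes every matrix full
rank (LERM needs no more than negligible flooring).  β = 0 is the null
condition: predictions have realistic inter-individual variability but no
individual information.

Defaults: n_subjects = 100, n_nodes = 68 (a standard cortical parcellation),
t_samples = 300, α = 0.05, β = 0.75, sc_density = 0.35, sc_noise = 0.5,
K = 10.  α = 0.05 encodes the empirical regime in which individual
differences contribute on the order of a few percent of FC variance, with
the group organization dominating.  At much larger α the naive test becomes
visibly conservative for the same column-effect reason described above —
subject-level reference effects inflate sd(d_i) but cancel in mean(d) — which
is itself one motivation for the permutation test.

What the generator does *not* emulate: spatial autocorrelation of real
parcellations, heavy-tailed motion artifacts, site/scanner effects, and any
actual SC→FC biophysics.  Passing tests therefore certify the statistical
machinery (calibration, power, invariances), not the realism of any
particular predictor.

## Problem sizes and numerical choices

Validation runs use desk-scale cohorts: calibration on 200 null cohorts
(N = 100, p = 30, K = 5) with 199 permutations each (the add-one estimator
makes p ≤ 0.05 exactly a top-10-of-200 event); power over
β ∈ {0, 0.25, 0.5, 1} with 100 cohorts per level (N = 200, α = 0.4); chance
matching with M = 2,500 subsets per size.  Matrix asymmetry up to 1e−8 is
silently symmetrized ((M + Mᵀ)/2) on load — numerical pipelines routinely
emit such rounding — and anything larger is an error.  Zero-variance
difference vectors mark results as degenerate (p forced to 0/1 by sign)
rather than raising.  All randomness flows through numpy Generators seeded
explicitly; identical seeds give bit-identical cohorts, reports and curves.

## Known limitations

- The evaluation grid skips conditions that are structurally degenerate
  (e.g. the z-scored group-mean benchmark at K = 2 is identically zero) and
  records them in the report instead.
- LERM on z-scored matrices is not offered: z-scored matrices are not
  correlation matrices and their SPD projection would measure the floor, not
  the data.
- The corrected resampled t assumes equal fold sizes when deriving
  n_test/n_train from the partition (it uses the mean fold size); strongly
  unbalanced partitions should pass explicit values.
- Masked (SC-pattern) correlation uses the prediction-side nonzero pattern;
  reference-side or intersection masks are not implemented.
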