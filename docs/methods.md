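# Methods

This note documents the models, conventions and design choices behind
`microsel`, in the package's own terms.  The benchmark throughout is a
two-class prostate microarray dataset with 59 healthy and 77 malignant
samples (N = 136) and 12,600 genes; the malignant class is the positive
class everywhere.

## Synthetic data generator

The generator draws per-gene noise standardized to mean 0 and variance 1
from one of three families, then adds a location shift of `effect_size`
(in within-class SD units) to the malignant class on a uniformly drawn
set of `n_informative` gene indices.  All other genes are exchangeable
between classes, and the informative index set is recorded on the
dataset so selection quality can be scored downstream.

* `gaussian` — N(0, 1); symmetric control condition.
* `lognormal` (default) — σ = 1, standardized analytically; skewness
  ≈ 6.2 and excess kurtosis ≈ 111, matching the strongly right-skewed,
  heavy-tailed regime reported for extracted microarray features
  (per-class skewness ~7–15, kurtosis up to ~126 in the benchmark's
  descriptive tables).
* `gamma` — shape 0.5, standardized; intermediate skew (≈ 2.8).

Defaults mirror the benchmark: 59/77 samples, 12,600 genes, 600
informative (a realistic few-percent signal fraction; the benchmark does
not state one), effect size 1.5 SD.  What the generator does **not**
emulate: probe-level physics, normalization artifacts, gene–gene
correlation structure, and batch effects.  Passing tests therefore
certify the pipeline's machinery and statistical behaviour under a
clean planted-signal model, not performance on real arrays.

## Feature extraction

Each method reduces a sample's gene vector to k values (default 6,000).
The benchmark never states *how* each method selects its k outputs, so
each extractor pairs the method with a retention rule built only from
the method's own outputs, fitted on training samples only:

* **DCT** — orthonormal DCT-II per sample (`scipy.fft.dct`,
  `norm="ortho"`); keep the k coefficient indices with the largest mean
  magnitude over training samples.  α(0) = 1/√N and α(k>0) = √(2/N)
  make the transform orthonormal, so Parseval's identity and exact
  inversion hold to 1e-9 and are tested.
* **PCA** — covariance eigendecomposition with denominator n (matching
  the covariance definition used by the benchmark); genes ranked by
  eigenvalue-weighted absolute loading summed over the leading
  components, top k gene columns kept.  Projection onto eigenvectors is
  limited by rank ≤ n_samples − 1 ≪ 6,000, which is why gene selection
  by loading is the default and projection (`mode="projection"`) is
  only available for k ≤ rank.  At gene scale the spectrum is computed
  via thin SVD of the centered matrix (O(n²d)); the explicit-covariance
  `pca_decompose` is kept for moderate dimensions and is verified
  against a characteristic-polynomial root oracle.
* **EM** — per-gene two-component univariate Gaussian mixture
  (vectorized across genes, median-split initialization); genes ranked
  by the between-class difference in mean posterior responsibility of
  the upper component.
* **NLR** — per-gene fit of m = θ₁e^(−θ₂n) + θ₃ over the sample index;
  genes ranked by residual sum of squares, worst fit first (largest
  departure from the smooth decay family = most structure).  The batch
  ranker uses variable projection over a 25-point log-spaced grid of
  decay rates (θ₁, θ₃ are linear given θ₂, so one shared QR per grid
  point prices all genes); it is a ranking device and intentionally
  trades exactness for tractability.  The reference `nlr_fit` uses
  damped least squares (Levenberg–Marquardt) and recovers noise-free
  parameters to 1e-6; a Jacobian condition number above 1e8 flags the
  θ₂ → 0 degeneracy where θ₁ and θ₃ are unidentifiable.
* **KMEANS** — Lloyd's algorithm on gene profiles (native: seeded
  distinct-point initialization, nearest-centroid ties broken by lowest
  index, emptied clusters re-seeded at the farthest point and
  recorded); genes ranked by d(own centroid)/d(nearest other centroid),
  most prototypical first.  K defaults to 8 clusters.

EM numerical guards: mixture variances are floored at 1e-6 × data
variance and the fit is flagged when flooring occurs; initial means are
spread quantiles with a seeded jitter when tied (identical means are a
symmetric EM fixed point).  The log-likelihood trace is monotone
non-decreasing to 1e-9 on every fit and is asserted in tests.

## Wrapper feature selection

A candidate is a continuous position in [0, 1]^d; coordinates above 0.5
select the corresponding feature (an all-zero mask falls back to the
argmax coordinate, so a mask always selects at least one feature).  The
fitness of a mask is the pooled k-fold cross-validated MSE of a
classifier trained on the masked features — for 0/1 labels this equals
the misclassification rate.  Fitness values are memoized by mask;
cache-on/cache-off equivalence is tested.  The selected-feature count
is emergent; an optional sparsity penalty λ·|mask|/d exists but
defaults to 0 (the benchmark states none).  All searches stop at
fitness ≤ 1e-5 or 1,000 iterations, whichever comes first, and count
the initial population evaluation as iteration one.

* **Harmony search** — memory of 20 harmonies (size not stated by the
  benchmark); per coordinate: copy from a random memory member with
  probability HMCR = 0.95, then perturb by ±BW·U(0,1) with probability
  PAR = 0.3 (BW = 0.1), else redraw uniformly; the improvisation
  replaces the worst memory member when it improves on it.
* **Firefly** — attractiveness β₀e^(−γr²) with γ = 0.1, β₀ = 1, r the
  Euclidean distance.  Movement is *toward* the brighter firefly; the
  printed update with the opposite sign is treated as a typo, as is the
  intensity expression that drops r from the exponent.  Updates are
  synchronous: each firefly's pull is the attractiveness-weighted mean
  displacement toward all brighter ones (the weight normalization
  tempers the otherwise unbounded accumulation of up to
  population−1 pulls), plus a uniform random kick whose scale starts at
  0.65 and decays by 0.97 per iteration.  The decay factor is a package
  choice — the benchmark gives only the initial value — set so the
  random term anneals from exploration to refinement within the
  1,000-iteration budget; the incumbent best position is never lost.
* **Elephant herding** — population 30 in 3 equal clans (clan count and
  population are package choices; the benchmark's "population of 6,000
  elephants" is read as the 6,000-dimensional search space, since 6,000
  agents with CV fitness is computationally implausible and the number
  matches the extraction output size exactly).  Followers move toward
  the clan best by α·(best − x)·r with α = 0.6, r ~ U(0,1); the clan
  best is re-placed at β·centre with β = 0.6; the clan worst is
  replaced by min + (max − min + 1)·rand per coordinate, clipped to
  bounds; elitism re-injects the global best over the current worst
  each iteration.

All three reach sphere-function fitness < 1e-2 (d = 10, default
budgets) in ≥ 18/20 seeds; the suite asserts exactly that.  The
wrapper's fitness classifier defaults to the downstream classifier
under test (wrapper semantics); a named cheap surrogate (e.g. the
native QDA) can be shared across classifiers to cut cost, which the
smoke profile uses.

## Classifiers and cross-validation

The eight classifier kinds carry the benchmark's fixed hyperparameters:
linear SVM C = 10; polynomial SVM degree 3 (C unstated, default 1); RBF
SVM C = 0.5, γ = 0.1; random forest 100 trees, depth 5, max_features 10
(capped at the feature count when d < 10); decision tree depth 10,
min_samples_leaf 1 ("min samples: 1" is read as per-leaf); QDA
regularization 0.5; AdaBoost 100 rounds, learning rate 0.1; XGBoost 100
rounds, learning rate 0.01, binary logistic objective.  SVM solvers use
tolerance 1e-5 and a 1,000-iteration cap, the benchmark's stopping
contract, where the backend exposes such controls.

SVM, forest, tree and boosting backends are scikit-learn/xgboost — the
benchmark's contribution is the framework, not the solvers.  QDA is
native: per-class Gaussians with MLE covariances shrunk toward their
diagonal, Σ_k ← (1−ρ)Σ_k + ρ·diag(Σ_k) with ρ = 0.5, a tiny
diagonal floor for positive-definiteness, Cholesky-based Mahalanobis
terms, and the argmax discriminant rule.  The native discriminant is
verified against a dense independent evaluation (explicit inverse and
log-determinant) and against the closed-form Bayes boundary of two
known Gaussians.  The AdaBoost round weight η·ln((1−ε)/ε) is also
native, with out-of-range errors clamped to [1e-10, 1−1e-10] under a
warning.

The canonical evaluation protocol is pooled stratified 10-fold
cross-validation over all samples: each class's shuffled indices are
dealt across folds (per-fold class counts within one of exact
proportionality; k = n degenerates to leave-one-out), and every
sample's prediction comes from a model whose training set excluded it
(asserted by index bookkeeping).  The benchmark's text also mentions a
0.1/0.9 train/test split, but its published matrices sum to all 136
samples, which only pooled CV produces; the pooled protocol is
therefore canonical here.

## Metrics, rounding and reconstruction

All ten metrics come from one confusion matrix; zero denominators yield
0 with the metric flagged degenerate rather than raised.  F1 is
computed in count form 2TP/(2TP+FP+FN), which is exact at rounding
boundaries where the precision/recall form drifts by an ulp.  Gmean and
CSI use the standard definitions √(recall·specificity) and
TP/(TP+FP+FN); the benchmark's printed Gmean/CSI values match neither
standard formula (e.g. its strongest row prints Gmean 94.58 where
√(recall·specificity) = 95.05), so those two columns are reported but
excluded from verification.  Malignant is the positive class: the
strongest published row admits an integer matrix only with TP+FN = 77.

Rounding: individual table values round half away from zero at 2
decimals.  Aggregate table averages are computed in integer hundredths
and rounded half to even, which reproduces all four published
cross-table averages exactly — including the no-selection table whose
exact mean is 69.025 and whose published average (69.02) is the
half-even rounding.

The inverse reconstruction enumerates all (TP, FP) with the given class
totals and keeps matrices whose recomputed accuracy/precision/F1 round
to the printed triple.  `ulp_slack` widens each comparison by that many
last-digit units: the published DCT+EHO+XGBoost row prints F1 = 94.60
while the (unique) consistent matrix has F1 = 94.5946 → 94.59, a
one-ulp slip in the source table; slack 1 recovers the matrix and the
reconstruction remains unique.  The round-trip property — every integer
matrix with totals 77/59 is contained in the reconstruction of its own
rounded metrics — is asserted exhaustively.

MCC/kappa analysis labels each (MCC, κ) pair by MCC band (R1 [0, 0.3],
R2 (0.3, 0.5], R3 [0.6, 0.7], otherwise unclassified; the source bands
leave (0.5, 0.6) unassigned) and reports the least-squares slope of κ
on MCC; over all 160 published rows the slope computes to 0.9999,
consistent with the published figure of 0.999.

Descriptive statistics average per-feature moments within each group
(constant columns are excluded from skewness/kurtosis with the count
reported); kurtosis is excess (Fisher) by default with a Pearson
switch, since the benchmark's convention is unstated.  The cross-group
terms are documented defaults where the source is silent: PCC is the
mean Pearson correlation of matched feature columns after truncating to
the smaller group; the t-test is Welch's on the per-feature column
means; CCA is the first canonical correlation with columns capped (30)
for stability.

## Pipeline, reproducibility and problem sizes

Stage order is fixed: extraction → selection → classification;
selection operates on extracted features.  "No selection" passes all
extracted features through.  Every cell of the
extraction × selection × classifier grid is evaluated fold-safely:
extractors and wrapper searches are fitted per fold on training data
only.  Per-cell seeds derive from the global seed via a CRC-tagged
`SeedSequence`, so identical configs produce byte-identical reports;
`--resume` caches completed cells keyed by the configuration hash, and
per-cell failures are isolated and recorded rather than aborting the
run.

The default test entry point is the smoke profile — 40 samples × 200
genes, k = 50, two extractors × {none, EHO} × three classifiers,
5-fold CV, reduced search budget, shared QDA surrogate fitness — which
completes in seconds.  Property suites use comparable scales (e.g.
planted-feature recovery at d = 16–20 over 20 seeds, sphere benchmarks
at d = 10 with full 1,000-iteration budgets).  Benchmark scale
(12,600 genes, 6,000-dimensional wrapper search with CV fitness) is
supported by the same code paths — full-scale extraction of all five
methods runs in seconds to ~10 s each — but a full-scale wrapper search
is an hours-long computation and is deliberately outside the default
test path.

## Known limitations

* The published accuracies of the original study are not reproducible
  here: its dataset provenance and split are under-specified, and the
  synthetic generator deliberately models only the data's shape and
  marginal statistics.  Verification instead targets the arithmetic of
  the published tables, which *is* exactly reproducible.
* The batch NLR ranker is grid-based; genes whose best decay rate falls
  between grid points get slightly pessimistic residuals (ranking is
  unaffected in practice, and the reference fit is exact).
* The firefly update is synchronous with a tempered pull; sequential
  per-pair updates (another common reading) would change trajectories
  but not the tested convergence properties.
* CCA is column-capped and row-truncated; with more features than
  samples the uncapped first canonical correlation is trivially 1.
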