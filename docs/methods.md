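# Methods

## Problem setting

Gene regulatory network (GRN) inference from expression data is cast as
binary classification of candidate edges: for every pair (r, g) with r a
transcription factor (TF) covered by a gold standard and g any gene, decide
whether r regulates g. A *level-1* method is any base inference algorithm
that assigns a confidence score x to each candidate edge from the
expression matrix alone (unsupervised with respect to the gold standard).
The *level-2* ensemble is a supervised classifier whose features are the
level-1 scores and whose labels e ∈ {0, 1} come from the gold standard,
with edges of gold-standard-absent pairs treated as negatives (closed-world
assumption — required to form a training set, and consistent with
precision-recall evaluation on present/absent edges).

Train and test sets are split *by transcription factor*: a random
two-thirds of the gold-standard regulators (rounded) supply the training
edges, the rest the test edges, and the two sides never share a TF. This
mirrors how validated edges accrue in practice — perturbation assays
validate all targets of one TF at a time — and prevents leakage through a
regulator's shared expression profile.

## Level-1 methods

The built-in level-1 suite contains simplified, well-understood
representatives of the three families of base algorithms. They target
category-level behaviour, not numerical equivalence with any published
tool.

| method | family | score for edge r→t |
|---|---|---|
| `pearson` | correlation | abs. Pearson correlation over all samples |
| `partial_correlation` | correlation | abs. partial correlation from the inverse of a shrunk correlation matrix, R\* = (1−λ)R + λI (default λ = 0.1; λ > 0 guarantees invertibility) |
| `lagged_correlation` | correlation (time-aware) | max over lags ℓ ≤ 2 of abs. correlation between r at tᵢ and t at tᵢ₊ℓ, pooled within trajectories |
| `mutual_information` | information | plug-in MI (nats) of the equal-frequency 4×4 joint histogram; symmetric in direction; equal-frequency binning is robust to heavy-tailed expression |
| `tree_importance` | tree ensemble | per-target random-forest regression on TF expressions; impurity importance, normalised to sum to 1 per target |
| `ode_ridge` | ODE regression | abs. ridge coefficient of r in a regression of the target's finite-difference derivative on TF levels plus the target's own level (decay term, never emitted as an edge); the penalty applies on standardised predictors and coefficients are reported on the original scale |

Externally produced ranked-edge files can be mixed in as additional
columns. Edges a file does not cover receive the file's minimum score: the
tabulation must cover *all* candidate edges, and an unlisted edge should
not look more confident than the least confident listed one.

## Kurtosis input filter

The default level-2 model is Gaussian Naive Bayes, which models each
method's score distribution per class as a Gaussian. Methods whose overall
score distribution is flat (platykurtic) violate that assumption badly, so
the ensemble retains only methods whose full score column has positive
sample excess kurtosis, g₂ = m₄/m₂² − 3 (population-moment form; exactly
Gaussian ⇒ 0, Uniform ⇒ −1.2, Laplace ⇒ +3). The filter sees only score
distributions, never labels, so it cannot leak test information. If no
method survives, all usable methods are retained (with a warning) so the
ensemble always has inputs; zero-variance columns are dropped because their
kurtosis is undefined.

## Feature construction and the level-2 model zoo

Raw level-1 scores live on wildly different scales, so each retained column
is rank-normalised over the full candidate universe: score → average-rank /
n ∈ (0, 1]. This makes features comparable across methods and renders the
pipeline invariant to any strictly monotone transform of a method's raw
output.

Nine level-2 kinds are available: `voting` (fraction of methods ranking the
edge in their top decile — no fitting), `logistic`, `logistic_sgd`,
`naive_bayes` (default), `svm` (decision value mapped through a logistic
sigmoid), `knn`, `random_forest`, `adaboost`, and `gradient_boost`.
All output one confidence in [0, 1] per test edge.

The Gaussian Naive Bayes classifier is implemented in-package: class priors
are empirical label frequencies; per-class per-feature means and
(population) variances define the Gaussian likelihoods; variances are
floored at 1e-9 × the largest feature variance to keep log-likelihoods
finite on degenerate features; the posterior follows from Bayes rule with
the naive factorisation.

**Gaussianised inputs for Naive Bayes.** Rank-normalised features are
bounded and near-uniform, which is the worst case for a Gaussian
class-conditional model: positive edges concentrate near rank 1, the fitted
positive-class variance collapses, and the posterior becomes so sharp that
a single disagreeing method vetoes a true edge. The `naive_bayes` kind
therefore maps each rank feature through the standard normal quantile
function (probit) before fitting and prediction. The map is strictly
monotone — no ranking information is created or destroyed, and every
rank-based invariance of the pipeline is preserved — but the transformed
features are far closer to Gaussian, which is the same consideration that
motivates the positive-kurtosis input filter. Set the hyperparameter
`gaussianize: false` to fit on raw ranks. Other kinds are scale-robust and
use the ranks directly.

Class imbalance is left as-is (no resampling): the evaluation metric is
AUPRC, which is computed on the natural prevalence, and the Bayes posterior
handles priors explicitly.

## Evaluation protocol

AUPRC is computed in average-precision (step) form: the mean over
positives, in descending score order, of the precision at each positive's
threshold; tied scores form one threshold group whose precision is assigned
to all its positives. No trapezoidal interpolation — the step form is
standard in the method-comparison literature and avoids optimistic
interpolation. A brute-force threshold-enumeration oracle pins this
convention in the tests to 1e-12.

The headline statistic is the **AUPRC ratio**: AUPRC divided by the test
side's positive prevalence (the expected AUPRC of a random predictor), so
1.0 means "random" and the statistic is comparable across splits with
different prevalences.

The repeated-split benchmark (default 20 splits) evaluates, on identical
test edges per split: every level-1 column, every requested ensemble, the
average-rank community baseline (mean normalised rank over retained
methods), the post-hoc best level-1 method per split
(`best_level1_test` — an unfair-to-the-ensemble reference, since the best
method cannot be known a priori), and the method selected by training-side
ratio (`best_level1_train`). Splits whose test side has no positive edge
(AUPRC undefined) are redrawn with a fresh seed and logged; more than 50%
redraws aborts the run.

Significance of paired comparisons uses a one-sided sign-flip permutation
test on per-split differences: the statistic is the mean difference, each
difference's sign is flipped independently under the null, and the p-value
is the fraction of flipped means at least as large as the observed one
(+1-corrected in Monte-Carlo mode; exact enumeration of all 2ⁿ patterns is
available for n ≤ 20). The test is paired because all systems share the
same splits, and it assumes nothing about the distribution of the
differences. The sign-flip construction is this package's explicit choice
of non-parametric paired test and is labelled as such in reports.

## Synthetic data generator

`netsim` emulates DREAM-style in-silico benchmarks at desk scale: a random
directed network (only TFs have outgoing edges; each TF→gene pair included
with probability mean_out_degree/(n_genes−1); activator:repressor 0.7:0.3;
strength ~ U[0.5, 2]) drives per-gene Hill kinetics

    dx_g/dt = α_g · f_g(x) − λ x_g,

where f_g is the strength-weighted mean of h(x) = xⁿ/(Kⁿ + xⁿ) over
activators and 1 − h(x) over repressors (f_g ≡ 1 for unregulated genes).
Defaults: α = 1, λ = 0.02 min⁻¹, n = 2, horizon 1000 min, sampling interval
50 min (10/20/25/100 are the other standard settings), 10 trajectories, 5%
noise. The half-saturation constant is specified as a *fraction* of the
unregulated steady-state level α/λ (default 0.5, i.e. K = 25 in expression
units): an absolute K far below the operating range would saturate every
Hill term and destroy the regulatory signal, so anchoring K to the
steady-state scale keeps the kinetics responsive at any parameterisation.

Each trajectory starts from the unperturbed fixed point (found by
integrating to convergence) with one randomly chosen TF knocked down — its
synthesis rate scaled by a factor drawn from [0, 0.2] — mimicking
perturbation time courses. Measurement noise is multiplicative lognormal:
x ← x·exp(ε), ε ~ N(0, noise_sd²), so the log-ratio to the noiseless
signal has standard deviation exactly noise_sd. Integration is classical
fixed-step RK4 with step min(0.5 min, Δ/20) — simple, deterministic, and
accurate for these smooth kinetics; all trajectories integrate
simultaneously as one vectorised state.

What the generator does *not* emulate: stochastic (Langevin) kinetics,
separate mRNA/protein layers, module structure extracted from real
networks, single-cell dropout, or library-size artefacts. Passing tests on
this generator therefore demonstrate correctness of the pipeline's
machinery and qualitative behaviour (signal recovery, stacking gain), not
performance claims about any real dataset.

Two purpose-built validation scenarios live in `grnstack.diagnostics`:

* **complementary-oracle**: two synthetic level-1 columns, each equal to
  the edge label plus N(0, 0.3) noise on one disjoint half of 60 TFs and
  pure Uniform(0, 1) noise on the other (labels Bernoulli(0.1) over a
  60 × 40 TF×target universe). Either column alone is blind on half the
  test TFs; a working stacking ensemble must beat both.
* **simulated_pipeline_ratios**: one full pipeline run (50 genes, 10 TFs,
  5% noise, 50-min sampling, all six built-in methods, 20-split
  protocol) returning mean test AUPRC ratios per system; the "best
  level-1" reference is the method with the highest mean test ratio.

## Problem sizes and numerical choices

Default problem sizes are chosen so a complete validation run takes minutes
on one CPU: 50–100 gene networks, 10 TFs, 20 splits, 100-seed repetition
for Monte-Carlo properties, 50 trees per forest in the end-to-end
diagnostics (100 by default elsewhere). Tie handling is explicit
everywhere: average ranks in normalisation, group-averaged precision in
AUPRC, lexicographic order in ranked-edge files, first-in-grid order in
hyper-parameter ties. Degenerate inputs have defined behaviour: constant
genes score 0 for correlation methods, zero-variance score columns are
dropped by the kurtosis filter, splits without test positives are redrawn,
single-class training raises a dedicated error (the fit-free voting kind
excepted).

## Known limitations

* Level-1 methods are didactic simplifications; absolute AUPRC ratios on
  the built-in simulator (often 5–20) are far above what real data yields
  (the ratio's scale depends entirely on data difficulty).
* The closed-world negative assumption understates performance when the
  gold standard is incomplete.
* Hyper-parameter tuning uses TF-disjoint folds on a user-supplied table;
  no nested tuning inside the benchmark loop.
* The simulator's knockdown perturbations make TF–target correlations
  unusually clean; methods relying on richer dynamics (e.g. oscillations)
  are not exercised.
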