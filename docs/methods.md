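# Methods

## The model

`ntcpbench` studies normal tissue complication probability (NTCP)
prediction for radiotherapy toxicity — concretely, grade-2 xerostomia
driven by parotid-gland dose — with the Lyman–Kutcher–Burman (LKB) model

    NTCP = Φ( (GMD − D50) / (m · D50) ),
    GMD(n) = ( Σᵢ vᵢ · Dᵢ^(1/n) )ⁿ,

where Φ is the standard normal CDF, (Dᵢ, vᵢ) are differential dose-volume
histogram (DVH) bins, `n` is the tissue's dose-volume dependence
(seriality), `m` the relative slope and `D50` the 50 %-complication dose.
The cohort objective is the mean binary cross-entropy of the predicted
probabilities against observed toxicity labels, with probabilities clipped
to [1e-15, 1 − 1e-15] so the loss is finite everywhere in the fitting box,
including the m → 0 step-function limit.

The GMD is a power mean with exponent 1/n. For small n the naive power sum
overflows double precision (70^100 ≫ 1e308), so it is evaluated as a
log-sum-exp; zero-dose bins are excluded (their contribution vanishes in
the limit) and an all-zero-dose DVH returns 0 by convention. Evaluation
refuses n below 1e-3 outright rather than clamping — exponents that
extreme are exactly the regime where fitting blows up, and the package
treats that as an explicit domain error. The fitter is stricter still and
rejects bounds that allow n < 0.01 unless an explicit unsafe flag is set.

## Fitting and the convergence pathology

The log-loss gradient has no known analytic form, so the local method
("gradient descent" in the radiotherapy literature) is bound-constrained
L-BFGS-B with central finite-difference gradients (relative step 1e-6).
The global methods are seeded dual annealing (maxiter 1000, function
budget 20 000) and differential evolution (popsize 15 per dimension,
maxiter 1000, polished). Default bounds: n ∈ [0.01, 4], m ∈ [0, 1],
D50 ∈ [0.01, 120] Gy — the upper D50 bound safely exceeds clinical
head-and-neck prescription doses. With m = 0 admitted in the box, the
evaluation floor m ≥ 1e-6 is applied inside the loss only.

A fit is *converged* when the optimizer reports success, the final loss is
finite, and the parameters lie within bounds (up to a 1e-9-of-range
tolerance). For the local method the success flag is the L-BFGS-B
termination status, so abnormal line-search terminations — which occur on
the clipped plateaus and between the competing gradient basins of this
surface — register as non-converged runs. Boundary optima of the global
optimizers count as converged: they are genuine optima of the bounded
problem, and `n` in particular is weakly identified on realistic cohorts
(near-symmetric DVHs make the GMD insensitive to n), so global fits
occasionally settle at the n boundary with essentially optimal loss.

The multi-start sweep samples initial points uniformly over the bounds box
(the least-informative choice; recorded in the output metadata) and
classifies each local fit into three *disjoint* classes: failed to
converge; converged but non-predictive (test ROC-AUC < 0.7, the
conventional predictiveness threshold, evaluated on the held-out cohort);
converged and predictive. An optional runtime budget projects total cost
from a few pilot fits and refuses oversized sweeps unless overridden.

The loss-landscape grid evaluates the loss and its central-difference
gradients over an (n, D50) grid at fixed m, one row per node — the table
behind quiver/heat-map renderings of the two competing descent directions.

## ComBat harmonization

Treatment-center effects on scalar features are removed with parametric
empirical-Bayes ComBat: per feature, standardize against a size-weighted
grand mean and an N-denominator pooled variance; estimate per-batch
additive (γ) and multiplicative (δ) effects; shrink them toward
moment-matched normal / inverse-gamma priors by the standard coupled
fixed-point iteration (stopping when the maximum relative change drops
below 1e-4); subtract and rescale. The arithmetic — including the
stopping rule — mirrors the Bioconductor reference implementation, and a
test verifies element-wise agreement to 1e-6 on a two-batch fixture.

Two deliberate restrictions: only scalar features are accepted (a DVH
curve is not a set of exchangeable features; the LKB input is therefore
never harmonized, only the classifier features are), and the outcome label
never enters the standardization design — the covariate hook exists but is
closed until a leakage-safe design-matrix path is implemented. The prior
moment-matching needs at least two features; a single-feature table falls
back to the unshrunken per-batch estimates, which makes the correction an
exact per-batch moment match.

In the pipeline, ComBat is fitted on the union of the train and test
feature tables with batch = center: cross-center harmonization requires
both centers in the design. This is recorded in the run log.

## Classifier benchmark

Four scikit-learn arms — AdaBoost, logistic regression, a Gini decision
tree, gradient boosting — are tuned by exhaustive grid search maximizing
mean validation-fold ROC-AUC over stratified folds (default 20; the fold
count must not exceed the minority-class count) and refitted on the full
training set. Default grids are the conventional ranges (AB: 50–400
estimators × learning rate 0.01–1; LR: six log-spaced inverse
regularization strengths; DT: depth 1–8 × min leaf 1–20; GB: 50–400
estimators × learning rate 0.01–0.3 × depth 1–4); all grids are
config-overridable. Scoring: accuracy at threshold 0.5 with ties classed
positive, rank-based ROC-AUC (ties one half), and the Brier score — the
headline comparison metric, being strictly proper and robust to extreme
probabilities. The LKB row is scored from its NTCP probabilities on each
split. Timing columns (tuning, fitting) are reported but excluded from all
determinism checks, being hardware-bound.

## The synthetic cohort generator

Real multi-center xerostomia registries are not distributable, so the
generator stands in for a 194-patient training registry and a 76-patient
external-trial test cohort. Per patient: a target mean dose from the
center's truncated-normal law; a DVH as a discretized normal spread around
it on a fixed bin grid (the simplest family whose GMD genuinely varies
with n, keeping n identifiable in principle; the family is pluggable);
toxicity Bernoulli with probability Φ(t), t the LKB probit argument at
the generating truth (n = 1, m = 0.55, D50 = 47 Gy) plus optional
covariate increments (age per SD, sex = F, chemo = yes) added on the
probit scale. Zero increments keep LKB correctly specified; nonzero
increments mis-specify it, the regime where feature-based classifiers
should win.

Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| truth (n, m, D50) | 1, 0.55, 47 Gy | canonical parotid xerostomia estimates |
| n_train / n_test | 194 / 76 | registry / external-trial scale |
| center mean doses | 46 / 42 Gy | realistic cross-center planning difference |
| dose_sd | 16 Gy | calibrated so the true model's test AUC ≈ 0.74, the discrimination typically reported for parotid mean-dose models |
| dvh_spread | 8 Gy | plausible within-organ dose heterogeneity |
| batch shift / scale | +3 Gy / 1.0 | modest recording artifact at the test center |
| bins | 60 × 2 Gy | covers 0–120 Gy |

The batch shift/scale distorts the *recorded* test-center DVH after the
toxicity draw — a protocol/recording artifact of the kind ComBat is meant
to remove. (Applying it before the draw would make the center difference
biologically real, in which case harmonization would be the wrong
operation.) Under the defaults the toxicity prevalence is ≈ 0.49; a
warning fires if a configuration leaves the (0.1, 0.6) trainable band.

What the generator does **not** emulate: anatomically realistic or skewed
dose distributions, multi-organ DVHs, correlated covariates, censoring or
missingness, and inter-center differences in toxicity grading. Passing
tests therefore demonstrate correctness of the machinery and the
qualitative phenomena (multi-basin convergence, batch-effect removal,
mis-specification costs), not clinical performance on real registries.

## Problem sizes in the test suite

The package's own checks run at desk scale: parameter recovery uses
N = 2000 cohorts over 10 seeds; the convergence sweep uses 1000 starts
(the million-start experiment is reachable through configuration); the
repeated-seed classifier comparison uses the default 194/76 cohorts over
10 seeds with trimmed grids and 5 CV folds. These sizes were chosen so the
full suite completes in minutes while leaving each phenomenon clearly
resolved; all of them are configuration, not limits.

## Known limitations

- `n` is weakly identified on near-uniform DVHs; recovery tests target
  D50 and m, and real fits should treat fitted n with caution (fixing
  n = 1 via `fix_n` reduces the problem to two parameters).
- The covariate hook in ComBat is intentionally closed (no design-matrix
  covariates yet).
- No confidence intervals on LKB parameters (profile likelihood is out of
  scope), and no plot rendering beyond the landscape CSV.
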