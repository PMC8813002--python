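# Methods

## Model and procedure

The package targets exploratory, hypothesis-generating analyses of
respondent-level survey data with a rare binary outcome y, sampling
weights w, and a very wide one-hot encoded design matrix X (thousands of
`variable=level` indicator columns). All model fitting maximizes the
survey-weighted Bernoulli log-likelihood

    l(θ, b) = Σᵢ wᵢ [ yᵢ ηᵢ − log(1 + e^ηᵢ) ],   ηᵢ = b + Xᵢθ,

minus a penalty: λ‖θ‖₁ for the lasso screen, λ‖θ‖₂² for the ridge
ranking. Two conventions matter for comparing λ across software: the
ridge penalty carries no ½ factor, and the likelihood is a *sum* (not a
mean), with weights normalized to mean 1 inside the fit so the effective
sample size equals n. Under these conventions doubling every weight
changes nothing, and λ_max — the smallest λ with an all-zero lasso
solution — equals the largest absolute entry of the weighted null-model
gradient on standardized columns.

One ITA round = CV-tuned lasso → drop zero-coefficient variables
(|θⱼ| ≤ 10⁻⁸ on the standardized scale) → CV-tuned ridge on the
survivors → sort ridge coefficient magnitudes → Kneedle knee point →
code the above-knee variables into themes → drop the theme containing
the top-coefficient variable → repeat. Stopping: three consecutive
rounds with no new theme, any round with no new variable, a degenerate
round (fewer than three lasso survivors, or no knee), or the round cap.

Interpretation of "drop the theme": only the variables coded in the
current round's selection are removed. Unselected variables that a human
might associate with the same topic stay in the pool and may be selected
(and the theme dropped again) in a later round; this is visible in the
README example and is intended — coding happens only above the knee, so
that is the only place theme membership is defined.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `test_ratio` | 0.2 | held-out fraction; 80:20 is the convention for this kind of analysis |
| `stratified` | on | preserves positive-class share in the split; essential at 1% prevalence (a plain random 20% test set can lose every positive). Plain random remains available. |
| `k` | 5 | CV folds for λ selection, stratified and seeded |
| `n_lambdas`, `lam_min_ratio` | 50, 10⁻⁴ | log-spaced grid from λ_max down to 10⁻⁴λ_max; the L1 anchor is reused for the ridge grid so both penalties share one grid construction |
| `knee_sensitivity` | 1.0 | Kneedle S; the customary default |
| `sort_mode` | absolute | rank |θⱼ|; protective (negative) correlates compete equally. `signed` mode ranks raw θⱼ for sensitivity analyses. |
| `zero_tol` | 10⁻⁸ | "zero" for the lasso drop, on the standardized scale — the solver produces exact zeros, but the contract must not assume it |
| `max_rounds` | 10 | safety cap |
| `ber_threshold` | 0.5 | BER cut-off; the prevalence-matched threshold is also computed per round, because at rare prevalence the 0.5 cut degenerates to the all-negative classifier |
| `reselect_lambda` | on | λ re-tuned by CV each round (the variable set changes); off reuses round 1's λ |
| `resplit_per_round` | off | fixed test set across rounds, so round metrics are comparable; redraw available |

Penalties act on weighted-standardized columns (mean 0, variance 1);
coefficients are reported on both scales, and knee selection compares
standardized magnitudes. The intercept is never penalized.

## Solver

The convex fits use an in-package IRLS + cyclic coordinate-descent path
algorithm (`itaselect/_cd.py`): warm starts along the decreasing λ grid,
soft-thresholding updates for L1 and closed-form shrinkage for L2,
active-set sweeps with periodic full passes, and an unpenalized intercept
coordinate. Convergence is declared on the exact first-order (KKT)
conditions of the true objective, scaled per observation (default
tolerance 10⁻⁸; CV exploration fits use 10⁻⁵, since only their held-out
likelihood matters). The λ-path design makes a 50-point, 5-fold CV on
n ≈ 15,500 × 1,000 columns run in seconds per fold on one CPU. Tests pin
the solver against a damped Newton–Raphson oracle at λ = 0, against
explicit KKT residuals at λ > 0, and against scikit-learn's liblinear
solver on small problems.

Degenerate inputs: zero-variance columns get scale 1 (their standardized
column is all zeros and their coefficient stays 0); probabilities are
clamped away from 0/1 inside IRLS; a fit that exhausts its iteration caps
is returned with `converged_ = False` and a warning, never silently.

## Knee detection

Kneedle, specialized to the non-increasing curves produced by sorting
coefficient magnitudes: min–max normalize to the unit square, form the
difference curve d = (1 − y_norm) − x, take local maxima of d as
candidates, and accept the first candidate whose lead persists — some
later point falls below d_max − S·mean(Δx) before the next local maximum.
Normalization makes the knee invariant to affine rescaling of the
values. A flat or linear curve has no knee; the round is then recorded as
degenerate and selects nothing (selecting everything would abolish the
screen). No smoothing is applied: the sorted curve is monotone by
construction. On smooth convex decreasing curves Kneedle (S = 1) agrees
with the maximum-distance-to-chord construction to within two positions;
tests assert exactly that.

## Evaluation metrics

AUC is the weighted probability that a random positive outranks a random
negative (ties ½; trapezoidal ROC integral). BER = 1 − ½(sensitivity +
specificity) at a probability threshold — the standard complement of
balanced accuracy; the phrase "average of true positives and true
negatives" is interpreted as class-conditional *rates*, the universal BER
definition. Metrics are unweighted on the test partition by default, with
weighted variants available; both the 0.5 and the prevalence-matched
threshold BER are logged per round.

## Synthetic benchmark

The real input this package was designed around — a DHS domestic-violence
module subsample — is access-restricted, so the package ships a
generator whose defaults mirror that study population's structure:

- n = 19,468 respondents; outcome prevalence calibrated to 14.4%
  (any-source help-seeking) with a 1.0% formal-institution variant;
- 6 themed blocks × 5 binary signal variables, log-odds effects drawn
  once per spec uniformly in [0.5, 1.2], within-block latent correlation
  ρ = 0.3, marginal positive rate 0.3;
- ~970 independent Bernoulli noise columns with rates drawn in
  [0.05, 0.5] (mimicking the wide range of indicator prevalences in an
  encoded survey);
- log-normal sampling weights (σ = 0.5), normalized to mean 1,
  independent of covariates by default.

Correlated binaries come from thresholding an equicorrelated latent
Gaussian (Z = √ρ·G + √(1−ρ)·E, x = 1{Z > Φ⁻¹(1 − rate)}): marginals are
exact and the implied pairwise phi correlation is computable by
bivariate-normal quadrature, which the tests use as an oracle. The
outcome follows the logistic model with intercept calibrated by bisection
against 200,000 Monte-Carlo latent draws (achieved prevalence within
10⁻³ of target; the calibration stream is derived deterministically from
the spec seed, separate from the data stream, so a spec always calibrates
identically). Everything is reproducible byte-for-byte from the seed.

What the generator does *not* emulate: real questionnaire content and
skip logic, missingness patterns, informative weights (an option exists),
cross-theme correlation (an option exists), and above all the semantic
coherence of themes — the ground-truth coder simply returns the planted
block labels. Passing benchmarks therefore demonstrate that the
*mechanics* of screening, ranking, knee selection, and theme elimination
recover planted structure at realistic scale and prevalence; they say
nothing about whether human coding of real survey variables yields
substantively meaningful themes.

## Problem sizes used in the shipped checks

- Performance check: the full-scale benchmark (n = 19,468, 1,000
  columns), three rounds, default settings — minimum held-out AUC across
  rounds is compared against the 65% floor.
- Multi-seed recovery check: ten replicates of the same generator
  structure at n = 5,000 with 200 noise columns and a 25-point λ grid —
  chosen so ten full ITA runs remain a routine test-suite item; the
  planted-signal recovery (≥ 80% of signal variables in the union of
  selections) and theme recovery (≥ 4 of 6 themes) are asserted for the
  majority of seeds.
- Unit-level oracles (Newton MLE, KKT, pair-counting AUC, chord-distance
  knee, quadrature phi) run at small n where exhaustive computation is
  exact.

## Known limitations

- The qualitative step is file- or callback-driven; the package cannot
  judge coding quality beyond inter-coder agreement.
- No inference (standard errors, CIs) on penalized coefficients; the
  procedure is exploratory by design.
- Theme dropping removes coded variables only (see above); a stricter
  construct-level removal would require metadata the selection step does
  not have.
- The CV criterion is the held-out weighted log-likelihood; AUC-based λ
  selection is not implemented.
- Missing data are handled by indicator levels, not imputation; survey
  "don't know" codes should be mapped explicitly by the user (they are
  not guessed at).
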