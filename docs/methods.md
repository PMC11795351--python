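# Methods

This note records the statistical model behind each estimator, the numerical
choices, what the synthetic data emulate, and the design decisions that were
genuinely open.

## Estimand and assumptions

The estimand is the average treatment effect on the probability scale,
`ψ = E[Y(1)] − E[Y(0)]`, for a binary treatment A and an outcome Y that is
binary or bounded in [0, 1]. Identification assumes consistency
(Y = A·Y(1) + (1−A)·Y(0)), conditional exchangeability given the measured
confounders W, no interference, and positivity (0 < P(A=1|W) < 1 almost
surely). None of these are testable from the data; the package's diagnostics
(balance tables, overlap densities, weight summaries, empty-cell errors)
surface *near*-violations of positivity but cannot repair confounding by
unmeasured variables.

## Estimators

**Nonparametric g-formula.** Stratum-specific contrasts of empirical outcome
means averaged over the empirical confounder distribution. Requires every
treatment-by-stratum cell to be occupied; an empty cell is a hard error
rather than a silently merged stratum, because any automatic collapse choice
injects bias invisibly. The saturated-regression route fits one least-squares
coefficient per (a, stratum) cell and averages predicted contrasts; both
routes are algebraically identical and the test suite asserts agreement to
1e-10.

**Parametric g-computation.** Outcome regressions fit *separately per arm*
(family `linear` for the linear probability model, `logistic` for bounded
predictions), then both counterfactual surfaces predicted for every subject.
The linear family is the default for regression-adjustment estimators;
the logistic family is the default wherever predictions feed a logit
(AIPTW's Q model, TMLE's initial estimate). Continuous confounders enter
linearly unless the caller expands them via `ModelSpec` (product terms are
written `"x:z"`).

**IPTW / MSM.** The propensity score is a logistic GLM; predictions are
clipped to a recorded bounding interval (default [0.01, 0.99] — the
literature warns about probabilities near 0/1 but fixes no number, so the
bound is configurable and every clipping event is counted, never silent).
Horvitz–Thompson weights divide by g (treated) or 1−g (controls); stabilized
weights multiply by the marginal treatment probability and should average
to 1 — a mean outside [0.5, 2] attaches a near-positivity warning. The MSM
is a weighted least-squares fit of Y on {1, A}; its treatment coefficient
equals the Hájek IPTW contrast exactly, so the HC0 sandwich SE it carries is
a secondary diagnostic and the bootstrap is the recommended inference.

**Weight hygiene.** Truncation winsorizes weights at user-specified
percentiles (or absolute values); trimming drops the rows and records the
mask. Both record thresholds and counts affected. Trimming changes the
effective estimand; that trade-off is the caller's.

**Balance and overlap.** Standardized difference
`(m₁ − m₀)/√((v₁ + v₀)/2)` per encoded confounder column, with unweighted
arm moments for the raw rows and Hájek means plus frequency-weight variances
`Σw(x − x̄_w)²/Σw` for the weighted rows. The frequency-weight convention is
a documented choice; alternative conventions move the third decimal.
Overlap densities use an Epanechnikov kernel with Silverman's rule scaled by
the Epanechnikov-optimal constant (2.345·σ·n^(−1/5)), a 512-point grid
spanning the propensity support padded by one bandwidth and clipped to
[0, 1], so each arm's density integrates to 1 within 1e-3 on the grid.

**AIPTW.** Canonical augmented form
`μ̂ₐ = (1/n) Σ [Q(a,W) + I(A=a)(Y − Q(a,W))/g(a|W)]`; the augmentation is the
arm-specific residual reweighted by the inverse treatment probability and
has exactly mean zero whenever g is a saturated fit. A published worked
example instead augments with the stabilized-weighted residual of the
observed-treatment prediction, `sws·(Y − Q(A,W)) + Q(a,W)`; that variant is
available behind `box_variant=True` for comparison but is not the canonical
estimating function (its two augmentation terms are not arm-specific).
Inference: influence function
`IF = [A(Y−Q₁)/g + Q₁ − μ₁] − [(1−A)(Y−Q₀)/(1−g) + Q₀ − μ₀]`,
SE = sd(IF)/√n, Wald interval.

**TMLE.** Steps: (1) initial pooled logistic Q(A, W), predictions clipped to
`q_bounds` (default [0.005, 0.995]) before the logit transform; (2) logistic
g and clever covariates H₁ = A/g, H₀ = (1−A)/(1−g); (3) intercept-free
logistic fluctuation of Y on {H₁, H₀} with offset logit(Q(A,W)) — because
H₁ and H₀ have disjoint support, the two-ε problem separates into two
one-parameter concave problems, each solved by damped Newton until the
score sum is below 1e-11, which is what guarantees the efficient-score
equations `|Σ Hₐ(Y − Q*(a,W))| ≤ 1e-8` after targeting; (4) updates
`Q*₁ = expit(logit(Q₁) + ε₁/g)`, `Q*₀ = expit(logit(Q₀) + ε₂/(1−g))`;
(5) plug-in means, which cannot leave [0, 1]; (6) influence-function Wald
inference, with mean(IF) = 0 by construction. The per-arm two-ε update is
used rather than the single-ε H(A,W) variant; the ε/g division in the
update mirrors the evaluation of the clever covariate at the counterfactual
treatment.

*Bounded continuous outcomes.* The frame contract already restricts Y to
[0, 1], so by default TMLE treats a continuous outcome as a proportion on
its known parameter space (identity transform). The alternative — stretching
the observed min/max onto [0, 1] (`outcome_scaling="observed"`, and the
exposed `scale_bounded_outcome` helper with its affine inverse) — is
appropriate when the attainable range is far narrower than [0, 1], but has
a real cost: a logistic Q specified on the original scale is no longer
exactly correct after the affine stretch, which measurably biases the
correct-Q arm of a double-robustness experiment. Known bounds are therefore
the default.

**Super learner.** Candidates: main-effects GLM; a GLM whose design adds
squares and pairwise products of the confounders; and backward stepwise AIC
elimination starting from that polynomial design (deterministic term order,
intercept always kept). 5-fold cross-validation (fold assignment is the only
randomness; deterministic given the seed); loss is the negative Bernoulli
log-likelihood, valid for binary outcomes and proportions alike; ensemble
weights minimize the cross-validated loss over the probability simplex by
projected gradient (500 iterations, tolerance 1e-9, adaptive step with
halving). A learner that fails on any fold is dropped with a warning and
the remaining weights renormalized. The ensemble is opt-in
(`q_learner="super"`); default nuisances are plain GLMs to keep the core
path deterministic and dependency-light.

**Bootstrap.** n-out-of-n resampling with replacement, seeded
(`numpy.random.default_rng`); default B = 1000. Intervals: normal
(est ± z·sd(replicates)), percentile (type-7 interpolated quantiles —
documented because other quantile rules move the third decimal), and
bias-corrected (percentile at z-shifted quantiles with
z₀ = Φ⁻¹(fraction of replicates below the full-data estimate); no
acceleration term — BC, not BCa). Replicates on which the estimator raises
(an empty stratum, a lost categorical level) are excluded and counted;
above a 10% failure rate the bootstrap aborts with advice to use a larger
sample or a parametric estimator. Bootstrap CIs are refused for TMLE at the
CLI because resampling inference is not theoretically supported for
data-adaptive plug-in estimators; influence-function intervals are used
there instead.

## GLM kernels

`fit_logistic` / `fit_linear` wrap statsmodels GLM (binomial family, IRLS,
deviance tolerance 1e-12, 100 iterations — tightened beyond the usual 1e-8
so that saturated fits reproduce cell proportions to machine precision,
which the exact-equivalence identities rely on) and weighted least squares.
The wrappers add what the estimators need: a zero-free-column fit returns
expit(offset) exactly; rank-deficient columns are detected by pivoted QR and
dropped with a warning; complete separation (statsmodels' perfect-prediction
warning plus fitted probabilities pinned at the 1e-10 floor plus a free
coefficient above 20 on the logit scale) raises an error naming the worst
column. Fitted probabilities are clipped to [1e-10, 1−1e-10] so downstream
logits stay finite. One-hot encoding drops the lowest sort-order level as
the reference (this affects coefficients, never the marginal estimates; the
test suite asserts relabeling invariance).

## Synthetic data

**Simulation DGP** (cancer-epidemiology flavored): deprivation quintile
`w1 = round(U(1,5))` (masses 1/8, 1/4, 1/4, 1/4, 1/8), age indicator
`w2 ~ Bern(0.45)`, stage `w3 = round(U(0,1) + 0.75 w2 + 0.8 w1)` with raw
values 5/6 recoded to stage 1 (this recode is what manufactures
near-positivity cells: high-deprivation subjects relabeled to stage 1),
comorbidity `w4 = round(U(0,1) + 1.2 w2 + 0.2 w1)`,
`A ~ Bern(expit(−3 − 0.5 w4 + 1.5 w2 + 0.75 w3 + 0.25 w1 + 0.8 w2·w4))`,
and potential-outcome *probabilities*
`Y(a) = expit(−3 + a + 0.25 w4 + 0.75 w3 + 0.8 w2·w4 + 0.05 w1)`, observed
Y being their consistency mixture — continuous in (0, 1), so every
individual effect ψᵢ = Y(1)ᵢ − Y(0)ᵢ is known. Rounding is half away from
zero (ties have probability zero under the uniforms, but the convention is
fixed because banker's rounding would change the w3/w4 distributions).
The population ATE is computed exactly by enumerating the 38-cell discrete
support with closed-form rounding-interval probabilities: 0.167365,
cross-checked in the tests by a 10⁶-row Monte Carlo draw and by midpoint
quadrature over the two uniforms.

What this DGP does *not* emulate: Bernoulli outcome noise (Y is the event
probability itself, which makes correct-specification fits exact in finite
samples and sharpens bias measurements), unmeasured confounding, and
measurement error. Passing Monte Carlo tests therefore demonstrate estimator
algebra and double robustness under the stated mechanisms, not robustness to
everything real cohorts do.

**Misspecification scenario.** The benchmark runner's default nuisance
models are factor (indicator) main effects of w1–w4 — deliberately omitting
the `w2·w4` interaction present in both true mechanisms. Under this
scenario the doubly robust estimators (IPTW-RA, AIPTW, TMLE) show strictly
smaller absolute relative bias than the single-robust ones (g-computation,
IPTW); with the interaction included (and the logistic family for the
outcome, since the true outcome surface is expit-linear) every estimator is
unbiased to Monte Carlo precision.

**RHC-like generator.** A mixed-type cohort shaped like a critical-care
effectiveness study (binary 30-day-mortality-like outcome, binary treatment,
confounders sex, age, education, race, carcinoma; ~44% female; mild
confounding through sex, age and carcinoma). Generating coefficients are
stored on the returned object so tests recover the implied truth by
large-sample g-computation. It is a synthetic stand-in with the same shape
as the real cohort, not a calibrated copy.

**toy8.** An 8-row confounded fixture with one binary confounder whose
stratified effect (2/3) differs from the crude arm contrast (1/2); small
enough that every estimator's value is checkable by hand, and used as the
anchor of the exact-equivalence tests.

## Problem sizes used in the experiments

Chosen once as the package's study conditions: double-robustness recovery
uses 200 replicates of n = 2000 per misspecification leg; the
misspecification-ordering experiment uses 500 replicates of n = 1000;
bootstrap calibration uses 500 cohorts of n = 200 with B = 400 and requires
empirical 95% coverage within [0.92, 0.98]; smaller unit-level Monte Carlo
checks (40 replicates, 10 seeded super-learner runs at n = 1000) assert the
same qualitative facts at reduced resolution. All Monte Carlo assertions
are stated with 3×MC-SE tolerances rather than fixed constants.

## Known limitations

- Point-treatment, single-time-point setting only: no time-varying
  treatments or longitudinal g-formula, no ATT estimand, no matching.
- Delta-method SEs for the weighting estimators are not reproduced; the
  bootstrap and influence functions carry inference.
- The super learner library is intentionally minimal (three GLM-family
  learners); no cross-fitting, so IF-based inference after the ensemble
  relies on the learners being simple enough (Donsker-type conditions).
- Near-positivity is handled by bounding/trimming/truncation with full
  provenance, but no estimator here can rescue a genuinely unidentified
  stratum.
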