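# Methods

## Model

The outcome model is a cumulative-logit (proportional-odds) regression of
the 90-day modified Rankin Scale (mRS), a 7-level ordinal disability score:

    P(mRS ≤ j | x) = expit(α_{j+1} + η(x)),   j = 0 … 5,

with strictly increasing cutpoints α₁ < … < α₆ and a linear predictor η
shared across thresholds (the proportional-odds assumption). We orient the
model so that **positive coefficients mean better outcomes**; the
probability of functional independence is then literally P(mRS ≤ 2). The
orientation is a free convention in this model class; this choice makes the
primary outcome a direct model quantity instead of a complement.

The linear predictor contains eleven baseline predictors and treatment
terms:

| term | form | unit |
| --- | --- | --- |
| age | linear | years |
| NIHSS | linear | points (0–42) |
| systolic blood pressure | linear | mmHg |
| glucose | piecewise-linear or restricted cubic (below) | mg/dL |
| IV alteplase, diabetes | binary indicators | — |
| prestroke mRS | linear score | 0–5 |
| ASPECTS | linear score | 0–10 |
| occlusion location | indicators for ICA/ICA-T and M2 vs M1 | — |
| collateral grade | linear score | 0–3 |
| onset-to-groin time | linear, uncentered | minutes |
| prior stroke | binary (original configuration only) | — |
| EVT | binary treatment indicator | — |
| EVT × onset-to-groin, EVT × collaterals, EVT × prior stroke | products | — |

M1 is the occlusion reference level because it is the most common category.
Collateral grade enters as a single linear score in both its main effect
and its interaction; onset-to-groin enters in raw minutes. Both are
conventions we fixed where the model class leaves them open; the spline and
interaction machinery does not depend on them.

Two named configurations are shipped: **original** (prior stroke in, three
EVT interactions, no glucose) and **updated** (nonlinear glucose in, prior
stroke and its interaction out). Configurations carry structure only;
coefficient values always come from fitting or from an explicit generator
configuration.

### Glucose nonlinearity

Two selectable forms:

* **piecewise linear** (default): basis `(g, max(0, g − 120))`, i.e.
  separate slopes below and above 120 mg/dL. This is the default because
  the effect this term models is commonly reported as separate odds ratios
  per 10 mg/dL below and above 120.
* **restricted cubic spline**: Harrell's truncated-power parameterization
  with default knots (90, 120, 180) mg/dL; the k−2 nonlinear terms vanish
  identically below the first knot, are linear beyond the last, and are
  normalized by (t_k − t₁)² to stay on the scale of g.

### Treatment benefit

For each patient the predicted benefit is

    B(x) = P(mRS ≤ 2 | x, EVT = 1) − P(mRS ≤ 2 | x, EVT = 0),

computed by rebuilding the design with the treatment indicator (and every
interaction that contains it) forced to 1 and then 0; the patient's
recorded treatment status is ignored. Because the link is logistic, a
constant relative effect yields absolute benefit that peaks at intermediate
baseline risk and vanishes at both extremes — the benefit is modified by
onset-to-groin time and collaterals explicitly, and by baseline prognosis
implicitly.

## Fitting

The multinomial log-likelihood of the cumulative-logit model is concave in
(α, β) for the logistic link (log-concave density), so we fit with a damped
Newton iteration in the natural parameterization, using the analytic
gradient and Hessian. Details:

* **Start values**: α from the empirical cumulative logits (clipped to
  [10⁻⁴, 1−10⁻⁴], tied levels separated by 10⁻⁶), β = 0.
* **Monotone cutpoints**: step halving rejects any step that breaks strict
  monotonicity or decreases the likelihood; with a concave objective this
  keeps the iterates valid without a reparameterization and leaves the
  observed information directly available at the optimum.
* **Convergence**: infinity norm of the per-observation mean gradient
  ≤ 10⁻⁸ (default `tol`); non-convergence is reported via
  `converged=False` plus diagnostics (iterations, gradient norm), never
  silently.
* **Covariance**: inverse of the negative Hessian (observed information) at
  the optimum, symmetrized; a singular information matrix falls back to the
  pseudo-inverse and is noted in the diagnostics.
* **Degenerate inputs**: outcomes concentrated in one mRS level raise an
  error; empty interior levels are tolerated by the step-halving fit but
  can leave boundary-flat cutpoints, which the convergence flag reflects.

An independent implementation (statsmodels `OrderedModel`, which uses the
opposite sign convention for β) reproduces our maximized log-likelihood and
parameters to ~10⁻⁷ in the test suite; it is used only as an oracle there.

**Likelihood-ratio tests** require the reduced model's design columns to be
a subset of the full model's and identical sample sizes; the statistic is
2·Δloglik (clamped at 0 within numerical tolerance), df the column-count
difference, p from the χ² upper tail.

**Intercept recalibration** maximizes the external-cohort likelihood over a
single shift δ applied to all six cutpoints (1-D Newton), leaving β
untouched — after recalibration the calibration-in-the-large on that cohort
is ≈ 0 by construction.

**Cohort-adjusted refit** pools cohorts and adds indicator main effects for
all non-reference cohort labels (reference = first label in sorted order).
We read the "adjustment factor" of the published workflow as exactly this
main-effect offset — the simplest structure consistent with refitting
shared coefficients. Predictions for a new population use
`with_cohort_baseline(label)`, which absorbs the chosen label's offset into
the cutpoints; the dropped indicator's sampling covariance is discarded in
that projection (an approximation that does not affect point predictions).

## Validation metrics

* **Binary concordance** (functional independence): over all
  (event, non-event) pairs, concordant = 1, prediction ties = 0.5. Computed
  by outcome-group binary search, O(L²·n log n), verified exactly against
  the O(n²) enumeration in the tests.
* **Ordinal concordance**: same pairwise rule over all pairs with different
  mRS, patients ranked by the model's **linear predictor**. A weighted
  probability score would be an alternative ranking; the linear predictor
  is the standard single-score choice and is what we document and test.
* **Calibration intercept and slope**: logistic regression of the observed
  binary outcome on logit(p̂) — slope from the free fit, intercept from the
  offset fit. Fitted by the package's own Newton solver. Predictions at
  exactly 0 or 1 are clipped to [10⁻⁸, 1 − 10⁻⁸] with a warning.
* **Percentile bootstrap**: patients (rows) are resampled with replacement
  and the metric recomputed with the model fixed — an external-validation
  bootstrap, no refitting. With B replications the 95% bounds are the
  ceil(0.025·B)-th and floor(0.975·B)-th order statistics (50th/1950th at
  B = 2000), computed with a float-safe ceiling/floor. Resamples on which a
  metric is undefined (e.g. a single-class resample) are redrawn and
  counted; more than 5% of B redraws aborts with an explicit failure.

## c-for-benefit

Treated and control patients are matched on predicted benefit: the larger
arm is down-sampled at random (seeded), both arms are sorted by predicted
benefit (ties broken by row position for determinism), and pairing is
rank-by-rank. A greedy nearest-neighbor matcher is available behind a flag
for sensitivity analysis. Each pair's predicted benefit is the arithmetic
mean of its two members'; its observed benefit is the treated member's
good-outcome indicator minus the control member's (−1, 0, or +1). The
c-for-benefit applies the same concordance rule over pairs-of-pairs:
observed-benefit ties are excluded, predicted ties count 0.5, so a model
with constant predicted benefit scores exactly 0.5. Down-sampling (rather
than reusing controls) was chosen so every retained patient appears in
exactly one pair. In the all-treated registry the "arms" are successful
(eTICI ≥ 2b) vs unsuccessful reperfusion; the output is labeled a surrogate
contrast and is never interpreted as a causal benefit.

Benefit-group calibration compares, within quintiles of the cohort's own
predicted-benefit distribution or within the three classes cut at exactly
1% and 10% predicted benefit, the mean predicted benefit against the
observed arm difference in P(mRS 0–2). Groups with an empty arm are flagged
and their observed benefit reported as undefined rather than fabricated.
Duplicate quantile edges (e.g. constant predicted benefit) collapse
quintiles gracefully.

## Synthetic cohorts

The generator emulates the *structure* of the motivating trial and registry
data, not their numbers: the real cohorts' individual patient data are not
released, so covariate laws are synthetic-but-plausible and fully
configurable. Defaults: age ~ truncated normal (68 ± 13, 18–95 y); NIHSS ~
rounded normal (16 ± 5, clipped 0–42); SBP ~ normal (145 ± 24 mmHg);
glucose ~ log-normal (median 115 mg/dL, σ_log = 0.22); IV alteplase 85%,
diabetes 15%, prior stroke 10%; prestroke mRS and ASPECTS multinomial with
mass concentrated at 0 and 8–10 respectively; occlusion ICA/ICA-T : M1 : M2
= 25 : 60 : 15; collaterals (7, 25, 40, 28)%; onset-to-groin uniform on
60–390 min (the 6.5 h treatment window). Covariates are independent by
default; an optional Gaussian copula (per-pair latent correlations) induces
joint structure — used in the tests to make collaterals predictable from
ASPECTS.

Outcomes: each patient receives **both** potential mRS values, under
control and under treatment, drawn from the true model's cumulative
probabilities through one shared uniform (comonotone coupling). This makes
individual-level benefit well defined in fixtures, while every cohort-level
statistic depends only on the marginals. The observed outcome is the
assigned arm's: exact 1:1 permutation randomization for trials; for
registries every patient is treated, reperfusion success is Bernoulli
(constant p or a logistic function of covariates), and an unsuccessful
procedure yields the control-arm potential outcome — an explicit, documented
simplification standing in for unmodeled procedure failure.

The default generating coefficients follow the updated model structure with
a weak nonlinear glucose effect (−0.003047 per mg/dL below 120 mg/dL and
−0.002020 above, the log-odds of 0.97 and 0.98 per 10 mg/dL with the sign
flipped for our orientation), a treatment main effect of +0.75 and
interactions −0.002/min and +0.15/grade; cutpoints (1.34 … 5.52) give a
control arm with ≈ 30% functional independence and all seven mRS levels
populated under the default laws.

Missingness is MCAR at per-field rates (defaults mirror the motivating
setting: a third of collateral scores, a few percent elsewhere); outcomes
are only blanked on explicit request and are excluded, not imputed.
Imputation follows the mean/mode rule for fields ≤ 5% missing and single
deterministic regression imputation above it (linear least squares for
continuous fields, the package's multinomial-logistic for categorical ones,
fitted on observed rows with the remaining covariates mean/mode-filled).
Multiple imputation is deliberately out of scope; single regression
imputation keeps every pipeline bit-reproducible.

**What passing tests do and do not show.** Self-consistency, recovery and
calibration tests demonstrate that the estimators and metrics are correct
under the assumed data-generating process. They cannot show that the model
is correctly specified for real stroke cohorts — real data have correlated
covariates, non-proportional odds, informative missingness and site
effects that the generator does not emulate (site clustering and non-MCAR
mechanisms are explicit non-goals).

## Pipeline

`run_study` executes: generate cohorts (with missingness + imputation) →
fit the original configuration on the derivation trial → first external
validation (four metrics with bootstrap CIs, benefit quintiles, matched
pairs, c-for-benefit) → updating (LR test adding glucose, LR test dropping
prior stroke, cohort-adjusted refit on the pooled trials) → registry
validation with the updated model at the validation-cohort baseline
(four metrics, three benefit classes, surrogate c-for-benefit, and the
registry intercept-recalibration offset δ reported alongside). The master
seed fans out via `SeedSequence([master, stage_id])` with fixed stage ids,
so per-stage seeds are independent and stable when stages are added. All
artifacts are plain JSON/CSV with sorted keys and no timestamps; reruns are
bit-identical, and any stage can be reproduced from the persisted
intermediates and the recorded stage seed.

## Problem sizes

Simulation-based checks use sizes chosen to make their tolerances sharp but
the runs quick: parameter recovery at n = 20,000 (3 SE criterion),
self-calibration and recalibration at n = 10,000 (±0.05), benefit-quintile
self-consistency at n = 50,000 (2 Monte-Carlo SEs), likelihood-ratio test
size with 1,000 simulations of n = 2,000, and the deterministic pipeline
check at n = 2,000 per cohort. The acceptance script defaults to n = 3,000
per cohort with B = 2,000 bootstrap replications.

## Known limitations

* The proportional-odds assumption is imposed, not tested; no
  partial-proportional-odds relaxation is provided.
* Cutpoint estimates extrapolate to covariate value 0 (uncentered design),
  so their standard errors are large and strongly correlated with the
  continuous-predictor coefficients; inference should focus on β.
* The greedy nearest-neighbor matcher is O(n²) and intended for small
  sensitivity analyses only.
* `with_cohort_baseline` drops the covariance contribution of the absorbed
  cohort offset.
* The registry surrogate contrast inherits confounding by indication;
  nothing in the package attempts causal adjustment for it.
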