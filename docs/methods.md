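# Methods

## Causal estimands and identification

The package estimates natural direct and indirect effects of a binary
exposure A (radiation modality: 0 photons, 1 protons) on a right-censored
survival time T, mediated by a binary intermediate M (grade-4
radiation-induced lymphopenia). Identification rests on the usual
sequential-ignorability assumptions: no unmeasured exposure–outcome,
exposure–mediator, or mediator–outcome confounding given the adjustment set
C, and no mediator–outcome confounder affected by exposure. In the intended
workflow C is the estimated propensity score of a matched cohort, which
addresses measured confounding of the exposure only; mediator–outcome
confounding is an assumption, not something the data can certify.

Counterfactual notation: T(a, M(a*)) is the survival time under exposure a
with the mediator drawn from its distribution under a*. On the mean-survival
scale the effects are time ratios,

* NIE: E[T(a, M(a))|c] / E[T(a, M(a*))|c] — the part transmitted by the
  exposure-induced shift in the mediator's distribution;
* NDE: E[T(a, M(a*))|c] / E[T(a*, M(a*))|c] — the part that remains when
  the mediator distribution is frozen at its reference level.

With a Bernoulli mediator each expectation is a two-point sum, giving the
closed forms in the package docstrings. The implementation of these forms is
verified in the test suite against (a) the literal two-point summation and
(b) a Monte-Carlo counterfactual simulation (10⁶ draws with common random
numbers), on 100 random parameter draws each.

## Outcome model and the hazard scale

The outcome regression is a Weibull accelerated failure time model with the
shape parameter fixed at 1, i.e. exponential survival with log-linear
covariate effects on time. Under shape 1 a time ratio TR maps to a hazard
ratio HR = 1/TR, so log HR = −log TR and the decomposition
TE = NDE × NIE is exact on both scales (asserted to 1e-12 at run time in
`MediationResult`). A general shape γ (log HR = −γ · log TR) is exposed in
`to_hazard_scale` for sensitivity use but is not the default and is not fit.

The exponential AFT likelihood
`ℓ(θ) = Σᵢ [dᵢ(−μᵢ) − Tᵢ e^{−μᵢ}]`, μᵢ = xᵢ′θ, is globally concave and is
maximized by damped Newton iteration (relative log-likelihood change
< 1e-10 or 100 iterations; non-convergence is an error, never a warning);
covariance is the inverse observed information. The independent oracle in
the tests is the Poisson-GLM equivalence (event indicator with offset
log T), fit with statsmodels. Logistic regression, Cox partial likelihood
(Efron ties by default, Breslow optional), Kaplan-Meier curves with
Greenwood/log-log intervals, and log-rank tests are delegated to
statsmodels and lifelines behind the `survival_core` interface. The
Kaplan-Meier median interval inverts the pointwise confidence band
(Brookmeyer-Crowley-style); published median intervals for the motivating
cohort may use a different construction, so these are documented choices,
not replicas.

## Interval estimation

Default: the delta method over the stacked (β, θ). The two fits share no
parameters, so the joint covariance is block diagonal; gradients of the
log effects are central differences with step 1e-6·max(1, |param|). A
seeded nonparametric bootstrap (row resampling, percentile intervals on the
log-time-ratio scale) is provided for small samples such as surgical
subgroups, where Wald intervals are least trustworthy. The delta intervals
are calibrated by simulation in the acceptance suite: 500 replicates at
n = 2000 under an unconfounded generator, requiring 92–98% coverage of the
generating log NIE.

## Proportion mediated and the median-survival conversion

PM = exp(NDE)[exp(NIE) − 1]/[exp(NDE)exp(NIE) − 1] with NDE/NIE as log
hazard ratios — the mediated share of the excess relative hazard. The
formula can leave [0, 1] when the component effects oppose or the total
effect is harmful; the package reports PM unclamped with a validity flag
rather than truncating. Applied to the published rounded component HRs
(0.79 direct, 0.95 indirect) the formula gives 0.158; the motivating
study's reported ≈14.5% used unrounded internal estimates that are not
recoverable from print, so 0.158 is the reproducible value from stated
inputs.

The indirect effect converts to months by summarizing the reference arm as
an exponential hazard λ (by default the intercept-only exponential fit on
the reference arm of the matched cohort) and comparing medians:
Δ = (ln 2/λ)(1/HR_NIE − 1). Interval endpoints substitute the NIE interval
endpoints. With the published photon-arm KM median (40.9 months) and
indirect HR 0.95 this gives 2.15 months; the study's 2.37 months used its
internally fitted marginal hazard, again not recoverable from print.

## Propensity model and matching

Screening fits one univariate logistic model (exposure) and one univariate
Cox model (survival) per candidate; a candidate is flagged at level α for
either endpoint. The propensity model starts from all flagged candidates
plus the forced set (age and surgical status, mirroring standard practice
for this design) and removes the worst non-forced candidate while its Wald
p exceeds 0.05, refitting each time; AIC-based removal is a config option.
The clinical-literature Wald-p convention was chosen as default because the
design this package emulates reports only "backward stepwise" selection.

Matching is globally optimal 1:1: the rectangular assignment problem on
|dᵢ − dⱼ| is solved exactly (scipy's Jonker–Volgenant implementation),
with the logit of the score as the default distance — distances near 0/1
are more discriminating on that scale — and the probability scale as an
option. No caliper is applied by default; an optional caliper drops pairs
after the optimal solution is found. Patients are sorted by id before the
solve so ties break deterministically and the result is invariant to row
order. Downstream regressions adjust for the raw propensity score as a
linear covariate.

## Synthetic cohort generator

The generator exists so every stage is testable without access to the
non-deposited patient data. It draws covariates from the published
marginals (age normal 63.1/10.7; baseline lymphocyte count truncated normal
1.6/0.6 above 0.3; planning target volume log-normal moment-matched to
612.3/279.3 — the printed minimum of 92.8 implies right skew a truncated
normal would distort; categorical fields at the printed frequencies), then
assigns exposure, mediator and latent survival from the same three
structural models the inference assumes, and censors administratively at
Uniform(24, 168) months. The motivating study never describes its censoring
mechanism; an independent uniform window is the weakest assumption
consistent with Kaplan-Meier and Cox validity, and the 2–14-year window is
what an accrual period of that length with a few years of further follow-up
would produce (~30–35% censoring). The censoring window is a modeling
choice, not a published fact.

Slope coefficients come from published per-unit odds/hazard ratios
(mediator odds 0.36 per 10³ lymphocytes/µL, death hazard 1.02 per year of
age, 0.62 for surgery, stage and location effects in the same spirit);
model intercepts and the exposure coefficients were solved once by
Monte-Carlo root-finding (2·10⁶ draws) so that in expectation
P(A=1) = 0.361, mediator prevalence is 0.452/0.226 by arm, and the
photon-arm marginal median survival is 40.9 months. The frozen values are
in `default_paper_params`. These are calibration targets, not ground truth:
the generator reproduces the published marginals and directions, not the
joint distribution of the real cohort. In particular the default mediator
effect on survival (conditional HR 1.49) is the published univariable
value, so the synthetic indirect effect (~0.89 at n = 2000) is stronger
than the ~0.95 the study estimated after adjustment; passing tests show the
machinery recovers whatever structure generated the data, not that the
synthetic cohort equals the real one.

All randomness flows from one integer seed through named substreams
(covariates, exposure, mediator, outcome, censoring), so a stage's draws
survive pipeline reordering and the same seed is bit-reproducible.

## Problem sizes and numerical choices

Test and acceptance simulations use n = 800–50 000 and 100–500 replicates,
chosen so the whole suite runs in well under a minute per file on one CPU
while keeping Monte-Carlo error far below the tolerances asserted
(3-standard-error bands for stochastic checks; 1e-10/1e-12 for exact
identities). Logistic separation is an explicit error (diverging
coefficient guard at |β| > 25), as are rank-deficient designs (pivoted QR
names the redundant columns), Cox monotone likelihood (a binary level with
no events), and AFT non-convergence. Welch's t-test is the default for
descriptive tables because the motivating analysis reports only "t tests";
the pooled-variance version and the 2×2 continuity correction are
configurable.

## Known limitations

* Sequential ignorability is untestable; no sensitivity analysis
  (E-values) is included.
* Single mediator, binary; no time-varying exposures or mediators, no
  competing risks, no frailty.
* The exponential (shape-1) outcome model imposes constant hazards; the
  shape is fixed by design, and a free-shape Weibull is deliberately out of
  scope for estimation.
* The generator simulates neither weekly lymphocyte trajectories nor
  dosimetric features, and censoring is independent by construction, so
  dependent-censoring robustness is not exercised.
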