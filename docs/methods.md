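# Methods

## The model

`idmspec` works with the illness-death model without recovery: three states
0 = "healthy" (e.g. progression-free after surgery), 1 = "progression",
2 = "death", and the transitions 0→1, 0→2 and 1→2.  Each transition ij
carries a Cox-type hazard

    α_ij(t) = α_ij,0(t) · exp(β_ij' z),

with a nonparametric baseline α_ij,0 and log-linear covariate effects.  Time
runs on the **clock-reset** scale: the clock restarts at zero when a state is
entered, so the 1→2 hazard is a function of time since progression.  A
clock-reset model is semi-Markov by construction; we additionally let the
1→2 hazard depend on the sojourn time spent healthy before progression by
entering that sojourn time (`t010`, months) as an ordinary covariate on the
1→2 transition.  A significant `t010` coefficient distinguishes the
non-homogeneous semi-Markov model from a homogeneous one and is the
package's test of the Markov assumption (`specification.markov_test`).

Two families of restriction make the model parsimonious:

* **Proportional baselines** — two transitions share one baseline up to a
  constant factor exp(γ).  For the death transitions, γ is the log change
  of the mortality hazard caused by progression.  Implemented as a shared
  baseline stratum plus an indicator covariate of "arrived from state 1".
* **Equal effects** — a covariate's coefficients are shared across a set of
  transitions (a single design column populated on all of them).

`structures.EffectStructure` is the declarative description of which
coefficients exist, which are shared, and how the baselines are stratified.
The unrestricted three-covariate model has 10 coefficients; adding the
proportional-baseline factor makes 11; the fully reduced form of the
reference analysis has 6.

## Estimation

`cox_engine.fit` maximizes the stratified Cox partial likelihood by
Newton–Raphson with analytic score and information, step-halving on a
likelihood decrease (decreases below 64·eps relative are treated as
round-off, not overshoot), and convergence when the relative log-likelihood
change falls below `tol` (default 1e-9) and the score max-norm below
`grad_tol` (default 1e-8).  The engine is written in-house because the
shared-coefficient/proportional-term designs and configurable tie handling
(Breslow default, Efron optional) are not simultaneously available in the
Python survival stack; it is cross-checked in the test suite against
brute-force risk-set enumeration and against lifelines on designs both can
express.  Monotone likelihoods (perfect separation on a transition with few
events) are detected by a coefficient bound (|β| > 15) and raised as
errors; bootstrap machinery drops and counts such replicates.

Baseline cumulative hazards use the Breslow estimator: increment
(events at u) / Σ_risk exp(η) per stratum.  Wald intervals and p-values
are reported per coefficient; the likelihood-ratio test is reserved for
nested model comparison; AIC = −2ℓ + 2·df on the partial likelihood.

The proportional-hazards diagnostic is a 1-df score test for a linear time
trend in a coefficient's Schoenfeld residuals, Σ(g−ḡ)s divided by
Σ(g−ḡ)²V with the per-event risk-set variance V and a V-weighted mean ḡ.
The time transform g is the identity (analysis time) by default, with rank
and Kaplan–Meier transforms available since the choice is conventional.
Simulation under a proportional truth puts its size at the nominal 5%.
Baseline proportionality between two transitions is tested by stacking the
pair in one stratum with a transition indicator plus transition-specific
covariate effects and applying the same test to the indicator; log-log
curves (ln Λ̂₀ vs ln t per stratum) accompany it for the graphical check.

## The specification procedure

Starting from the model with proportional death baselines, `specification.reduce`
runs a greedy step-down: at each step it screens equality moves (share a
covariate across all three transitions, or across the two death
transitions), then drops of main effects with Wald p > α; a move is
accepted only if the LR test against the current model is non-significant
(p ≥ α, default α = 0.05) and the AIC does not increase.  Among acceptable
moves the lowest resulting AIC wins, ties broken by the larger df
reduction, then covariate order.  `t010` is never a candidate: once the
Markov assumption is rejected it is the structural justification of the
model, not an ordinary predictor.  A user-supplied ordered move list
reproduces any specific published path and records rejected moves.

Note a structural property of the acceptance rule: for a true k-df equality
the LR statistic is asymptotically χ²_k, and "AIC does not increase" means
statistic < 2k, so a correct 2-df merge is accepted with probability
P(χ²₂ < 4) ≈ 0.86, not 1 − α.  The rule deliberately trades some power to
merge for protection against fit deterioration.

## Prediction

For a covariate profile, subject-specific cumulative hazards are the
Breslow baselines scaled by exp(linear predictor).  From the healthy state,

    P00(t) = exp(−Λ01(t) − Λ02(t)),
    P01(t) = Σ_{u ≤ t} m01(u) · S12(t−u | u),       P02 = 1 − P00 − P01,

summing over the baseline jump times u, where S12(s|u) =
exp(−Λ12,0(s)·exp(η12 + β_t010·u)) so the post-progression survival
depends on when progression happened.  The progression mass at a jump
defaults to m01(u) = P00(u−)(1 − e^{−ΔΛ(u)})ΔΛ01(u)/ΔΛ(u), which is
exactly the law sampled by the inversion-based microsimulation
(`prediction.microsimulate`, the package's independent oracle); the
first-order form P00(u−)ΔΛ01(u) is available as `mass="hazard"` and agrees
to O(ΔΛ²).  Exponentiated cumulative hazards are used rather than
product-limit factors; the difference is likewise O(ΔΛ²).  From the
progression state, P11(s) = S12(s | t010) with the profile's known sojourn
time.  Beyond the last event time baselines are carried forward flat.
Default grids are monthly out to 120 months.

## Prediction error

Predictive performance from time 0 uses the time-dependent Brier score
with inverse-probability-of-censoring weights from the reverse
Kaplan–Meier estimator Ĝ (left limits at event times, Ĝ(t) for subjects
still under observation).  The 0.632+ estimator combines the apparent
error with a bootstrap cross-validation error from repeated training
subsamples drawn **without replacement** (default 300 of 434, 300
replicates, both configurable), the weight driven by the relative overfit
against the all-pairs no-information error.  When evaluating the reduced
model, the entire step-down selection is re-run inside every training
replicate, so model selection is honestly cross-validated.  Evaluation
grids stop at the 95th percentile of follow-up so Ĝ stays bounded away
from zero.  The Kaplan–Meier curve of the training set serves as the
covariate-free null model.  For a constant prediction (the null model) the
no-information error equals the apparent error by construction; the
relative overfit is then defined as 0.

## The synthetic cohort generator

`simulate.generate` draws covariates (age ~ Normal, centered at 60 years in
the hazards; two Bernoulli binaries), latent 0→1 and 0→2 times by
closed-form inversion of subject-specific Weibull cumulative hazards
(cause-specific-hazard construction), post-progression survival from the
1→2 Weibull with the healthy sojourn entering the log hazard, and
independent uniform censoring.  Everything is reproducible from one seed.
The packaged `paper_like_config` (n = 434; Weibull shapes 1.1/1.0/1.1,
scales 72/380/12 months; residual-tumor log-HR 0.6 on all transitions;
FIGO log-HR 1.4 on progression; age 0.05 and 0.015 per year on the death
transitions; t010 −0.028 per month; uniform censoring on (0, 70) months)
was calibrated once against the shape of the ovarian-cancer cohort the
methodology was developed on — about 66% progressing, 5% dying without
progression, three quarters of progressors dying, median follow-up ≈ 35
months — and is frozen.

What the generator does **not** emulate: covariate measurement error,
dependent censoring, ties in recorded times (its times are continuous, so
the half-month tie-breaking rule is exercised only by dedicated unit
tests), cohort heterogeneity beyond the three covariates, and
non-proportional baseline violations.  Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to their violation.  When a test needs the
proportional-baseline start model to be exactly true (e.g. equality-merge
calibration), the generator is switched to a single shared death baseline
with an explicit γ; the default configuration keeps separate death
baselines, under which the proportional-baseline restriction is only
approximately correct — as in real data.

With a shared death baseline and unequal age effects on the two death
transitions, the age centering constant is absorbed into the fitted γ;
recovery studies of γ therefore use equal death-transition age effects.

## Numerical conventions and degenerate inputs

* Ties in progression/death times are resolved by subtracting half a month
  (configurable `delta`) from the progression time; a tie within `delta`
  of the origin is an error, not a silent shift.
* Subjects with zero-length healthy intervals are rejected at stacking.
* A subject censored for progression exactly at the death/censoring time is
  treated as plain censoring for 0→1.
* Expanded design columns are named `<covariate>.<ij>` and
  `<covariate>.shared:<ij+kl>`; the proportionality factor is
  `<name>.gamma`.  Fits are deterministic given the table and structure.
* State probability curves are clipped to [0,1] and forced to sum to one;
  the convolution grid is the union of the relevant baseline jump times.

## Scale of the shipped studies

The simulation studies run at the sizes that keep the full suite quick on a
laptop: 200 replications of n = 2000 for coefficient coverage, 40
replications for merge-decision rates, 50 bootstrap training sets of 300
subjects (of 434) for the prediction-error comparison, and 200 000 paths
for microsimulation cross-checks.  All sizes are arguments, so larger
studies are one flag away.
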