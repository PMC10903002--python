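# Methods

## The problem

Disease-modifying treatments in early Alzheimer's disease are expected to
slow progression, but trials report their effects as point differences on
clinical scales (here CDR-SB, the Clinical Dementia Rating sum of boxes,
range 0–18, higher = worse). A *time-based* reading of the same data —
"the treated arm is where placebo was k months ago" — is easier to
interpret and plugs directly into health-economic models. This package
implements that pipeline end to end on simulated trials:

1. simulate two-arm trials where the active arm's mean trajectory is the
   placebo trajectory evaluated at `(1 − s)·t` (a proportional slowing by
   the fraction `s`);
2. estimate the effect three ways — in months of delay (time-based
   progression model for repeated measures, PMRM), in CDR-SB points
   (constrained longitudinal / MMRM-style model), and as a hazard ratio
   (Cox model on dichotomized progression to dementia);
3. extrapolate an estimated slowing over 15 years with a four-state
   Markov cohort model whose treatment arm runs on a stretched time axis.

## Simulation model

Subjects are observed at months 0, 6, 12, 18, 24, 36 (truncated at the
trial duration: 18, 24, or 36 months). Each subject's visit vector is one
draw from a multivariate normal: placebo subjects centred on the placebo
means `α_j`, active subjects on `L((1 − s)·t_j)` where `L` is the
piecewise-**linear** interpolant of `(t_j, α_j)`; both arms share the
residual covariance `Σ` (unstructured). The default truth is `s = 0.20`.

The packaged default trajectory is a declared fixture, not a cohort
estimate: baseline mean 1.5 points (the typical median severity of an
amyloid-positive MCI trial population), convex worsening to a 2-point
change from baseline at 36 months `(1.5, 1.72, 2.0, 2.29, 2.67, 3.5)`,
visit standard deviations growing from 1.1 to 2.6 points, and
within-subject correlation `0.75^(Δt/12 months)`. With this shape a 20%
slowing on the time axis corresponds to roughly 22–26% vertical
reductions in change from baseline, and roughly a third of placebo
subjects cross the dementia threshold by 36 months — magnitudes a
practitioner would call realistic for this population. Users with real
trajectory/covariance estimates can supply them via the YAML config.

What the generator deliberately does **not** emulate: dropout or any
missingness (scenarios vary only n and duration), the half-point
discreteness and 0–18 bounds of the instrument (scores stay continuous
and unclipped), floor/ceiling effects, and baseline inclusion truncation
(real trial entry requires CDR-SB < 4.5; the simulated baseline is
unconditioned Gaussian). Passing tests therefore demonstrate estimator
behaviour under a clean Gaussian repeated-measures law, not robustness
to real-data pathologies.

## Time-based PMRM

Mean structure: placebo mean `α_j` at visit `j`; active mean
`g(t_j − Δ_j)` for post-baseline visits, where `g` is a **natural cubic
spline** through `(t_j, α_j)` with linear extrapolation beyond the visit
range; baseline means are shared across arms (randomization). One free
delay `Δ_j` per post-baseline visit — proportionality of the slowing
across visits is *not* assumed; the per-visit percent slowing is
`Δ_j / t_j`. Residuals are multivariate normal with unstructured `Σ`.
Note the deliberate asymmetry: data are *generated* with linear
interpolation of the mean curve, but *fitted* with a spline reference
curve. The resulting bias is the spline-vs-linear interpolation error —
a fraction of a month at every visit for the default fixture, which is
under one percentage point on the percent scale except at the 6-month
visit where dividing by t = 6 inflates it to about two points.

Estimation is full maximum likelihood (not REML; with ≥ 200 subjects per
arm the small-sample variance bias is negligible). Because the mean
structure is saturated, `Σ` is profiled out in closed form: for fixed
mean parameters the ML covariance is the mean residual scatter
`S(α, Δ)`, and the profile objective is `log det S(α, Δ)` — a function
of the per-arm visit means and pooled within-arm scatter only, so fit
cost is independent of n. The optimizer is L-BFGS-B with an exact
analytic gradient (spline evaluation at fixed knots is linear in the
knot ordinates, so the warped active means and their derivatives are
matrix products), started from (a) a warm start that inverts the
reference curve at the constrained-longitudinal fitted active means and
(b) the best of a proportional-delay grid `{0, 10, 20, 30}%`; the best
polished solution wins. Delays are box-constrained to `|Δ_j| ≤ t_j`
(the active arm cannot be warped to before baseline). Convergence:
optimizer success, or a stalled line search with max gradient < 1e−5.

Standard errors come from the inverse observed information of the mean
parameters with `Σ` fixed at its ML value (mean and covariance blocks
are orthogonal for Gaussian likelihoods), computed by central finite
differences. The "treatment effect detected" event is a two-sided Wald
test on `Δ` at the final visit at α = 0.05; Wald confidence intervals
are available on the month or percent scale.

Degenerate inputs: with zero residual scatter (noise-free test data) the
likelihood is singular and the fit falls back to exact least-squares
interpolation with no standard errors. A non-monotone fitted placebo
trajectory emits a warning (the delays remain defined).

## Comparators

**MMRM/cLDA.** Default is the constrained longitudinal data analysis
model: shared baseline mean, free arm-by-visit means post baseline,
unstructured `Σ`, ML via iterative GLS ("flip-flop": exact conditional
updates of means given covariance and vice versa, monotone in the
likelihood, tolerance 1e−10 relative). The reported effect is the
final-visit change-from-baseline difference (placebo − active), its
percent of the placebo change, GLS standard error, and Wald p. A classic
change-from-baseline MMRM with the centred baseline as a per-visit
covariate is available (`model="cfb"`). On the same data the cLDA
placebo means coincide with the PMRM's fitted placebo means (both
likelihoods are saturated in the placebo cells), which is asserted in
the tests.

**Cox PH.** Progression to dementia is the first post-baseline visit
with CDR-SB ≥ 4.5; baseline values never count as events (a subject
simulated above threshold at baseline still needs a post-baseline
crossing); never-crossers are censored at their last visit. Events sit
exactly at the handful of visit times — no interval-censoring
correction is attempted — so ties are heavy and Efron's method is the
default (a Breslow option exists; with ties this sparse it is visibly
biased toward zero). The fit is lifelines' partial-likelihood Newton
solver at precision 1e−9, cross-checked in the tests against a
brute-force Efron partial-likelihood enumeration. Zero events or failed
estimation yield a fit flagged non-estimable.

## Replication harness

`run_study` crosses per-arm sample sizes (default 200–700) with
durations (18/24/36 months), simulates `n_replicates` trials per
scenario, fits all three models per replicate, and reports per-scenario
medians (PMRM % delay and months at the final visit, MMRM % reduction
and points, Cox HR) and empirical power. Per-replicate seeds derive from
the master seed and the scenario coordinates via `SeedSequence` spawn
keys, so results are bit-reproducible and independent of execution
order. Medians are taken over converged fits only; a convergence rate
below 95% in any scenario aborts the run. Tables render with percent
effects to whole percent and hazard ratios to two decimals.

Problem sizes: the package's desk-scale default is 200 replicates per
scenario (median stable to ~±1 point, power to ~±0.07 at power 0.5);
1000 replicates is a constructor argument away. The shipped tests run
the delay-recovery check at 200 replicates (n = 700/arm, 36 months) and
the power-ordering and type-I checks at 500 replicates on n = 200/arm
scenarios, where power is far from 1 and the ordering is informative.

## Markov cohort model

Four states — MCI due to AD → mild AD dementia → moderate-to-severe AD
dementia → death — with no back-transitions, all cohort mass starting in
MCI, monthly cycles, 15-year (180-month) horizon, constant intensities.
Monthly mortality is 0.3 / 0.5 / 1.0 % in the three alive states; annual
progression probabilities 23% (MCI→mild) and 39% (mild→mod-severe)
convert to monthly via `1 − (1 − p)^(1/12)`. Within a cycle the
competing risks resolve as: state-specific death first, progression
applied to survivors (default); an alternative ordering (progression
first, with progressors exposed to the destination state's mortality)
is available as a sensitivity switch and moves 15-year survival by
under half a month.

Time in state integrates occupancy over time by the trapezoid rule on
the cycle grid — for equal cycles this is exactly the classical
half-cycle correction (first and last occupancy weighted ½) — truncated
at the horizon. The treatment arm traverses the *identical* occupancy
trace but cycle k ends at `(1 + s)·k` months; the straddling cycle
contributes only its within-horizon fraction. Oracle property (tested):
with a very large horizon every time-in-state equals exactly `(1 + s)`
times its placebo value, so truncation is the only mechanism that keeps
time in the moderate-to-severe state from growing. The slowing fed to
the model defaults to 0.19 and can be taken from a converged PMRM fit
via `from_pmrm` (final-visit percent slowing, unrounded). Outcomes are
time in each state and restricted mean survival only — no costs,
utilities, discounting, or treatment waning.

## Known limitations

- Gaussian, complete-case, fixed-schedule data only; no dropout,
  missingness handling, or covariates.
- ML (not REML) inference; Wald tests can be slightly liberal at the
  smallest sample sizes.
- Only the per-visit time-based PMRM variant is implemented (no
  proportional-slowing or proportional-reduction parameterizations).
- The Markov model uses constant intensities and a deterministic cohort
  (no microsimulation, no parameter uncertainty propagation).
- The default trajectory and covariance are packaged fixtures chosen for
  realism, not estimates from any cohort; conclusions about real trials
  require user-supplied trajectories.
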