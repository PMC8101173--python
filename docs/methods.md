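# Methods

## Scope and models

`hazstrat` fits and diagnoses the two standard families of hazard
regression for right-censored survival data, and orchestrates the
diagnostics into two step-by-step fitting procedures.

**Multiplicative family.** The Cox model
λ_i(t | x_i) = λ₀(t) exp(x_i′β) with two extensions: non-log-linear effects
λ₀(t) exp(f(x)′β) through a library of functional forms f (identity,
exp(x/c), polynomials, fractional polynomials with powers in
{−2, −1, −½, 0, ½, 1, 2, 3}, truncated-power cubic splines, and
threshold forms that add the base form of (x − c) above a cut-off), and
time-varying coefficients λ₀(t) exp(x β(t)) with β(t) expanded on a small
basis: constant; β₀ + β₁t; β₀ + β₁t + β₂(t − c)·I(t > c).

**Additive family.** Aalen's nonparametric model
λ_i(t | x_i) = λ₀(t) + x_i′α(t), summarised through the cumulative
regression functions B_k(t) = ∫₀ᵗ α_k(s) ds, and Lin's (Lin–Ying)
semiparametric special case λ_i(t | x_i) = λ₀(t) + x_i′γ with constant
coefficients. The same functional-form library applies to f(x).

Conventions throughout: time origin 0, episodes are half-open intervals
(start, stop], and a subject is at risk at t when its follow-up time is
≥ t, so a subject is at risk at its own event time.

## Estimation

**Cox partial likelihood.** Newton–Raphson starting at β = 0, tolerance
10⁻⁹ on the score sup-norm, at most 50 iterations, step-halving whenever a
step decreases the log partial likelihood (with a relative slack of
10⁻⁹·(1+|ℓ|) to tolerate the floating-point plateau at the optimum). Ties
are handled by the Efron correction, which reduces exactly to Breslow when
event times are unique; the covariance is the inverse observed information
and the baseline cumulative hazard is the Breslow step estimator. Two
failure modes are distinguished at the optimum by the smallest eigenvalue
of the information (threshold 10⁻⁶ per event): a flat likelihood with
β ≈ 0 is reported as a degenerate design (a column constant within every
risk set), a flat likelihood at large β as monotone likelihood (divergent
coefficient, e.g. perfect separation).

Time-varying coefficient terms are *not* materialised by splitting
episodes at every event time. Because the partial likelihood only ever
looks at risk sets at event times, a covariate-by-time-basis column can be
evaluated directly at each event time inside the likelihood; this is
algebraically identical to episode-splitting at all distinct event times
(a unit test verifies the equality against an explicit split) and avoids
an n × (number of events) blow-up of the data. `split_episodes` is still
provided for user-supplied counting-process data, e.g. external
time-dependent covariates.

Two evaluation paths produce identical results (verified to 10⁻¹³): a
stacked vectorised path used when event times are unique and the stacked
risk sets stay below 4·10⁵ rows, and a per-event-time loop used otherwise
(ties, very large samples). The dispatch is purely a speed optimisation.

**Aalen least squares.** At each ordered event time t_j the increment is
ΔB̂(t_j) = (X_j′X_j)⁻¹ X_j′ dN(t_j) over the at-risk design X_j (intercept
included); the variance increment is the squared hat vector. The at-risk
Gram matrix is maintained by downdating as subjects leave the risk set,
giving O(n·k²) total cost. Estimation stops at the first event time whose
Gram matrix has condition number above 10¹⁰ (reciprocal-condition rule);
the truncation time is reported as `last_estimable_time`. Event times must
be unique (use `jitter_ties`); ties among censoring times are harmless and
accepted. Negative cumulative effects are legal output and are not
clipped.

**Lin–Ying estimating equation.** γ̂ = A⁻¹b with
A = ∫ Σ_{i at risk}(x_i − x̄(t))(x_i − x̄(t))′ dt accumulated exactly over
the inter-exit-time intervals (Lebesgue time integral, not an event sum)
and b = Σ_events (x_event − x̄(t_event)); covariance by the sandwich
A⁻¹ B A⁻¹ with B the outer-product sum of the event residuals. The
baseline is Λ̂₀(t) = Σ_{t_j ≤ t} dN_j/Y_j − ∫₀ᵗ x̄(s)′γ̂ ds. The Methods
literature sometimes describes Lin's model as fitted "by partial
likelihood"; the closed-form estimating equation is the standard estimator
for this model and is what is implemented here.

## Diagnostics

**Schoenfeld residuals and the PH test.** One residual row per event:
r_j = z_(j)(t_j) − the exp(z′β̂)-weighted risk-set mean. The
proportional-hazards test is the Pearson correlation between each
column's residuals and the rank order of event times, with the two-sided
t-test p-value; the assumption is called satisfied when p > 0.05. The
unscaled residuals are used (the scaled Grambsch–Therneau variant is not
part of the fitting strategy). Residual columns that are identically zero
have no information and are reported as satisfied with p = 1. Measured on
1000 simulated proportional-hazards datasets (n = 500, binary covariate,
β = 0.5, exponential baseline, ≈30% censoring) the empirical type-I error
is ≈0.04.

**Martingale residuals.** m_i = d_i − Λ̂₀(T_i)·exp(z_i′β̂) (for the null
model, d_i minus the Nelson–Aalen estimate); they sum to zero exactly at
the fitted coefficients by the Breslow score identity. The lowess smooth
of null-model residuals against a continuous covariate (span 2/3, 3
robustness iterations) estimates the covariate's functional form; the
smooth is trusted in the central bulk only — tails are unstable and
martingale residuals saturate at 1, so very strong effects curve the
smooth even on the correct transform scale.

**Functional-form scan.** Each candidate form is fitted univariately and
ranked by AIC = −2ℓ(β̂) + 2k with k the number of regression coefficients;
a flatness score (maximum absolute deviation of the fitted model's
residual smooth from its mean) is reported alongside as an advisory
quantity. Candidates that are non-finite on the observed range (e.g. log
of a non-positive covariate) are skipped with a note.

**Breakpoint scan.** For each candidate break time c, the model with
basis β₀ + β₁t + β₂(t−c)I(t>c) is fitted and the AIC profile returned;
the minimiser is selected with ties broken toward smaller c, and grid
points with no events on one side are skipped.

**Pseudo-observations.** Ŝ_i(t) = n·Ŝ(t) − (n−1)·Ŝ^(−i)(t) from
leave-one-out Kaplan–Meier. The leave-one-out curves are computed by an
exact incremental adjustment of each product-limit factor for the removed
subject's at-risk status and own event (ties handled), equal to n full
refits to ~10⁻¹³; the naive refit is kept as the test oracle. The default
grid is the nine deciles of the uncensored event-time distribution
(linear-interpolation quantiles, h = (n−1)p indexing; duplicates
collapsed with a warning). For the assumption checks, pseudo-values are
lowess-smoothed against the covariate *first*, clamped into
[10⁻⁶, 1−10⁻⁶] (clamp events counted and reported), then transformed:
cloglog log(−log s), linear in z with slope β under a log-linear
proportional-hazards model; scaled-log −log(s)/t, linear in z with slope γ
under a constant additive model. Two numerical choices matter here and
are deliberate:

* the pseudo-value smoother uses **no** lowess robustness iterations —
  with little censoring pseudo-values are legitimate 0/1 extremes and
  robust reweighting discards the minority outcome wholesale, flattening
  every curve;
* per-curve slopes and linearity scores are computed on the clamp-free
  region only, because the transform is saturated where the smooth left
  (0, 1) and those plateaus would otherwise dominate the least-squares
  slope.

With these choices the nine cloglog curve slopes recover a true β = 0.8
within ±0.05 at n = 2000, and the scaled-log slopes a true γ = 0.3
within ±0.03. Linearity is scored as the maximum deviation of a curve
from its secant divided by the curve's range; parallelism as the mean
absolute pairwise difference of the nine slopes. Both are advisory
operationalizations of a visual judgement, with configurable thresholds
(default 0.1).

**Martingale residual processes (additive GOF).** For strata g (quantile
groups of a continuous covariate, or levels of a categorical one),
M_g(t) = Σ_{i∈g} [N_i(t) − ∫₀ᵗ Y_i(s)(dB̂₀ + x_i′dB̂)]. Because the Aalen
increments are least-squares projections, the drift cancels exactly and
M_g(t) = Σ_i ∫₀ᵗ w_{g,i}(s) dM_i(s) with projection-corrected weights
w_{g,i}(s) = I(i∈g) − (Σ_{l∈g∩R(s)} x̃_l)′(X′X)⁻¹x̃_i. Confidence bounds
and test variances come from wild-bootstrap resampling: one standard
normal multiplier per subject applied to the estimated per-subject
integrals (default 500 replicates, seeded). Without the projection
correction the resampling is conservative; with it, the global chi-square
test's empirical type-I error is ≈0.04–0.05 at n = 800. The
end-of-follow-up tests are M_g(τ)²/Var̂ against χ²(1) per stratum, and the
quadratic form M′Σ̂⁻M (pseudo-inverse of the resampling covariance,
df = rank) globally; strata saturated in the design have M_g ≡ 0 exactly,
which is detected by a numerical-zero guard on the resampling variance
(relative to the event-count scale) and reported as p = 1.

**Constant-effect check (Lin vs Aalen).** The graphical device overlays
Lin's straight line γ̂_k·t on Aalen's cumulative B̂_k(t). The automated
verdict asks whether |γ̂_k·t − B̂_k(t)| stays within
1.96·(SE[B̂_k(t)] + t·SE[γ̂_k]) on at least 95% of the event-time grid,
after discarding the first 10% of events. The combined band is used
because the Aalen band alone ignores the line's own sampling variability
and falsely rejects constancy — 8–14% per covariate at n = 1000 in a
two-covariate design in our measurements, with the excursions
concentrated at early event times where a pointwise-normal band built
from one or two increments is meaningless (hence the burn-in). With the
combined band the false-non-constant rate is below 1%, an early-only
effect (α = 0.6 for t < 0.5, then 0) is detected in 40/40 replicates, and
a constant effect is correctly called constant in 200/200. The price is
reduced sensitivity to slow gradual drifts of α(t) (a halving of the
effect over follow-up is detected only ~3% of the time at n = 1500);
the overlay plot remains the tool for judging those.

**Arjas curves.** Per stratum, expected cumulative events (x) against
observed (y) at each event time: expected =
Σ_{i∈g} ∫₀^{min(T_i,t)} exp(z_i(s)′β̂) dΛ̂₀(s) for Cox fits (the Breslow
identity makes the totals over all strata match observed events exactly)
and Σ_{i∈g} ∫ (dB̂₀ + x_i′dB̂) for Aalen fits (exactly on the diagonal for
saturated categorical strata). The advisory verdict integrates the signed
observed-minus-expected difference over event time and compares it to a
95% wild-bootstrap threshold built from the same projection-corrected
per-subject increments; for Cox fits the first-order influence of β̂
(Lin–Wei–Ying decomposition through the observed information) is
subtracted as well, without which the threshold misses mid-follow-up
deviations that cancel at τ. Under a well-specified model the
any-stratum advisory flag fires in roughly 10% of replicates (four
correlated strata at the 5% pointwise level); the curves themselves are
the primary output.

## The two fitting procedures

The automated strategies mirror the manual workflow: the multiplicative
arm checks log-linearity (residual smooths + AIC scan), proportional
hazards (Schoenfeld correlation test, escalating a flagged covariate to
the linear-in-t basis and only then to linear-with-break, with the break
chosen by AIC scan), both assumptions simultaneously (cloglog
pseudo-observation curves), goodness-of-fit (Arjas), and finally the
multivariate model (PH test + Arjas), iterating to a configurable cap
(default 5) because "repeat until satisfied" has no termination
guarantee. The additive arm checks linearity (scaled-log pseudo curves +
MRP chi-square over quantile strata, advancing through candidate forms),
constant effects (below; all constant ⇒ Lin's model,
otherwise Aalen's), Arjas curves for continuous covariates (skipped for
categorical ones, where observed and estimated events agree exactly), and
the multivariate MRP check.

Where the manual procedure reads a plot, the automation needs a decision
rule; four choices are deliberate. (1) A functional-form switch requires
an AIC improvement > 2 (the usual "essentially equivalent" band), so
near-equivalent transforms do not churn. (2) The additive arm accepts or
rejects a functional form on the *global* MRP chi-square p-value; the
per-stratum p-values are logged, and the `mrp_chisq_test`
verdict field still flags any stratum below α for the analyst. (3) The
purely graphical diagnostics (pseudo-curve scores, Arjas areas) are
computed, scored and logged but advisory: they do not trigger automatic
revisions, since their false-alarm behaviour is not controlled at a known
level. (4) The revision-driving assumption tests are computed on the
model containing *all* covariates at their current specification rather
than on univariate fits: a univariate screen tests the covariate's
marginal hazard, which is non-proportional by construction whenever other
covariates have effects (the omitted-covariate artifact), and stacking
weakly correlated univariate and multivariate 5%-level tests pushed the
procedure's spurious-revision rate to ~15% on assumption-satisfying data;
with the adjusted-model tests (and a shared resampling seed for the
repeated multivariate check) the per-covariate screen and the final check
coincide on a clean run and the measured unmodified-model rates are 0.90
(multiplicative) and 0.97 (additive) at n = 1000 with two covariates.
Every decision is written to an ordered audit report (JSON) whose
`final_model` block is sufficient to re-execute the final fit; identical
data + config + seed give byte-identical reports. When several covariates
fail a step simultaneously they are processed in the sample's column
order.

## Synthetic data

The generators sample event times by inverse transform of each subject's
cumulative hazard, with coefficient paths β(t)/α(t) and the piecewise-
constant baseline discretised on a grid of step ≤ 10⁻³ × horizon (hazard
approximation error ≤ grid step × max |path slope|); beyond the grid the
terminal hazard applies, so the tail is sampled exactly. Additive
scenarios are validated for a non-negative total hazard on the realised
covariate support before sampling. Covariate distributions: normal,
uniform, Bernoulli. Censoring: administrative time and/or independent
exponential.

The TRACE-like fixture emulates an infarction cohort of n = 1878:
age ~ N(67, 11.4²); binary prevalences 52.29% (chf), 69.54% (sex),
10.01% (dia), 7.24% (vf); a decreasing piecewise baseline (an
early-mortality spike over the first 0.15 y, then a low chronic rate)
giving a survival median near 6.5 y; an exponential age effect
(2.87·exp(age/100)), a linearly decaying chf effect (0.95 − 0.08t),
an early-only vf effect (2.24 falling to 0 by t = 0.15) and constant sex
(0.18) and dia (0.35) effects; administrative censoring at 8.5 y. It is a
qualitative analogue for end-to-end strategy tests — the generating
mechanism is multiplicative, so the additive arm correctly identifies
non-constant effects and model misfit on it — and is not intended to
reproduce any cohort's published estimates.

What the generators do *not* emulate: dependent censoring, covariate
measurement error, clustering, recurrent events, delayed entry. Passing
tests therefore demonstrate correctness of the estimators and calibration
of the diagnostics under independent censoring and correctly specified
(or deliberately misspecified) hazard structure, not robustness to those
complications.

## Study sizes used in the validation suite

The Monte-Carlo studies in the test suite use these problem sizes, chosen
as the smallest at which the asymptotic calibration of each tool is
expected to hold: PH-test type-I error from 1000 replicates at n = 500;
MRP chi-square type-I error from 300 replicates at n = 800 with 200
bootstrap replicates (the library default stays at 500); power studies at
n = 500 (PH) and n = 2000 (MRP); Wald-interval coverage from 300
replicates at n = 800 per estimator; strategy end-to-end behaviour from
50 replicates at n = 1000 per arm, with assertions on estimated rates
allowing two binomial standard errors at the replicate count used. The
acceptance script re-runs the same studies at similar or slightly reduced
replicate counts.

## Known limitations

* No stratified Cox, frailty, penalized likelihood or robust (sandwich)
  variance for the multiplicative family; no weighted Aalen least squares.
* The PH correlation test is mildly conservative (type-I ≈ 0.04 at
  nominal 0.05) — consistent with its use of unscaled residuals.
* Pseudo-observation curves need ≥ 10 events for the decile grid and are
  computed for time-fixed continuous covariates only.
* The β̂-influence correction in the Cox Arjas calibration is first-order;
  the verdict is advisory by design.
* CSV is the only ingest format; categorical covariates are dummy-encoded
  at load with the first-observed level as reference.
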