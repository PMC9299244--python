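# Methods

## The problem being modelled

Sequential vaccine-safety surveillance on routinely collected health data
re-estimates a vaccine–outcome association every calendar month as data
accumulate, declaring a signal when the evidence crosses a pre-specified
boundary. Because the data are observational, every design carries
systematic error; because the hypothesis is re-tested monthly, naive
thresholds inflate the false-positive rate. This package evaluates how
design choice, sequential testing (MaxSPRT) and negative-control empirical
calibration interact, on synthetic data where the truth is known.

## Synthetic data generator

Time is measured in integer days; person-years use 365.25 days. The default
calendar is a 9-month study period (2009-09-01 to 2010-05-31) preceded by a
same-length historic period one year earlier.

Per person: sex (53% female), age uniform 18–80 at study start, a latent
standard-normal *health-seeking* score `h`, and a mean-one log-normal
*frailty* `f` with log-scale s.d. `frailty_sd`. Observation periods start
well before the historic period for `eligible_fraction` (default 0.95) of
persons; 5% are right-censored inside the study period.

* **Visits**: homogeneous Poisson, rate
  `visit_rate · exp(a_h·h + a_f·log f)` with `a_h = health_seeking_strength`
  and `a_f = frailty_visit_strength`. Default 2.5/year.
* **Vaccination**: monthly discrete hazard `uptake_curve[m] · exp(a_h·h +
  b_f·log f)` (`b_f = frailty_uptake_strength`), clipped at 0.95; day uniform
  within the month. A configured fraction receives a second dose
  `dose_gap_days` later; at most two doses.
* **Outcomes**: per person and outcome, an inhomogeneous Poisson process
  with rate `λ0 · f · season(t)`, multiplied by the true rate ratio inside
  each dose's time-at-risk (days +1..+28 inclusive). The boost is realised
  by superposition (baseline process plus an independent excess process at
  `(RR−1)·baseline` inside time-at-risk), which is exact for RR ≥ 1; the
  generator therefore rejects injected effects below 1. `season(t)` is
  `exp(A·cos(2π(doy − peak)/365.25))/I0(A)`, normalised to mean ≈ 1 over a
  year. Only the first event per (person, outcome) is retained, mirroring
  first-occurrence outcome definitions. Baseline rates across the 93
  negative-control outcomes are log-normal around `baseline_rate`
  (default 0.02/person-year, spread 0.5 on the log scale), emulating the
  prevalence spread of a curated negative-control list.

Determinism: every stage draws from a generator derived from
`sha256(seed:stage)`, so identical configurations are byte-identical and
stages can be re-run in isolation.

### The standard confounded scenario

`synthetic_data.confounded_scenario` fixes the conditions under which the
designs display their characteristic biases: `frailty_sd = 0.8`,
`health_seeking_strength = 0.7`, `frailty_uptake_strength = 0.8`,
`frailty_visit_strength = 1.5`, no seasonality, and a pandemic-style uptake
pulse peaking at 0.04/month (≈17% coverage). Two mechanisms matter:

* Coverage must be modest. The cohort design excludes comparator candidates
  vaccinated on or before index; at high coverage the never-vaccinated
  remainder is strongly selected for low frailty/health-seeking, which tilts
  *both* comparator anchors healthy and masks the visit-anchor effect.
* Frailty must drive visits more strongly than uptake. A visit-day
  comparator over-samples frail persons in proportion to their visit rate
  (tilt `1.5·σ²`), the vaccinated in proportion to uptake (tilt `0.8·σ²`),
  so the visit-anchored hazard ratio is biased down while the random-day
  comparator (no tilt) is biased up; the historical comparator and
  case-control, which compare vaccinated against the general population,
  are biased up.

Seasonality is kept at zero here because it adds a second, separate bias
channel (the SCRI control window sits ~2 months off the risk window on the
seasonal curve); the season-adjusted SCCS variant is tested against it
separately.

## Design implementations

**Historical comparator.** Background rate from the historic window, either
over all observed person-time or over the 28-day window after one uniformly
sampled outpatient visit per person. Expected count `u = Σ rate_s × TaR
person-time_s` with TaR truncated at observation end and at the look cutoff.
Stratified variants use 5-year age bands × sex, with age measured at a
common reference day (study start) on both sides so band membership cannot
drift between periods. IRR `c/u` with the exact Poisson (Garwood) CI; the
log-scale SE is recovered from the CI width; the one-sided p is the Poisson
upper tail `P(X ≥ c | u)`. The instability filter drops an outcome at a look
when the overall incidence changed by more than 50% from the historic to the
surveillance period so far.

**Cohort method.** Comparator sampling as described above, at ratio 1
(unadjusted) or 4 (adjusted) times the vaccinated cohort, from data before
the look cutoff only. Covariates are strictly pre-index: age (continuous and
5-year bands), sex, index month, log(1+visits in the prior 365 days), and a
binary history indicator per outcome. The latent frailty and health-seeking
scores are deliberately *not* covariates (confounders missing from the
data); `include_latents=True` adds them for testing that PS adjustment works
when confounding is measured. Propensity scores: L1-penalised logistic
regression, penalty chosen by 3-fold cross-validation. Adjustments: greedy
1:1 nearest-neighbour matching on logit(PS) with a 0.2-s.d. caliper;
quintile stratification (one-armed strata dropped); ATT weights
`PS/(1−PS)` truncated at the comparator 99th percentile; per-month matching
frozen across looks. Outcome model: Cox proportional hazards (Breslow ties)
on time to first outcome within time-at-risk, censored at observation end,
look cutoff, and (comparators) the day before their own vaccination;
stratified by matched pair / PS stratum; the weighted variant uses a robust
sandwich variance.

**Case-control.** Cases are first in-study occurrences up to the cutoff with
365 days of prior observation. Matched variant: up to four controls per case
sharing 5-year age band and sex, outcome-free through the case's outcome
date (their index); conditional logistic regression over sets. Random
variant: controls from all eligible persons with index dates resampled from
the empirical case outcome-date distribution; unconditional logistic with
age-band and sex terms. Exposure is a vaccination in `[index−28, index−1]` —
the mirror image of the time-at-risk, so a vaccination on the index day does
not count. Controls may serve multiple cases (without replacement within a
set), which avoids control exhaustion at desk scale.

**Self-controlled.** Interval construction labels each observed in-study day
risk / control / excluded with precedence risk > excluded > control across
doses. SCCS control time is all non-risk, non-excluded observed time
(exclusion: 30 days before each dose, through day 0; or all pre-vaccination
time in the `sccs_all_pre` variant); SCRI control time is exactly days
−43..−15 (pre) or +43..+71 (post) per dose. The SCCS estimate maximises the
within-person multinomial likelihood (events distribute over a person's
intervals with probability ∝ length × exp(x'β)) by damped Newton iteration
with backtracking line search; the adjusted variant splits intervals at
calendar-month boundaries and adds cubic B-spline bases (5 equally spaced
knots, first column dropped) in age and in study day, evaluated at interval
midpoints. Because the conditioning absorbs between-person level
differences, the spline directions are only weakly identified; they carry a
ridge of 1e-2 while the exposure coefficient is essentially unpenalised
(1e-8). The SCRI estimate is the conditional binomial on pooled interval
lengths with an exact Clopper–Pearson interval mapped to the rate-ratio
scale.

## Sequential testing

MaxSPRT compares, at each monthly look, a log-likelihood ratio on the
cumulative data against a flat critical value whose any-look null crossing
probability is at most alpha = 0.05. Three data models:

* Poisson (historical comparator): `LLR = c·ln(c/u) − (c−u)` for `c > u`.
* Binomial (self-controlled): `c` of `n` events in the risk window against
  null proportion `1/(1+z)`, `z` = control/risk person-time.
* Normal (cohort, case-control, and imputed positives, which are summarised
  by estimate and SE): `LLR = θ̂²/(2·SE²)` for `θ̂ > 0`, with the boundary
  simulated from the Brownian score process at the observed cumulative
  information `1/SE²` per look.

Critical values are the `⌈(1−α)·R⌉`-th order statistic of the per-replicate
maximum null LLR over the look schedule (default R = 1e5; 2e4 inside the
evaluation grid), seeded per (variant, outcome). The single-look Poisson
case is cross-checked analytically in the tests against the exact Poisson
tail. Because the count models are lattice-valued, the attained alpha is ≤
nominal (slightly conservative) rather than exact. Signals persist once
declared.

## Empirical calibration

Negative-control log estimates are modelled as `θ_i ~ N(μ, τ² + se_i²)`.
The likelihood is maximised by profiling μ (precision-weighted mean) and a
grid-plus-refinement search over τ ≥ 0; the homoscedastic case has the
closed form μ = mean, τ² = max(0, MLE variance − se²), used as an oracle in
the tests. Calibrated quantities are plug-in:
`p_cal = 1 − Φ((θ̂−μ)/√(τ²+se²))` and `LLR_cal = (θ̂−μ)²/(2(τ²+se²))` for
`θ̂ > μ`, which reduce exactly to their uncalibrated forms at (μ, τ) = (0,0).
Evaluation uses leave-one-out fits: each control (and the positives imputed
from it) is calibrated against the distribution fitted on all *other*
controls. The plug-in form ignores the sampling error of (μ̂, τ̂), leaving a
small anti-conservative bias of order 1/n_controls — about +0.4 percentage
points on the 5% rate at 93 controls — visible in the calibration
simulation. Imputed positives multiply the estimate by k ∈ {1.5, 2, 4},
carry the SE and counts unchanged (the assumption that systematic error does
not vary with true effect size), and recompute the one-sided p from the
shifted estimate via the normal approximation.

## Performance metrics

Type 1 error: fraction of estimable negative-control records rejected
(one-sided p < 0.05, or LLR > CV in sequential mode). Type 2 error: fraction
of estimable positives of a given true size not rejected. Months to 50%
sensitivity: the earliest look at which at least half of a size's positive
controls have signalled at that or an earlier look; `never` if not reached.
Every grid cell is either an estimable record or an explicit
`estimable=false` record — failures are logged, never silently dropped.

## Problem sizes

The defaults are chosen for single-CPU desk scale: the full acceptance suite
runs 20,000 persons × 93 outcomes for the bias-direction checks (~1 minute),
110 replicates of 3,000 persons for SCCS coverage (~1 minute), and 100 × 93
leave-one-out calibrations (~10 s). The evaluation grid with all 25 variants
× 93 outcomes × 9 looks is feasible in tens of minutes; the shipped examples
use subsets.

## Known limitations

* The generator's confounding is two latent scalars; real claims data have
  richer, time-varying confounding, coding drift and measurement error, so
  passing these tests shows the machinery reproduces the *mechanisms*, not
  that any design is safe on real data.
* First-occurrence outcomes deplete the risk set over time, which perturbs
  the historical comparator (and, mildly, SCCS) at high baseline rates; at
  the default 0.02/person-year the effect is small.
* Injected effects are constant multiplicative boosts over the whole
  time-at-risk; no induction periods or effect decay.
* The normal-model MaxSPRT boundary treats the per-look information as known
  and the score process as Brownian; for very small event counts the
  count-model boundaries are more faithful.
* SCRI with few events relies on the pooled-length conditional binomial,
  which is exact only when interval lengths are equal across persons;
  truncation at observation end makes it approximate.
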