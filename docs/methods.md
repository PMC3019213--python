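# Methods

## Data model

Follow-up of one subject is a sequence of *at-risk intervals* in
counting-process form. Interval *j* is `(start_j, stop_j, delta_j)` with an
event type attached at `stop_j` (`locoregional`, `contralateral`,
`metastasis`, `second_cancer`, `breast_cancer_death`, or `censor`). On the
age-calendar timescale the first interval opens at the entry age (age at
surgery): subjects are **left-truncated** — never at risk before entry — and
risk sets at an event age contain exactly the intervals with
`start < age <= stop` (half-open convention: a subject is not at risk at
her entry age itself). `breast_cancer_death` and `censor` are terminal;
death from other causes is coded as censoring. Ties between a subject's own
events are rejected rather than perturbed. Two alternative timescales are
pure re-expressions that preserve every duration and indicator: *gap*
(each interval restarts at 0) and *surgery-calendar* (origin shifted to the
entry age).

Times are decimal years throughout; there is no date arithmetic.

## Event-dependence covariates

Two time-dependent summaries of a subject's past can be attached to each
interval: the **number of prior events**, either as four classes
{0, 1, 2, >=3} dummy-coded against 0 (three indicators for four classes) or
as a linear count; and the **type of the subject's first event** (reference:
no previous event), with a switch to track the most recent event instead.
Because an interval of rank *j* is always preceded by exactly *j−1* events,
these covariates are functions of rank.

## Cox model with delayed entry

The partial likelihood, its analytic gradient and Hessian are implemented
directly for `(start, stop]` data, with Efron (default) and Breslow tie
conventions — the two coincide exactly on tie-free data. Newton–Raphson
with step-halving declares convergence when the relative log-likelihood
change is below 1e−9 and the score norm below 1e−6. Monotone likelihoods
(complete separation) are detected by coefficient divergence and reported
as an error rather than returned. Relative risks use log-symmetric 95% Wald
intervals `exp(beta ± 1.96 se)`. Descending stepwise selection drops whole
covariate blocks (a categorical covariate's dummies together) on block Wald
tests at level alpha. Per-event-type analyses treat one type as the failure,
everything else as censoring, on rank-1 intervals (time to first failure).

## Shared gamma-frailty model

Conditional hazard `Z_i * lambda0(t) * exp(beta'X_ij)` with
`Z_i ~ Gamma(1, theta)` i.i.d. at the time origin. The gamma integral is
closed-form; per subject with `m_i` events and accumulated hazard
`Lambda_i = sum_j [Lambda0(stop_j) − Lambda0(start_j)] exp(beta'X_ij)`:

```
ll_i = sum_events [log lambda0 + beta'X]
     + sum_{k=0}^{m_i−1} log(1 + k theta)
     − (1/theta + m_i) log(1 + theta Lambda_i)
```

computed with `log1p` so it is continuous down to `theta = 0`, where the
Poisson/no-frailty form is used. Left truncation with frailty: hazard is
accumulated only over observed at-risk intervals, the frailty distribution
being taken at the time origin; the likelihood is therefore not additionally
conditioned on event-free survival to entry — an approximation, acceptable
here because entry (age at surgery) is the start of observation, not a
selection on prior event history.

**Baseline hazard.** Cubic B-spline with 8 interior knots (default) at
event-time quantiles, boundary knots at the data range. Coefficients are
optimized on the log scale, so `lambda0 >= 0` everywhere, `Lambda0` is
non-decreasing and `Lambda0(lower boundary) = 0` by construction. The
roughness penalty `kappa * Int lambda0''(u)^2 du` is exact in the basis
(`c'Pc` with `P` assembled by 3-point Gauss–Legendre per knot span, exact
for the piecewise-quadratic integrand).

**Smoothing parameter.** `kappa` has units; a fixed absolute value that is
negligible on an 80-year age scale oversmooths a 3-year gap-scale stratum
by five orders of magnitude. The default is therefore expressed as a
dimensionless scale, `kappa = s · T^3 / lambda_bar^2` with `T` the data
range and `lambda_bar` the crude event rate. `s = 1.0` was fixed once by
2-fold held-out marginal likelihood on the default synthetic cohort
(grid 1e−6…1e3; the held-out curve is flat within ~10 log-likelihood units
over s ∈ [0.1, 10] and degrades outside). Any absolute `kappa` can be
passed instead; the resolved value is recorded in the fit metadata.

**Optimization and inference.** L-BFGS-B over (log spline coefficients,
beta, log theta) with the exact analytic gradient. `theta` is bounded below
at 1e−8 on the log scale; an estimate pinned there is reported as
`boundary_theta` with no standard error (no mixture-chi-square boundary
test is attempted). Standard errors come from the inverse observed
information of the **penalized** marginal likelihood (central finite
differences of the analytic gradient), a known approximation that is
flagged in the metadata; `se(theta)` uses the delta method from the log
scale. Posterior frailties are the gamma-conjugacy means
`E[Z_i | data] = (1/theta + m_i)/(1/theta + Lambda_i)`, which satisfy
`sum_i E[Z_i](1/theta + Lambda_i) = sum_i (1/theta + m_i)` exactly.

**AIC.** `2k − 2 loglik_marginal` with `k` = #beta + 1 (theta) + all spline
coefficients — a deliberate, reproducible convention (no effective-degrees
correction), monotone in basis size and recorded in the fit metadata; it is
meant for comparing models on the same cohort with the same basis, nothing
more.

**Hazard curves.** Rank- and type-specific curves come from separate
penalized fits per stratum (intervals of one rank, or one event type as
failure), on any timescale, with pointwise delta-method bands from the
spline-coefficient covariance. Per-stratum fits hold `theta = 0`: a stratum
contains at most one event per subject, so the frailty variance is not
identifiable stratum-wise. Strata under a minimum event count (default 10)
are skipped with a warning.

## Joint frailty model for informative death

Recurrence hazard `Z_i r0(t) e^{beta_r'X}` and death hazard
`Z_i^alpha lambda0_D(t) e^{beta_d'X}` share the frailty; `alpha = 0` makes
death non-informative (the likelihood factorizes — checked to 1e−8 in the
tests), `alpha = 1` folds death into the single-frailty closed form (exact
oracle in the tests). The per-subject frailty integral uses generalized
Gauss–Laguerre quadrature matched to the rate `1/theta + Lambda_r_i`, which
absorbs the recurrence exponential into the weight exactly; at `alpha = 1`
the rule is then exact to machine precision, and for fractional `alpha`
accuracy is limited by the `z^alpha` kink at the origin (~1e−5 at 32 nodes
in unfavourable corners). The default 32 nodes are doubled automatically
when doubling still moves the log-likelihood by more than 1e−6. Both
baselines carry their own roughness penalty with the same auto-scaled
default. When `theta` is estimated at the boundary, `alpha` is flagged as
unidentifiable.

## Synthetic cohorts

The generator emulates the structure of a breast-conserving-surgery cohort
with known truth: per subject it draws covariates, a gamma frailty, a
truncated-normal entry age (mean 56.7, sd 11, min 29 years), a uniform
administrative horizon (12–16 years after surgery), then generates
successive event times by **exact Weibull inversion** of the conditional
cumulative hazard `Z rho^min(k,3) Lambda0 e^{beta'x}` (no discretization
bias), assigns event types multinomially (locoregional/contralateral/
metastasis/second-cancer ≈ 34/16/43/7%), and lets a death process with
frailty power `alpha` and its own per-prior-event multiplier compete as the
terminal event. All draws come from one seeded generator in a fixed
per-subject order, so equal seeds give bit-identical cohorts.

Default parameters (frailty variance 0.38, dependence multiplier 1.97,
combined-analysis-scale covariate effects) were calibrated once so the
defaults reproduce the published cohort structure: ~0.62 events per
subject, ~63% event-free, event counts concentrated on 0–4. Two structural
choices matter: the dependence multiplier saturates after three prior
events (mirroring the >=3 top count class — an uncapped `rho^k` is
explosive), and the death hazard rises after recurrences (multiplier 8 per
prior event, capped likewise), which is what truncates long event cascades
in real data, where most deaths follow a recurrence.

What the generator does **not** emulate: covariate correlations (marginals
only), calendar-period effects, non-proportional covariate effects,
visit-schedule interval censoring, and recurrence-type-specific covariate
effects. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to these violations.

## Problem sizes used in the test battery

Oracle comparisons run on ~100 randomized cohorts of ≤8 subjects (where
quadrature and enumeration are exact and fast). Recovery studies use 50
replicates of 500 subjects at ~1 event/subject — chosen as the smallest
sizes at which the frailty variance is well identified (at the sparser
default event density, theta has a sampling sd of ~0.4 and single-cohort
estimates are uninformative). The no-frailty degeneracy check uses one
800-subject cohort. The pipeline test uses 150 subjects.

## Known limitations

- Standard errors ignore the smoothing bias of the penalized baseline and
  the selection of `kappa`.
- The entry-conditioning approximation above matters if frailty also drives
  selection into the cohort before entry.
- The joint model's quadrature accuracy degrades for `alpha` far below 1
  with large `theta`; the node-doubling check reports, but cannot fully
  remove, this.
- AIC values are comparable only within a fixed basis/penalty convention.
- One shared covariate-effect vector across event types (type enters only
  through the first-event covariate and type-specific baselines); a
  multivariate model with one hazard per type is out of scope.
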