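# sharedfrailty

Shared gamma-frailty and joint frailty survival models for **multi-type
recurrent events with delayed entry**, built for cohorts like women followed
after breast-conserving surgery: one subject may successively experience a
locoregional recurrence, a contralateral tumour, distant metastases, a
second primary cancer, and finally die of her disease. Analysing only the
first of these events wastes information and cannot say whether a woman who
relapses once is more likely to relapse again; analysing all of them
together requires a model for the correlation they induce.

## Who this is for

Biostatisticians and epidemiologists who need to

- tabulate gap times between successive events of several types,
- fit Cox models with **left truncation** (age as the basic timescale:
  a subject is at risk only from her age at surgery onward),
- fit a **shared gamma-frailty model** over all events per subject with a
  smooth, penalized spline baseline hazard,
- separate **unobserved heterogeneity** (frailty) from **event dependence**
  (prior events raising the hazard of the next one),
- probe **informative censoring by death** with a joint frailty model, and
- generate synthetic cohorts with known truth for all of the above.

## The model

The hazard of subject *i* on her *j*-th at-risk interval is

```
lambda_ij(t | Z_i, X_ij) = Z_i * lambda0(t) * exp(beta' X_ij)
```

with `Z_i ~ Gamma(mean 1, variance theta)` shared by all of the subject's
intervals. Integrating `Z_i` out gives a closed-form marginal likelihood:
a subject with `m_i` events and accumulated hazard `Lambda_i` contributes

```
sum_events [log lambda0(t) + beta'X]
  + sum_{k=0}^{m_i-1} log(1 + k*theta)
  - (1/theta + m_i) * log(1 + theta * Lambda_i)
```

`theta = 0` recovers the ordinary Cox/Poisson form. The baseline hazard
`lambda0` is a cubic B-spline with non-negative coefficients, estimated by
maximizing the marginal likelihood minus `kappa * Int lambda0''(u)^2 du`.
Event dependence is modelled with time-dependent covariates: the number of
prior events (four classes 0/1/2/>=3, or a linear count) or the type of the
subject's first event. The joint model for informative death gives the death
hazard its own baseline and coefficients and couples it to recurrence
through `Z_i^alpha`.

## Worked example

```python
from sharedfrailty import (SimulationParams, simulate_cohort, summarize_gap_times,
                           fit_shared_frailty, prior_event_covariates, compare_models)

cohort, truth = simulate_cohort(SimulationParams(n_subjects=919, seed=1))
s = summarize_gap_times(cohort)
print(f"events per subject: mean {s.events_per_subject_mean:.2f}")

covs = ["grade", "positive_nodes", "pr_negative", "tumor_size_mm"]
m1 = fit_shared_frailty(cohort, covs)                              # Model 1
coded = prior_event_covariates(cohort, "count_linear")
m2 = fit_shared_frailty(coded, covs + ["prior_count_linear"])      # Model 2
```

Output (printed by the snippet plus a `compare_models` call):

```
simulated 919 subjects, 572 events
events per subject: mean 0.62, range (0, 7)

Model 1 (no event-dependence covariate):
  theta = 2.56 (SE 0.31), AIC = 4007.02
Model 2 (+ number of prior events):
  theta = 0.64 (SE 0.19), AIC = 3870.40
  prior-event count: RR 2.48 (95% CI 2.14-2.88)
```

Read: without an event-dependence covariate, the cascade of successive
events masquerades as enormous between-subject heterogeneity
(`theta = 2.56`). Adjusting for the number of prior events absorbs most of
it (`theta` drops to 0.64, AIC improves by 137), and each prior event
multiplies the hazard of the next by ~2.5 — the generator's true dependence
multiplier is 1.97, inflated here because frailty and dependence are
partially confounded at this event density.

The same analyses are scriptable from a shell:

```
sharedfrailty simulate --n 919 --seed 1 --out cohort.csv
sharedfrailty summarize --input cohort.csv
sharedfrailty fit-frailty --input cohort.csv --model 2 \
    --covariates grade,positive_nodes,pr_negative,tumor_size_mm
sharedfrailty report --config analysis.yaml
```

`report` writes the full bundle: gap-time table, five per-event Cox tables,
frailty Models 1–3 with the AIC ladder, rank- and type-specific hazard
curves on the age and time-since-surgery scales, and a manifest of every
decision knob.

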