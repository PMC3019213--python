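"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from sharedfrailty import (
    Cohort,
    CovariateSchema,
    EventType,
    RiskInterval,
    SubjectHistory,
)
from sharedfrailty.event_history import CovariateSpec
from sharedfrailty.synthetic import CovariateSim, SimulationParams, simulate_cohort

# ---------------------------------------------------------------------------
# cohort builders


def interval(start, stop, indicator, etype, rank, cov=None):
    return RiskInterval(start, stop, indicator, EventType(etype), rank, cov or {})


def subject(sid, triplets, entry=None, cov=None):
    """triplets: list of (start, stop, indicator, type)."""
    ivs = tuple(
        interval(s, e, d, t, j + 1, cov) for j, (s, e, d, t) in enumerate(triplets)
    )
    return SubjectHistory(sid, ivs, entry if entry is not None else triplets[0][0])


def numeric_schema(*names):
    return CovariateSchema(tuple(CovariateSpec(n) for n in names))


def random_toy_cohort(seed: int, max_subjects: int = 8, p_cov: int = 1) -> Cohort:
    """Small random event-history cohort with continuous (tie-free) times."""
    rng = np.random.default_rng(seed)
    n = rng.integers(2, max_subjects + 1)
    subjects = []
    for i in range(n):
        entry = rng.uniform(0, 2)
        cov = {f"x{k}": float(rng.normal()) for k in range(p_cov)}
        t = entry
        ivs = []
        n_iv = rng.integers(1, 4)
        for j in range(n_iv):
            dur = rng.uniform(0.2, 3.0)
            last = j == n_iv - 1
            if last:
                died = rng.random() < 0.5
                ivs.append(
                    interval(t, t + dur, int(died), "metastasis" if died else "censor", j + 1, cov)
                )
            else:
                ivs.append(interval(t, t + dur, 1, "locoregional", j + 1, cov))
            t += dur
        subjects.append(SubjectHistory(f"s{i}", tuple(ivs), entry))
    return Cohort(tuple(subjects), numeric_schema(*[f"x{k}" for k in range(p_cov)]))


def dense_event_params(seed: int, n_subjects: int = 500, theta: float = 0.5, rho: float = 1.0):
    """Single binary covariate (beta=0.7), constant baseline, no terminal death.

    The event density (~1 event per subject) is chosen so the frailty
    variance is well identified from within-subject event counts.
    """
    return SimulationParams(
        n_subjects=n_subjects,
        theta=theta,
        dependence_rho=rho,
        seed=seed,
        covariate_dist=(CovariateSim("x", "binary", p=0.5),),
        beta={"x[1]": 0.7},
        death_rho=1.0,
        death_scale=1e9,
        baseline_scale=20.0,
    )


# ---------------------------------------------------------------------------
# independent oracles


def cox_partial_loglik_bruteforce(cohort, beta, covariates, event_filter=None, ranks=None):
    """Brute-force Breslow partial log-likelihood by direct risk-set enumeration.

    Iterates over every event interval and sums exp(eta) over all intervals
    with start < t <= stop; independent of the package's vectorized path.
    """
    rows = []
    for s in cohort.subjects:
        for iv in s.intervals:
            is_event = iv.indicator == 1
            if event_filter is not None:
                is_event = is_event and iv.type == EventType(event_filter)
            if ranks is not None and iv.rank not in ranks:
                continue
            x = np.array([float(iv.covariates[c]) if c in iv.covariates else 0.0 for c in covariates])
            rows.append((iv.start, iv.stop, is_event, x))
    beta = np.asarray(beta, float)
    ll = 0.0
    for start_e, t, is_event, x_e in rows:
        if not is_event:
            continue
        denom = 0.0
        for start, stop, _, x in rows:
            if start < t <= stop:
                denom += np.exp(x @ beta)
        ll += x_e @ beta - np.log(denom)
    return ll


def gamma_marginal_loglik_quadrature(cohort, baseline, beta, theta, covariates=()):
    """Numerical-quadrature oracle for the gamma-frailty marginal likelihood.

    Per subject integrates prod_j (z*lambda0*e^{beta x})^Delta * exp(-z*Lambda_i)
    against the gamma(1/theta, theta) density with scipy.integrate.quad.
    """
    beta = np.asarray(beta, float)
    total = 0.0
    for s in cohort.subjects:
        Lam = 0.0
        log_const = 0.0
        m = 0
        for iv in s.intervals:
            x = np.array([float(iv.covariates.get(c, 0.0)) for c in covariates])
            eta = float(x @ beta) if len(covariates) else 0.0
            w = float(baseline.cumulative([iv.stop])[0] - baseline.cumulative([iv.start])[0])
            Lam += w * np.exp(eta)
            if iv.indicator == 1:
                lam = float(baseline.hazard([iv.stop])[0])
                log_const += np.log(lam) + eta
                m += 1
        if theta == 0:
            total += log_const - Lam
            continue
        a = 1.0 / theta

        def integrand(z, m=m, Lam=Lam, a=a):
            return z**m * np.exp(-z * Lam) * stats.gamma.pdf(z, a, scale=theta)

        val, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-13, epsrel=1e-13, limit=400)
        total += log_const + np.log(val)
    return total


@pytest.fixture(scope="session")
def medium_null_cohort():
    """theta=0, rho=1 cohort with one binary covariate (beta=0.7), ~500 events."""
    cohort, _ = simulate_cohort(dense_event_params(seed=3, theta=0.0))
    return cohort


@pytest.fixture(scope="session")
def medium_frailty_cohort():
    """theta=0.5 cohort with one binary covariate (beta=0.7)."""
    cohort, manifest = simulate_cohort(dense_event_params(seed=11, theta=0.5))
    return cohort, manifest
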