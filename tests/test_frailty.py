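"""Shared gamma-frailty model: marginal likelihood, penalty, fitting, curves."""

import numpy as np
import pytest

from sharedfrailty import (
    Cohort,
    SplineBaseline,
    fit_cox,
    fit_shared_frailty,
    hazard_curves,
    marginal_loglik_gamma,
    penalized_objective,
    posterior_frailty,
    prior_event_covariates,
)
from sharedfrailty.synthetic import SimulationParams, simulate_cohort
from conftest import (
    dense_event_params,
    gamma_marginal_loglik_quadrature,
    numeric_schema,
    random_toy_cohort,
    subject,
)


def unit_baseline(lo=0.0, hi=10.0):
    """Constant baseline hazard lambda0 = 1 on [lo, hi] (partition of unity)."""
    b = SplineBaseline.from_times(np.array([]), lo, hi, n_interior=3)
    return b.with_coefficients(np.ones(b.n_basis))


class TestSplineBaseline:
    def test_constant_coefficients_give_constant_hazard(self):
        b = unit_baseline()
        t = np.linspace(0, 10, 50)
        assert b.hazard(t) == pytest.approx(np.ones(50), abs=1e-12)
        assert b.cumulative(t) == pytest.approx(t, abs=1e-10)

    def test_cumulative_zero_at_lower_boundary_and_nondecreasing(self):
        rng = np.random.default_rng(0)
        b = SplineBaseline.from_times(rng.uniform(0, 10, 40), 0, 10, n_interior=4)
        b = b.with_coefficients(rng.uniform(0, 2, b.n_basis))
        t = np.linspace(0, 10, 200)
        cum = b.cumulative(t)
        assert cum[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(cum) >= -1e-12)
        assert np.all(b.hazard(t) >= 0)

    def test_penalty_matrix_symmetric_psd_and_zero_for_constant(self):
        b = unit_baseline()
        P = b.penalty_matrix()
        assert P == pytest.approx(P.T)
        assert np.all(np.linalg.eigvalsh(P) > -1e-10)
        assert b.roughness() == pytest.approx(0.0, abs=1e-10)

    def test_negative_coefficients_rejected(self):
        b = unit_baseline()
        with pytest.raises(ValueError):
            b.with_coefficients(-np.ones(b.n_basis))


class TestMarginalLoglik:
    def test_no_events_no_exposure_contributes_zero(self):
        # with a zero baseline a censored subject accrues no hazard
        b = unit_baseline().with_coefficients(np.zeros(unit_baseline().n_basis))
        cohort = Cohort((subject("A", [(0, 1, 0, "censor")], cov={}),))
        assert marginal_loglik_gamma(cohort, b, [], theta=1.0) == pytest.approx(0.0)

    def test_single_event_unit_interval_theta_one(self):
        # m=1, lambda0=1, Lambda=1, theta=1: log(1 * (1+1)^-2) = -2 log 2
        cohort = Cohort((subject("A", [(0, 1, 1, "metastasis")], cov={}),))
        ll = marginal_loglik_gamma(cohort, unit_baseline(), [], theta=1.0)
        assert ll == pytest.approx(-2 * np.log(2), abs=1e-10)

    def test_negative_theta_rejected(self):
        cohort = Cohort((subject("A", [(0, 1, 1, "metastasis")], cov={}),))
        with pytest.raises(ValueError):
            marginal_loglik_gamma(cohort, unit_baseline(), [], theta=-0.1)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cohort = random_toy_cohort(seed + 300)
        b = SplineBaseline.from_times(rng.uniform(0, 6, 20), 0.0, 12.0, n_interior=3)
        b = b.with_coefficients(rng.uniform(0.1, 1.5, b.n_basis))
        beta = rng.normal(scale=0.5, size=1)
        theta = rng.uniform(0.2, 2.0)
        ll = marginal_loglik_gamma(cohort, b, beta, theta, covariates=["x0"])
        oracle = gamma_marginal_loglik_quadrature(cohort, b, beta, theta, covariates=["x0"])
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_theta_to_zero_continuity(self):
        cohort, _ = simulate_cohort(SimulationParams(n_subjects=40, seed=8))
        b = unit_baseline(25, 110).with_coefficients(
            0.02 * np.ones(unit_baseline(25, 110).n_basis)
        )
        ll_eps = marginal_loglik_gamma(cohort, b, [], theta=1e-8)
        ll_0 = marginal_loglik_gamma(cohort, b, [], theta=0.0)
        assert abs(ll_eps - ll_0) < 1e-4


class TestPenalizedObjective:
    def setup_method(self):
        self.cohort = Cohort((subject("A", [(0, 1, 1, "metastasis")], cov={}),))
        rng = np.random.default_rng(2)
        b = SplineBaseline.from_times(rng.uniform(0, 1, 10), 0, 1, n_interior=3)
        self.bumpy = b.with_coefficients(rng.uniform(0.2, 2.0, b.n_basis))

    def test_kappa_zero_equals_marginal(self):
        ll = marginal_loglik_gamma(self.cohort, self.bumpy, [], 0.5)
        assert penalized_objective(self.cohort, self.bumpy, [], 0.5, kappa=0.0) == pytest.approx(ll)

    def test_constant_baseline_unpenalized(self):
        flat = unit_baseline(0, 1)
        ll = marginal_loglik_gamma(self.cohort, flat, [], 0.5)
        assert penalized_objective(self.cohort, flat, [], 0.5, kappa=1e6) == pytest.approx(
            ll, abs=1e-6
        )

    def test_penalty_linear_in_kappa(self):
        ll = marginal_loglik_gamma(self.cohort, self.bumpy, [], 0.5)
        pen1 = ll - penalized_objective(self.cohort, self.bumpy, [], 0.5, kappa=1.0)
        pen2 = ll - penalized_objective(self.cohort, self.bumpy, [], 0.5, kappa=2.0)
        assert pen1 > 0
        assert pen2 == pytest.approx(2 * pen1, rel=1e-9)


class TestFitSharedFrailty:
    def test_recovers_theta_and_beta(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=11, n_subjects=1000, theta=0.5))
        fit = fit_shared_frailty(cohort, ["x"])
        assert 0.3 < fit.theta < 0.7
        assert abs(fit.beta[0] - 0.7) < 3 * fit.se[0]
        assert fit.se_theta > 0

    def test_theta_zero_data_degenerates_to_cox(self):
        cohort, _ = simulate_cohort(
            dense_event_params(seed=3, n_subjects=800, theta=0.0)
        )
        fit = fit_shared_frailty(cohort, ["x"])
        cox = fit_cox(cohort, ["x"])
        assert fit.theta < 0.05 or fit.boundary_theta
        assert abs(fit.beta[0] - cox.beta[0]) < 0.05

    def test_zero_events_rejected(self):
        cohort = Cohort(
            tuple(subject(f"s{i}", [(0, 5, 0, "censor")], cov={}) for i in range(10)),
        )
        with pytest.raises(ValueError, match="no .*events"):
            fit_shared_frailty(cohort)

    def test_aic_definition_and_determinism(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=19, n_subjects=200))
        fit1 = fit_shared_frailty(cohort, ["x"])
        fit2 = fit_shared_frailty(cohort, ["x"])
        assert fit1.aic == fit2.aic  # identical refit
        k = len(fit1.beta) + 1 + fit1.baseline.n_basis
        assert fit1.aic == pytest.approx(2 * k - 2 * fit1.loglik_marginal)

    def test_aic_prefers_event_dependence_covariate_under_dependence(self):
        wins = 0
        reps = 30
        for rep in range(reps):
            cohort, _ = simulate_cohort(
                dense_event_params(seed=5000 + rep, n_subjects=300, theta=0.3, rho=2.0)
            )
            f1 = fit_shared_frailty(cohort, ["x"])
            coded = prior_event_covariates(cohort, "count_classes")
            f2 = fit_shared_frailty(coded, ["x", "prior_count"])
            wins += f2.aic < f1.aic
        assert wins >= 0.9 * reps

    def test_dependence_absorbed_reduces_theta(self):
        # adjusting for the prior-event count moves "dependence" out of the
        # frailty variance (the Model 1 -> Model 2 signature)
        wins = 0
        reps = 20
        for rep in range(reps):
            cohort, _ = simulate_cohort(
                dense_event_params(seed=6000 + rep, n_subjects=300, theta=0.5, rho=2.0)
            )
            f1 = fit_shared_frailty(cohort, ["x"])
            coded = prior_event_covariates(cohort, "count_classes")
            f2 = fit_shared_frailty(coded, ["x", "prior_count"])
            wins += f2.theta <= f1.theta + 1e-9
        assert wins >= 0.9 * reps


class TestPosteriorFrailty:
    def test_hand_computed_values(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=23, n_subjects=150))
        fit = fit_shared_frailty(cohort, ["x"])
        i = 0
        expected = (1 / fit.theta + fit.m_i[i]) / (1 / fit.theta + fit.Lambda_i[i])
        assert posterior_frailty(fit, i) == pytest.approx(expected)
        # formula check at round numbers: theta=1, m=2, Lambda=1 -> 1.5
        assert (1 / 1 + 2) / (1 / 1 + 1) == pytest.approx(1.5)

    def test_shrinkage_identity_exact(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=29, n_subjects=300, theta=0.5))
        fit = fit_shared_frailty(cohort, ["x"])
        lhs = np.sum(fit.posterior_frailties * (1 / fit.theta + fit.Lambda_i))
        rhs = np.sum(1 / fit.theta + fit.m_i)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_population_mean_near_one(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=31, n_subjects=500, theta=0.5))
        fit = fit_shared_frailty(cohort, ["x"])
        z = fit.posterior_frailties
        assert abs(z.mean() - 1.0) < 3 * z.std(ddof=1) / np.sqrt(len(z))


class TestHazardCurves:
    def test_flat_hazard_recovered_within_band(self):
        lam = 0.2
        params = SimulationParams(
            n_subjects=600,
            theta=0.0,
            dependence_rho=1.0,
            covariate_dist=(),
            beta={},
            baseline_scale=1 / lam,
            admin_censor_years=5.0,
            death_rho=1.0,
            death_scale=1e9,
            seed=37,
        )
        cohort, _ = simulate_cohort(params)
        curves = hazard_curves(cohort, stratify_by="rank", timescale="surgery_calendar")
        c = curves["rank_1"]
        lo, hi = np.quantile(c.grid, [0.1, 0.9])
        sel = (c.grid >= lo) & (c.grid <= hi)
        assert np.all(c.lower[sel] <= lam) and np.all(lam <= c.upper[sel])

    def test_rank_two_curve_above_rank_one_under_dependence(self):
        cohort, _ = simulate_cohort(
            dense_event_params(seed=41, n_subjects=2000, theta=0.0, rho=3.0)
        )
        curves = hazard_curves(cohort, stratify_by="rank", timescale="gap", ranks=(1, 2))
        c1, c2 = curves["rank_1"], curves["rank_2"]
        grid = np.linspace(
            max(c1.grid.min(), c2.grid.min()), min(c1.grid.max(), c2.grid.max()), 40
        )
        h1 = np.interp(grid, c1.grid, c1.hazard)
        h2 = np.interp(grid, c2.grid, c2.hazard)
        assert np.mean(h2 > h1) > 0.9

    def test_sparse_stratum_skipped_with_warning(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=43, n_subjects=60))
        with pytest.warns(UserWarning, match="skipped"):
            curves = hazard_curves(cohort, stratify_by="type", min_events=10)
        assert "type_second_cancer" not in curves
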