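"""Cox model with delayed entry: risk sets, ties, inference, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sharedfrailty import Cohort, backward_eliminate, fit_cox, partial_loglik, wald_rr
from sharedfrailty.cox import SeparationError
from sharedfrailty.synthetic import CovariateSim, SimulationParams, simulate_cohort

from conftest import (
    cox_partial_loglik_bruteforce,
    dense_event_params,
    interval,
    numeric_schema,
    subject,
)


class TestPartialLoglik:
    def test_risk_set_of_two_gives_log_half(self):
        cohort = Cohort(
            (
                subject("A", [(0, 5, 1, "metastasis")], cov={"x": 0.0}),
                subject("B", [(0, 6, 0, "censor")], cov={"x": 0.0}),
            ),
            numeric_schema("x"),
        )
        ll, _, _ = partial_loglik(cohort, [0.0], ["x"])
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_delayed_entry_excludes_late_entrants(self):
        # B enters at t=5, after A's event at t=5 -> risk set is {A} alone
        cohort = Cohort(
            (
                subject("A", [(0, 5, 1, "metastasis")], cov={"x": 0.0}),
                subject("B", [(5, 9, 0, "censor")], cov={"x": 0.0}),
            ),
            numeric_schema("x"),
        )
        ll, _, _ = partial_loglik(cohort, [0.0], ["x"])
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_four_subject_toy(self):
        rng = np.random.default_rng(1)
        cohort = Cohort(
            (
                subject("A", [(0, 2, 1, "metastasis"), (2, 6, 0, "censor")], cov={"x": 1.0}),
                subject("B", [(1, 4, 1, "locoregional"), (4, 5, 0, "censor")], cov={"x": 0.0}),
                subject("C", [(0, 7, 0, "censor")], cov={"x": 0.5}),
                subject("D", [(3, 8, 0, "censor")], cov={"x": -1.0}),
            ),
            numeric_schema("x"),
        )
        for _ in range(5):
            beta = rng.normal(size=1)
            ll, _, _ = partial_loglik(cohort, beta, ["x"], ties="breslow")
            oracle = cox_partial_loglik_bruteforce(cohort, beta, ["x"])
            assert ll == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), bscale=st.floats(-1.5, 1.5))
    def test_matches_bruteforce_on_random_toy_cohorts(self, seed, bscale):
        from conftest import random_toy_cohort

        cohort = random_toy_cohort(seed)
        beta = np.array([bscale])
        ll, _, _ = partial_loglik(cohort, beta, ["x0"], ties="breslow")
        oracle = cox_partial_loglik_bruteforce(cohort, beta, ["x0"])
        assert ll == pytest.approx(oracle, abs=1e-12)

    def test_no_events_rejected(self):
        cohort = Cohort(
            (subject("A", [(0, 5, 0, "censor")], cov={"x": 0.0}),), numeric_schema("x")
        )
        with pytest.raises(ValueError, match="no events"):
            partial_loglik(cohort, [0.0], ["x"])

    def test_breslow_equals_efron_without_ties(self):
        from conftest import random_toy_cohort

        for seed in range(5):
            cohort = random_toy_cohort(seed + 50)
            for beta in ([0.0], [0.8]):
                llb, gb, hb = partial_loglik(cohort, beta, ["x0"], ties="breslow")
                lle, ge, he = partial_loglik(cohort, beta, ["x0"], ties="efron")
                assert llb == pytest.approx(lle, abs=1e-12)
                assert gb == pytest.approx(ge, abs=1e-12)


class TestFitCox:
    def test_null_simulation_recovers_zero(self):
        cohort, _ = simulate_cohort(
            SimulationParams(
                n_subjects=500,
                theta=0.0,
                dependence_rho=1.0,
                covariate_dist=(CovariateSim("x", "binary", p=0.5),),
                beta={"x[1]": 0.0},
                death_rho=1.0,
                death_scale=1e9,
                baseline_scale=20.0,
                seed=31,
            )
        )
        fit = fit_cox(cohort, ["x"])
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_log2_effect_recovered(self):
        params = dense_event_params(seed=41, n_subjects=1000, theta=0.0)
        cohort, _ = simulate_cohort(params)
        fit = fit_cox(cohort, ["x"])  # true log-hazard ratio 0.7
        assert abs(fit.beta[0] - 0.7) < 3 * fit.se[0]

    def test_timescale_origin_shift_leaves_beta_unchanged(self):
        from dataclasses import replace

        cohort, _ = simulate_cohort(dense_event_params(seed=43, n_subjects=200))
        fit0 = fit_cox(cohort, ["x"])
        shifted_subjects = tuple(
            replace(
                s,
                entry_age=s.entry_age + 100.0,
                intervals=tuple(
                    replace(iv, start=iv.start + 100.0, stop=iv.stop + 100.0)
                    for iv in s.intervals
                ),
            )
            for s in cohort.subjects
        )
        shifted = Cohort(shifted_subjects, cohort.schema, cohort.timescale)
        fit1 = fit_cox(shifted, ["x"])
        assert fit1.beta == pytest.approx(fit0.beta, abs=1e-8)

    def test_subject_entering_after_all_events_is_irrelevant(self):
        late = subject("Z", [(1000.0, 1001.0, 0, "censor")], cov={"x": "1"})
        cohort, _ = simulate_cohort(dense_event_params(seed=47, n_subjects=100))
        with_late = Cohort(cohort.subjects + (late,), cohort.schema, cohort.timescale)
        fit0 = fit_cox(cohort, ["x"])
        fit1 = fit_cox(with_late, ["x"])
        assert fit1.beta == pytest.approx(fit0.beta, abs=1e-10)
        assert fit1.loglik == pytest.approx(fit0.loglik, abs=1e-10)

    def test_complete_separation_reported(self):
        # events only ever occur in the x=1 arm -> monotone likelihood
        subs = []
        for i in range(6):
            subs.append(subject(f"e{i}", [(0, 1 + 0.1 * i, 1, "metastasis")], cov={"x": 1.0}))
            subs.append(subject(f"c{i}", [(0, 5 + 0.1 * i, 0, "censor")], cov={"x": 0.0}))
        cohort = Cohort(tuple(subs), numeric_schema("x"))
        with pytest.raises(SeparationError):
            fit_cox(cohort, ["x"])

    def test_event_filter_restricts_failures(self):
        cohort, _ = simulate_cohort(SimulationParams(n_subjects=300, seed=5))
        fit = fit_cox(cohort, [], event_filter="metastasis", ranks=(1,))
        frame = cohort.intervals_frame()
        expected = int(
            ((frame["event_type"] == "metastasis") & (frame["status"] == 1) & (frame["rank"] == 1)).sum()
        )
        assert fit.n_events == expected

    def test_agrees_with_lifelines_on_counting_process_data(self):
        lifelines = pytest.importorskip("lifelines")
        cohort, _ = simulate_cohort(dense_event_params(seed=53, n_subjects=300))
        fit = fit_cox(cohort, ["x"], ties="efron")
        frame = cohort.intervals_frame()
        X, names = cohort.design_matrix(["x"])
        df = frame[["subject_id", "entry", "exit", "status"]].copy()
        df["x"] = X[:, 0]
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            df, id_col="subject_id", start_col="entry", stop_col="exit", event_col="status"
        )
        assert fit.beta[0] == pytest.approx(ctv.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(ctv.standard_errors_["x"], abs=1e-5)


class TestWaldRR:
    def test_printed_interval_reproduced(self):
        # RR 4.25 with 95% CI (2.51-7.21): recover (beta, se) from the
        # printed numbers and check the interval round-trips to the printed
        # precision (the published bounds themselves carry 0.01 rounding)
        beta = np.log(4.25)
        se = (np.log(7.21) - np.log(2.51)) / (2 * 1.96)
        rr, lo, hi, p = wald_rr(beta, se)
        assert round(rr, 2) == 4.25
        assert abs(lo - 2.51) < 0.01
        assert abs(hi - 7.21) < 0.01
        assert p < 1e-6
        # log-symmetry of the printed interval: geometric mean of the bounds
        # reproduces the printed RR
        assert round(float(np.sqrt(2.51 * 7.21)), 2) == 4.25

    def test_null_coefficient(self):
        rr, lo, hi, p = wald_rr(0.0, 0.1)
        assert rr == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-0.196), rel=1e-12)
        assert hi == pytest.approx(np.exp(0.196), rel=1e-12)
        assert p == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(beta=st.floats(-3, 3), se=st.floats(0, 2))
    def test_log_symmetry_identity(self, beta, se):
        rr, lo, hi, _ = wald_rr(beta, se)
        assert lo * hi == pytest.approx(rr**2, rel=1e-9)


class TestBackwardElimination:
    def test_empty_start_set(self):
        cohort, _ = simulate_cohort(dense_event_params(seed=1, n_subjects=50))
        assert backward_eliminate(cohort, []) == []

    def test_alpha_one_retains_everything(self):
        cohort, _ = simulate_cohort(SimulationParams(n_subjects=200, seed=61))
        retained = backward_eliminate(
            cohort, ["grade", "positive_nodes", "pr_negative", "tumor_size_mm"], alpha=1.0
        )
        assert retained == ["grade", "positive_nodes", "pr_negative", "tumor_size_mm"]

    def test_selects_the_strong_effect(self):
        # one strong binary effect (log 3), one pure-noise covariate
        hits = 0
        reps = 60
        for rep in range(reps):
            params = SimulationParams(
                n_subjects=250,
                theta=0.0,
                dependence_rho=1.0,
                covariate_dist=(
                    CovariateSim("strong", "binary", p=0.5),
                    CovariateSim("noise", "binary", p=0.5),
                ),
                beta={"strong[1]": np.log(3.0)},
                death_rho=1.0,
                death_scale=1e9,
                baseline_scale=20.0,
                seed=700 + rep,
            )
            cohort, _ = simulate_cohort(params)
            retained = backward_eliminate(cohort, ["strong", "noise"], alpha=0.05)
            hits += retained == ["strong"]
        assert hits >= 0.85 * reps
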