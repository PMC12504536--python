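"""Hazard-model fitting: partial-likelihood oracles, Fine–Gray, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import stats

from paequiv import (
    ModelSpec,
    compute_knots,
    finegray_expand,
    fit_cox,
    fit_finegray,
    generate_cohort,
    generate_finegray_cohort,
    loglinear_scenario,
    null_scenario,
    schoenfeld_ph_test,
    wald_nonlinearity_test,
)
from paequiv.errors import ArgumentError, DesignError, EstimationError
from paequiv.hazards import _newton_cox


def brute_force_cox_beta(times, events, x):
    """Independent oracle: Newton solve of the explicitly coded tie-free
    partial-likelihood score, written with plain per-event loops."""

    def score_and_curvature(beta):
        score, curv = 0.0, 0.0
        for i in range(len(times)):
            if events[i] != 1:
                continue
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            wts = np.exp(beta * x[risk])
            mean = np.sum(wts * x[risk]) / np.sum(wts)
            mean2 = np.sum(wts * x[risk] ** 2) / np.sum(wts)
            score += x[i] - mean
            curv += mean2 - mean**2
        return score, curv

    beta = 0.0
    for _ in range(60):
        s, c = score_and_curvature(beta)
        beta += s / c
        if abs(s) < 1e-13:
            break
    return beta


class TestCoxOracle:
    def test_six_subject_partial_likelihood_oracle(self):
        # tie-free toy data, one binary covariate
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        beta_oracle = brute_force_cox_beta(times, events, x)
        b, *_ = _newton_cox(np.zeros(6), times, events, x[:, None], np.ones(6))
        assert b[0] == pytest.approx(beta_oracle, abs=1e-8)

    def test_matches_lifelines_with_and_without_ties(self):
        rng = np.random.default_rng(12)
        n = 800
        X = rng.normal(size=(n, 3))
        T = rng.exponential(1 / np.exp(X @ np.array([0.4, -0.2, 0.0])))
        C = rng.uniform(0, 3, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        for tt in (t, np.ceil(t * 10) / 10):  # tied version second
            df = pd.DataFrame(X, columns=list("abc"))
            df["t"], df["e"] = tt, e
            ours, cov, *_ = _newton_cox(np.zeros(n), tt, e, X, np.ones(n))
            ref = CoxPHFitter().fit(df, "t", "e")
            assert np.allclose(ours, ref.params_.to_numpy(), atol=5e-7)
            assert np.allclose(np.sqrt(np.diag(cov)), ref.standard_errors_.to_numpy(),
                               atol=1e-6)

    def test_rank_invariance_under_time_scaling(self, loglinear_prepared):
        basis = compute_knots(loglinear_prepared["vpa_min"].to_numpy())
        spec = ModelSpec("acm", "vpa", basis)
        fit1 = fit_cox(loglinear_prepared, spec)
        doubled = loglinear_prepared.copy()
        doubled["follow_time"] = 2.0 * doubled["follow_time"]
        fit2 = fit_cox(doubled, spec)
        assert np.allclose(fit1.params, fit2.params, atol=1e-9)

    def test_null_covariate_within_3se(self):
        coh = generate_cohort(null_scenario(seed=31, baseline_hazard=0.02), 5000)
        basis = compute_knots(coh["vpa_min"].to_numpy())
        fit = fit_cox(coh, ModelSpec("acm", "vpa", basis))
        # lifestyle has a true effect; the dose terms are null
        for i in fit.spline_idx:
            assert abs(fit.params[i]) < 3 * fit.se[i]

    def test_loglik_increases_monotonically(self, loglinear_prepared):
        basis = compute_knots(loglinear_prepared["mpa_min"].to_numpy())
        fit = fit_cox(loglinear_prepared, ModelSpec("acm", "mpa", basis))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-9)

    def test_collinear_design_named(self, loglinear_prepared):
        coh = loglinear_prepared.copy()
        coh["age2"] = 2.0 * coh["age"]
        basis = compute_knots(coh["vpa_min"].to_numpy())
        spec = ModelSpec("acm", "vpa", basis, covariates=("age", "age2", "sex"))
        with pytest.raises(DesignError, match="age"):
            fit_cox(coh, spec)

    def test_no_events_raises(self, toy_cohort):
        coh = toy_cohort.copy()
        coh["event_code"] = 0
        with pytest.raises(EstimationError):
            fit_cox(coh, ModelSpec("acm", "vpa", None, covariates=("age",)))


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        truth = loglinear_scenario(seed=5, competing_hazard=0.0)
        coh = generate_cohort(truth, 2000)
        assert (coh["event_code"] == 2).sum() == 0
        basis = compute_knots(coh["vpa_min"].to_numpy())
        fc = fit_cox(coh, ModelSpec("acm", "vpa", basis, family="cox"))
        ff = fit_finegray(coh, ModelSpec("acm", "vpa", basis, family="finegray"))
        assert np.max(np.abs(fc.params - ff.params)) < 1e-6

    def test_ipcw_weight_one_for_plainly_censored(self):
        coh = pd.DataFrame(
            {
                "follow_time": [1.0, 2.0, 3.0, 4.0, 5.0],
                "event_code": [0, 1, 2, 1, 0],
            }
        )
        rows = finegray_expand(coh)
        censored_rows = rows[rows["row"] == 0]
        assert len(censored_rows) == 1
        assert censored_rows["weight"].iloc[0] == 1.0
        # competing subject gets extension rows at later event times with
        # non-increasing weights starting at 1
        ext = rows[(rows["row"] == 2) & (rows["start"] > 0)]
        assert len(ext) == 1  # one later event time (t=4)
        assert 0 < ext["weight"].iloc[0] <= 1.0

    def test_recovers_subdistribution_truth(self):
        beta = 0.5
        df = generate_finegray_cohort(beta=beta, p_event=0.30, n=4000, seed=11)
        rows = finegray_expand(df)
        X = df["x"].to_numpy()[:, None][rows["row"].to_numpy()]
        b, cov, *_ = _newton_cox(
            rows["start"].to_numpy(), rows["stop"].to_numpy(),
            rows["status"].to_numpy(), X, rows["weight"].to_numpy(),
        )
        assert abs(b[0] - beta) < 3 * np.sqrt(cov[0, 0])

    def test_all_competing_raises(self):
        coh = pd.DataFrame(
            {
                "lpa_min": [50.0, 60.0], "mpa_min": [10.0, 20.0], "vpa_min": [1.0, 2.0],
                "age": [50.0, 60.0], "sex": [0, 1], "lifestyle": [0.0, 0.0],
                "follow_time": [1.0, 2.0], "event_code": [2, 2],
            }
        )
        with pytest.raises(EstimationError):
            fit_finegray(coh, ModelSpec("acm", "vpa", None, family="finegray"))


class TestWaldNonlinearity:
    def test_single_term_equals_squared_z(self, loglinear_prepared):
        basis = compute_knots(loglinear_prepared["vpa_min"].to_numpy())
        fit = fit_cox(loglinear_prepared, ModelSpec("acm", "vpa", basis))
        (j,) = fit.nonlinear_idx
        z = fit.params[j] / fit.se[j]
        assert wald_nonlinearity_test(fit) == pytest.approx(
            2 * stats.norm.sf(abs(z)), rel=1e-9
        )

    def test_zero_coefficients_give_p_one(self, loglinear_prepared):
        basis = compute_knots(loglinear_prepared["vpa_min"].to_numpy())
        fit = fit_cox(loglinear_prepared, ModelSpec("acm", "vpa", basis))
        fit.params = np.zeros_like(fit.params)
        assert wald_nonlinearity_test(fit) == 1.0

    def test_empty_index_set_raises(self, loglinear_prepared):
        basis = compute_knots(loglinear_prepared["vpa_min"].to_numpy())
        fit = fit_cox(loglinear_prepared, ModelSpec("acm", "vpa", basis))
        with pytest.raises(ArgumentError):
            wald_nonlinearity_test(fit, indices=[])


class TestSchoenfeld:
    def test_residuals_sum_to_zero(self, loglinear_prepared):
        from paequiv.hazards import _schoenfeld_residuals

        basis = compute_knots(loglinear_prepared["vpa_min"].to_numpy())
        fit = fit_cox(loglinear_prepared, ModelSpec("acm", "vpa", basis))
        d = fit._data
        resid, _ = _schoenfeld_residuals(
            d["start"], d["stop"], d["status"], d["X"], d["w"], fit.params
        )
        # score identity at the MLE: residuals sum to ~0 per term
        col_scale = np.abs(resid).sum(axis=0) + 1e-12
        assert np.max(np.abs(resid.sum(axis=0)) / col_scale) < 1e-6

    def test_time_varying_effect_detected(self):
        # effect reverses sign at median follow-up: PH grossly violated
        rng = np.random.default_rng(2)
        n = 3000
        x = rng.normal(size=n)
        # piecewise-constant hazard per subject, slope flips at t=1
        u = rng.random(n)
        lam1 = 0.5 * np.exp(1.2 * x)
        lam2 = 0.5 * np.exp(-1.2 * x)
        t_first = -np.log(u) / lam1
        crossed = t_first > 1.0
        u2 = rng.random(n)
        t = np.where(crossed, 1.0 - np.log(u2) / lam2, t_first)
        c = rng.uniform(0.5, 4.0, n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        coh = pd.DataFrame(
            {
                "lpa_min": 40 + rng.random(n), "mpa_min": rng.random(n),
                "vpa_min": rng.random(n), "age": x, "sex": 0.0 * x,
                "lifestyle": rng.normal(size=n),
                "follow_time": times, "event_code": events,
            }
        )
        fit = fit_cox(coh, ModelSpec("acm", "vpa", None, covariates=("age", "lifestyle")))
        res = schoenfeld_ph_test(fit)
        assert res["p_values"]["age"] < 1e-4
        assert res["global_p"] < 1e-3

    def test_matches_lifelines_statistic(self):
        # identical two-column design, so the statistics must agree closely
        from paequiv.hazards import HazardFit

        rng = np.random.default_rng(4)
        n = 600
        X = rng.normal(size=(n, 2))
        T = rng.exponential(1 / np.exp(X @ np.array([0.5, -0.5])))
        C = rng.uniform(0, 2.5, n)
        t, e = np.minimum(T, C), (T <= C).astype(int)
        b, cov, ll, tr, it = _newton_cox(np.zeros(n), t, e, X, np.ones(n))
        fit = HazardFit(
            params=b, cov=cov, names=("age", "sex"),
            spec=ModelSpec("acm", "vpa", None), basis=None,
            spline_idx=(0,), nonlinear_idx=(), n=n, n_events=int(e.sum()),
            loglik=ll, loglik_trace=tuple(tr), n_iter=it, converged=True,
            _data={"start": np.zeros(n), "stop": t, "status": e, "X": X,
                   "w": np.ones(n)},
        )
        res = schoenfeld_ph_test(fit, transform="km")

        from lifelines.statistics import proportional_hazard_test

        df = pd.DataFrame({"age": X[:, 0], "sex": X[:, 1], "t": t, "e": e})
        cph = CoxPHFitter().fit(df, "t", "e")
        ref = proportional_hazard_test(cph, df, time_transform="km")
        ref_p = {
            (k[0] if isinstance(k, tuple) else k): v
            for k, v in zip(ref.name, np.atleast_1d(ref.p_value))
        }
        assert res["p_values"]["age"] == pytest.approx(ref_p["age"], abs=1e-3)
        assert res["p_values"]["sex"] == pytest.approx(ref_p["sex"], abs=1e-3)

    def test_too_few_events_raise(self, toy_cohort):
        coh = toy_cohort.copy()
        coh.loc[coh["event_code"] == 1, "event_code"] = [1, 0, 0, 0]
        fit = fit_cox(coh, ModelSpec("acm", "vpa", None, covariates=("age",)))
        with pytest.raises(EstimationError):
            schoenfeld_ph_test(fit)
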