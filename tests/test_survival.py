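"""Survival-engine tests: partial-likelihood fits against generating
values, lifelines cross-checks, Fine-Gray reductions and simulation
oracles, nonparametric estimators against closed forms."""

import numpy as np
import pandas as pd
import pytest

import akrisk.survival as sv


def two_group_exponential(n, hr, base=0.2, admin=5.0, seed=0, day_ties=True):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.4, n)
    t = rng.exponential(1.0 / (base * np.exp(np.log(hr) * x)))
    event = np.where(t < admin, "kidney_failure", "censored")
    tt = np.minimum(t, admin)
    if day_ties:
        tt = np.ceil(tt * 365.25) / 365.25
    return pd.DataFrame({"x": x, "time_years": tt, "event": event})


def competing_exponential(n, lam1=0.2, lam2=0.2, admin=5.0, seed=0):
    rng = np.random.default_rng(seed)
    t1 = rng.exponential(1 / lam1, n)
    t2 = rng.exponential(1 / lam2, n)
    t = np.minimum(np.minimum(t1, t2), admin)
    event = np.where(np.minimum(t1, t2) >= admin, "censored",
                     np.where(t1 <= t2, "kidney_failure", "death"))
    return pd.DataFrame({"time_years": t, "event": event,
                         "x": rng.normal(size=n)})


SPEC_X = sv.CovariateSpec([sv.identity("x")])


class TestCoxFit:
    def test_parameter_recovery_hr2(self):
        df = two_group_exponential(20000, hr=2.0, seed=1)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        assert fit.coef[0] == pytest.approx(np.log(2), abs=0.05)

    def test_null_consistency(self):
        df = two_group_exponential(5000, hr=1.0, seed=2)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        assert abs(fit.coef[0]) < 2 * fit.se[0]

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 3000
        x = rng.binomial(1, 0.5, n)
        z = rng.normal(size=n)
        t = rng.exponential(1 / (0.3 * np.exp(0.5 * x - 0.25 * z)))
        tt = np.ceil(np.minimum(t, 4.0) * 52) / 52  # weekly ties
        df = pd.DataFrame({"x": x, "z": z, "time_years": tt,
                           "event": np.where(t < 4.0, "kidney_failure", "censored")})
        spec = sv.CovariateSpec([sv.identity("x"), sv.identity("z")])
        fit = sv.fit_cox_cause_specific(df, spec, "kidney_failure")
        cph = lifelines.CoxPHFitter()
        ldf = df.assign(e=(df["event"] == "kidney_failure").astype(int)).drop(columns="event")
        cph.fit(ldf, "time_years", "e")
        assert np.abs(fit.coef - cph.params_.to_numpy()).max() < 1e-4
        assert np.abs(fit.se - cph.standard_errors_.to_numpy()).max() < 1e-4

    def test_likelihood_ascent(self):
        df = two_group_exponential(2000, hr=1.8, seed=4)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        X, _ = SPEC_X.build(df)
        d = (df["event"] == "kidney_failure").to_numpy().astype(int)
        prep = sv._prepare(df["time_years"].to_numpy(), d,
                           np.zeros(len(df), int), X)
        ll0, _, _ = sv._pl_derivs(np.zeros(1), prep)
        assert fit.loglik >= ll0

    def test_shift_invariance(self):
        df = two_group_exponential(2000, hr=1.5, seed=5)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        df2 = df.assign(x=df["x"] + 7.0)
        fit2 = sv.fit_cox_cause_specific(df2, SPEC_X, "kidney_failure")
        assert fit.coef[0] == pytest.approx(fit2.coef[0], abs=1e-8)

    def test_scale_covariance(self):
        df = two_group_exponential(2000, hr=1.5, seed=6)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        df2 = df.assign(x=df["x"] * 4.0)
        fit2 = sv.fit_cox_cause_specific(df2, SPEC_X, "kidney_failure")
        assert fit2.coef[0] == pytest.approx(fit.coef[0] / 4.0, abs=1e-8)

    def test_cause_relabel_symmetry(self):
        df = competing_exponential(3000, seed=7)
        fit_kf = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        swapped = df.assign(event=df["event"].map(
            {"kidney_failure": "death", "death": "kidney_failure",
             "censored": "censored"}))
        fit_sw = sv.fit_cox_cause_specific(swapped, SPEC_X, "death")
        assert np.allclose(fit_kf.coef, fit_sw.coef)
        assert fit_kf.n_events == fit_sw.n_events

    def test_zero_variance_term_named(self):
        df = two_group_exponential(200, hr=1.5, seed=8).assign(flat=1.0)
        spec = sv.CovariateSpec([sv.identity("x"), sv.identity("flat")])
        with pytest.raises(ValueError, match="flat"):
            sv.fit_cox_cause_specific(df, spec, "kidney_failure")

    def test_no_events_error(self):
        df = two_group_exponential(100, hr=1.5, seed=9)
        with pytest.raises(ValueError, match="no events"):
            sv.fit_cox_cause_specific(df, SPEC_X, "death")

    def test_separation_error(self):
        # perfectly separating covariate -> monotone likelihood
        n = 200
        rng = np.random.default_rng(10)
        t = np.sort(rng.exponential(1.0, n))
        df = pd.DataFrame({"x": np.arange(n, dtype=float),
                           "time_years": t,
                           "event": "kidney_failure"})
        with pytest.raises((sv.ConvergenceError,)):
            sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")


class TestFineGray:
    def test_reduces_to_cox_without_competing_events(self):
        df = two_group_exponential(4000, hr=1.7, seed=11)
        cox = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        fg = sv.fit_fine_gray(df, SPEC_X, "kidney_failure")
        assert np.abs(cox.coef - fg.coef).max() < 1e-6

    def test_administrative_censoring_weights_are_one(self):
        df = competing_exponential(2000, seed=12)
        t = df["time_years"].to_numpy()
        any_ev = (df["event"] != "censored").to_numpy().astype(int)
        ct, cs = sv.censoring_survival(t, any_ev)
        # all censoring is administrative at t=5: G(t-) = 1 before then
        event_times = np.unique(t[any_ev == 1])
        G = sv._step_eval(ct, cs, event_times, side="left")
        assert np.allclose(G, 1.0)

    def test_subdistribution_parameter_recovery(self):
        """Simulation oracle for the subdistribution model with beta=0.5
        (direct inverse-CDF draw from the subdistribution)."""
        rng = np.random.default_rng(13)
        n, beta, p = 20000, 0.5, 0.4
        x = rng.binomial(1, 0.5, n)
        p1 = 1 - (1 - p) ** np.exp(beta * x)
        u = rng.uniform(size=n)
        cause1 = u < p1
        tvals = np.empty(n)
        v = rng.uniform(size=n)
        eb = np.exp(beta * x[cause1])
        tvals[cause1] = -np.log(
            1 - (1 - (1 - v[cause1] * p1[cause1]) ** (1 / eb)) / p)
        tvals[~cause1] = rng.exponential(1.0, size=(~cause1).sum())
        c = rng.uniform(0.5, 4.0, size=n)
        df = pd.DataFrame({
            "x": x,
            "time_years": np.minimum(tvals, c),
            "event": np.where(tvals <= c,
                              np.where(cause1, "kidney_failure", "death"),
                              "censored")})
        fg = sv.fit_fine_gray(df, SPEC_X, "kidney_failure")
        assert fg.coef[0] == pytest.approx(0.5, abs=0.06)

    def test_differs_from_cox_with_competing_events(self):
        rng = np.random.default_rng(14)
        n = 5000
        x = rng.binomial(1, 0.5, n)
        t1 = rng.exponential(1 / (0.1 * np.exp(0.0 * x)), n)
        t2 = rng.exponential(1 / (0.4 * np.exp(1.0 * x)), n)  # competing depends on x
        t = np.minimum(np.minimum(t1, t2), 5.0)
        ev = np.where(np.minimum(t1, t2) >= 5.0, "censored",
                      np.where(t1 <= t2, "kidney_failure", "death"))
        df = pd.DataFrame({"x": x, "time_years": t, "event": ev})
        cox = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        fg = sv.fit_fine_gray(df, SPEC_X, "kidney_failure")
        # competing pressure pushes the subdistribution coefficient down
        assert fg.coef[0] < cox.coef[0] - 0.1


class TestAalenJohansen:
    def test_single_cause_no_censoring_is_ecdf(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(1.0, 500)
        df = pd.DataFrame({"time_years": t, "event": "kidney_failure"})
        times, cif = sv.aalen_johansen_cif(df, "kidney_failure")[None]
        ecdf = np.searchsorted(np.sort(t), times, side="right") / len(t)
        assert np.allclose(cif, ecdf)

    def test_conservation_identity(self):
        df = competing_exponential(2000, seed=16)
        times_kf, cif_kf = sv.aalen_johansen_cif(df, "kidney_failure")[None]
        times_d, cif_d = sv.aalen_johansen_cif(df, "death")[None]
        t = df["time_years"].to_numpy()
        e = (df["event"] != "censored").to_numpy().astype(int)
        km_t, km_s = sv.kaplan_meier(t, e)
        # evaluate all three at every event time
        grid = km_t
        ckf = sv._step_eval(times_kf, cif_kf, grid, start=0.0)
        cd = sv._step_eval(times_d, cif_d, grid, start=0.0)
        s = sv._step_eval(km_t, km_s, grid, start=1.0)
        assert np.allclose(ckf + cd + s, 1.0, atol=1e-10)

    def test_exponential_closed_form(self):
        lam1 = lam2 = 0.2
        df = competing_exponential(50000, lam1, lam2, seed=17)
        times, cif = sv.aalen_johansen_cif(df, "kidney_failure")[None]
        expected = lam1 / (lam1 + lam2) * (1 - np.exp(-(lam1 + lam2) * 5.0))
        assert cif[-1] == pytest.approx(expected, abs=0.01)

    def test_nondecreasing_and_zero_at_origin(self):
        df = competing_exponential(500, seed=18)
        times, cif = sv.aalen_johansen_cif(df, "kidney_failure")[None]
        assert np.all(np.diff(cif) >= 0)
        assert cif[0] >= 0

    def test_unknown_group_error(self):
        df = competing_exponential(100, seed=19).assign(g="a")
        out = sv.aalen_johansen_cif(df, "kidney_failure", group_col="g")
        assert set(out) == {"a"}


@pytest.fixture(scope="module")
def fg_fit():
    df = competing_exponential(4000, seed=20)
    df["x"] = np.round(df["x"], 1)
    return sv.fit_fine_gray(df, SPEC_X, "kidney_failure")


class TestPredictAbsoluteRisk:

    def test_reference_profile_risk(self, fg_fit):
        risk = sv.predict_absolute_risk(fg_fit, pd.DataFrame({"x": [0.0]}))
        s0 = np.exp(-fg_fit.cumhaz_at(5.0))
        assert risk[0] == pytest.approx(1 - s0, abs=1e-12)

    def test_low_lp_limit(self, fg_fit):
        x_low = -40.0 / fg_fit.coef[0]  # drive LP to -40
        risk = sv.predict_absolute_risk(fg_fit, pd.DataFrame({"x": [x_low]}))
        assert risk[0] == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_lp(self, fg_fit):
        sgn = np.sign(fg_fit.coef[0])
        risks = sv.predict_absolute_risk(
            fg_fit, pd.DataFrame({"x": [0.0, sgn * 1.0]}))
        assert risks[1] > risks[0]


class TestLogLogSurvival:
    def test_proportional_groups_parallel(self):
        rng = np.random.default_rng(21)
        n = 20000
        g = rng.binomial(1, 0.5, n)
        lam = 0.3 * np.exp(np.log(2.0) * g)
        t = np.minimum(rng.exponential(1 / lam), 4.0)
        df = pd.DataFrame({"g": g, "time_years": t,
                           "event": np.where(t < 4.0, "kidney_failure", "censored")})
        curves = sv.loglog_survival(df, "g")
        grid = np.array([0.5, 1.0, 2.0])
        c0 = np.interp(grid, *curves[0])
        c1 = np.interp(grid, *curves[1])
        offsets = c0 - c1
        assert np.allclose(offsets, np.log(2.0), atol=0.1)

    def test_identical_groups_zero_offset(self):
        rng = np.random.default_rng(22)
        n = 20000
        g = rng.binomial(1, 0.5, n)
        t = np.minimum(rng.exponential(1 / 0.3, n), 4.0)
        df = pd.DataFrame({"g": g, "time_years": t,
                           "event": np.where(t < 4.0, "kidney_failure", "censored")})
        curves = sv.loglog_survival(df, "g")
        grid = np.array([0.5, 1.0, 2.0])
        assert np.allclose(np.interp(grid, *curves[0]) - np.interp(grid, *curves[1]),
                           0.0, atol=0.1)

    def test_crossing_hazards_offset_changes_sign(self):
        rng = np.random.default_rng(23)
        n = 20000
        # group 0: Weibull shape 0.5; group 1: shape 2 — hazards cross
        t0 = rng.weibull(0.5, n)
        t1 = rng.weibull(2.0, n)
        df = pd.DataFrame({
            "g": np.repeat([0, 1], n),
            "time_years": np.minimum(np.concatenate([t0, t1]), 4.0),
            "event": np.where(np.concatenate([t0, t1]) < 4.0,
                              "kidney_failure", "censored")})
        curves = sv.loglog_survival(df, "g")
        early = np.interp(0.2, *curves[0]) - np.interp(0.2, *curves[1])
        late = np.interp(2.5, *curves[0]) - np.interp(2.5, *curves[1])
        assert np.sign(early) != np.sign(late)

    def test_group_without_events_omitted(self):
        df = pd.DataFrame({"g": [0] * 50 + [1] * 50,
                           "time_years": [1.0] * 100,
                           "event": ["kidney_failure"] * 50 + ["censored"] * 50})
        curves = sv.loglog_survival(df, "g")
        assert 1 not in curves


class TestStepwiseAttenuation:
    def test_confounded_aki_attenuates_with_adjustment(self):
        """With AKI prevalence depending on a prognostic covariate, the AKI
        coefficient moves toward the truth when the covariate is added."""
        rng = np.random.default_rng(24)
        n = 20000
        z = rng.normal(size=n)                      # prognostic confounder
        aki = rng.binomial(1, 1 / (1 + np.exp(-(z - 1.0))))
        true_b = 0.3
        t = rng.exponential(1 / (0.2 * np.exp(true_b * aki + 0.8 * z)))
        df = pd.DataFrame({"aki": aki, "z": z,
                           "time_years": np.minimum(t, 5.0),
                           "event": np.where(t < 5.0, "kidney_failure", "censored")})
        crude = sv.fit_cox_cause_specific(
            df, sv.CovariateSpec([sv.identity("aki")]), "kidney_failure")
        adj = sv.fit_cox_cause_specific(
            df, sv.CovariateSpec([sv.identity("aki"), sv.identity("z")]),
            "kidney_failure")
        assert crude.coef[0] > adj.coef[0] + 0.1
        assert adj.coef[0] == pytest.approx(true_b, abs=0.1)


class TestSurvivalFitContract:
    def test_covariance_symmetric_psd_and_baseline_monotone(self):
        df = two_group_exponential(3000, hr=1.6, seed=25)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.all(np.linalg.eigvalsh(fit.cov) > -1e-12)
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)
        assert fit.cumhaz_at(0.0) == 0.0

    def test_json_round_trip(self):
        import json
        df = two_group_exponential(500, hr=1.5, seed=26)
        fit = sv.fit_cox_cause_specific(df, SPEC_X, "kidney_failure")
        d = json.loads(fit.to_json())
        assert d["model_kind"] == "cause_specific_cox"
        assert d["coef"][0] == fit.coef[0]
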