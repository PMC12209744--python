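import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import ifnstrat as I
from ifnstrat.coxmodel import CollinearityError, natural_spline_basis


def cox_df(durations, events, **covs):
    return pd.DataFrame({"ttcw_months": durations, "event_observed": events, **covs})


class TestFitCox:
    def test_toy_matches_partial_likelihood_oracle(self):
        # 4 subjects, all events, x = (1,0,1,0) at t = (1,2,3,4)
        df = cox_df([1.0, 2.0, 3.0, 4.0], [True] * 4, x=[1.0, 0.0, 1.0, 0.0])

        def neg_pl(beta):
            # risk sets written out by hand (no ties)
            terms = [
                beta - np.log(2 * np.exp(beta) + 2),   # event at t=1, x=1
                0.0 - np.log(np.exp(beta) + 2),        # t=2, x=0
                beta - np.log(np.exp(beta) + 1),       # t=3, x=1
                0.0,                                   # t=4, last subject
            ]
            return -sum(terms)

        oracle = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12}).x
        fit = I.fit_cox(df, covariates=["x"])
        assert fit.coef["x"] == pytest.approx(oracle, abs=1e-6)
        assert fit.hr["x"] == pytest.approx(np.exp(oracle), rel=1e-6)
        assert oracle == pytest.approx(0.94, abs=0.01)  # HR ~ 2.56

    def test_constant_zero_covariate_is_neutral(self):
        df = cox_df([1.0, 2.0, 3.0, 4.0], [True] * 4, x=[1.0, 0.0, 1.0, 0.0],
                    z=[0.0] * 4)
        fit = I.fit_cox(df, covariates=["x", "z"])
        assert fit.coef["z"] == 0.0 and fit.hr["z"] == 1.0
        assert "z" in fit.dropped_constant

    def test_monotone_likelihood_flagged(self):
        # all group-1 events precede all group-0 events: score equation has
        # no finite root; the fit must warn and cap the coefficient
        df = cox_df([1.0, 2.0, 3.0, 4.0], [True] * 4, x=[1.0, 1.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            fit = I.fit_cox(df, covariates=["x"])
        assert fit.monotone_warning and np.isfinite(fit.coef["x"])

    def test_collinear_design_named(self):
        df = cox_df([1.0, 2.0, 3.0, 4.0], [True] * 4,
                    a=[1.0, 0.0, 1.0, 0.0], b=[2.0, 0.0, 2.0, 0.0])
        with pytest.raises(CollinearityError, match="a.*b|b.*a"):
            I.fit_cox(df, covariates=["a", "b"])


class TestSpline:
    def test_basis_is_orthogonal_to_linear(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        lin, nl = natural_spline_basis(x, df=4)
        assert nl.shape == (300, 3)
        design = np.column_stack([np.ones_like(x), x])
        proj = design.T @ nl
        assert np.allclose(proj, 0.0, atol=1e-8 * len(x))

    def test_linear_truth_gives_calibrated_nonlinear_p(self):
        """With a purely log-linear effect the nonlinearity test is null."""
        rng = np.random.default_rng(7)
        hits, reps = 0, 30
        for _ in range(reps):
            n = 250
            x = rng.normal(0, 1, n)
            t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x)))
            d = np.minimum(t, 60.0)
            e = t <= 60.0
            df = cox_df(d, e, ifn_score=x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = I.fit_cox(df, covariates=["ifn_score"], smooth="ifn_score")
            hits += fit.spline_nonlinear_p < 0.05
        assert hits / reps <= 0.2  # ~5% expected; generous 3-sigma-ish bound

    def test_detects_strong_nonlinearity(self):
        rng = np.random.default_rng(9)
        n = 400
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.02 * np.exp(1.2 * x ** 2)))
        d = np.minimum(t, 60.0)
        df = cox_df(d, t <= 60.0, ifn_score=x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = I.fit_cox(df, covariates=["ifn_score"], smooth="ifn_score")
        assert fit.spline_nonlinear_p < 0.01


@pytest.fixture(scope="module")
def screen(small_cohort, small_outcomes):
    truth = small_cohort["truth"]
    data = small_outcomes.merge(truth[["subject_id", "ifn_high"]], on="subject_id")
    data = data.merge(small_cohort["baseline"], on="subject_id")
    data["event_observed"] = ~data["censored"]
    data["ifn_high"] = data["ifn_high"].astype(float)
    return I.univariable_screen(data, ["ifn_high", "ild", "du_disease", "age", "mrss"])


class TestUnivariableScreen:
    def test_bh_matches_hand_oracle(self, screen):
        ps = screen["p"].to_numpy()
        m = len(ps)
        order = np.argsort(ps)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            prev = min(prev, ps[i] * m / (rank + 1))
            q_oracle[i] = prev
        assert screen["q"].to_numpy() == pytest.approx(q_oracle, rel=1e-12)

    def test_q_dominates_p(self, screen):
        assert (screen["q"] >= screen["p"] - 1e-15).all()

    def test_single_covariate_q_equals_p(self, small_outcomes, small_cohort):
        data = small_outcomes.merge(small_cohort["baseline"], on="subject_id")
        data["event_observed"] = ~data["censored"]
        tab = I.univariable_screen(data, ["mrss"])
        assert tab["q"].iloc[0] == pytest.approx(tab["p"].iloc[0])

    def test_failing_covariate_does_not_abort(self, small_outcomes, small_cohort):
        data = small_outcomes.merge(small_cohort["baseline"], on="subject_id")
        data["event_observed"] = ~data["censored"]
        data["broken"] = 1.0  # constant with strict check off still fits; force NaN
        data.loc[0, "broken"] = np.nan
        tab = I.univariable_screen(data, ["mrss", "broken"])
        assert tab.loc[tab["covariate"] == "broken", "error"].iloc[0] != ""
        assert np.isfinite(tab.loc[tab["covariate"] == "mrss", "hr"].iloc[0])


class TestMultivariable:
    def test_term_sets(self, small_cohort, small_outcomes):
        truth = small_cohort["truth"]
        data = small_outcomes.merge(truth[["subject_id", "ifn_score", "ifn_high"]],
                                    on="subject_id")
        data = data.merge(small_cohort["baseline"], on="subject_id")
        data["event_observed"] = ~data["censored"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, m2 = I.multivariable_models(data)
        assert set(m1.terms) == {"ifn_score", "ild", "pah", "mrss", "du_disease", "age"}
        assert set(m2.terms) == {"ifn_high", "ild", "pah", "mrss", "du_disease", "age"}
        assert m1.spline_nonlinear_p is not None

    def test_constant_column_raises(self, small_cohort, small_outcomes):
        truth = small_cohort["truth"]
        data = small_outcomes.merge(truth[["subject_id", "ifn_score", "ifn_high"]],
                                    on="subject_id")
        data = data.merge(small_cohort["baseline"], on="subject_id")
        data["event_observed"] = ~data["censored"]
        data["pah"] = False
        with pytest.raises(CollinearityError, match="pah"):
            I.multivariable_models(data)


class TestCloglog:
    def test_exponential_closed_form(self):
        # S(t) = e^{-lambda t}  ->  ln(-ln S) = ln lambda + ln t
        rng = np.random.default_rng(13)
        d = rng.exponential(10.0, 3000)
        res = I.ph_cloglog({"g": (d, np.ones(3000, bool))})
        curve = res["curves"]["g"]
        mid = curve[(curve["t"] > 2) & (curve["t"] < 30)]
        pred = np.log(0.1) + np.log(mid["t"])
        assert np.allclose(mid["cloglog"], pred, atol=0.1)

    def test_common_shape_weibull_parallel(self):
        rng = np.random.default_rng(17)
        a = 12 * rng.weibull(1.5, 1500)
        b = 20 * rng.weibull(1.5, 1500)
        res = I.ph_cloglog({"a": (a, np.ones(1500, bool)), "b": (b, np.ones(1500, bool))})
        assert not res["non_parallel"]

    def test_crossing_hazards_flagged(self):
        rng = np.random.default_rng(19)
        a = 10 * rng.weibull(0.5, 1500)
        b = 10 * rng.weibull(3.0, 1500)
        res = I.ph_cloglog({"a": (a, np.ones(1500, bool)), "b": (b, np.ones(1500, bool))})
        assert res["non_parallel"]


class TestTdRoc:
    def test_perfect_marker(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(30.0, 150)
        res = I.td_roc(t, np.ones(150, bool), -t, times=(12.0, 24.0), n_bootstrap=5)
        assert all(a == 1.0 for a, _ in res.auc_at.values())
        assert res.c_index == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(29)
        t = rng.exponential(30.0, 200)
        e = rng.random(200) < 0.8
        m = rng.normal(size=200)
        r1 = I.td_roc(t, e, m, n_bootstrap=2, seed=1)
        r2 = I.td_roc(t, e, np.exp(3 * m), n_bootstrap=2, seed=1)
        assert r1.c_index == pytest.approx(r2.c_index, abs=1e-12)
        for tt in r1.auc_at:
            assert r1.auc_at[tt][0] == pytest.approx(r2.auc_at[tt][0], abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            I.td_roc([50.0, 60.0], [False, False], [1.0, 2.0], times=(12.0,),
                     n_bootstrap=2)
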