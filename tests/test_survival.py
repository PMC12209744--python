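import numpy as np
import pytest
from hypothesis import given, strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

import ifnstrat as I
from ifnstrat.survival import SurvivalCurve

TOY_D = np.array([2.0, 4.0, 6.0, 8.0])
TOY_E = np.array([True, False, True, False])


class TestKaplanMeier:
    def test_hand_product_limit(self):
        c = I.km_estimate(TOY_D, TOY_E)
        assert c.survival == pytest.approx([0.75, 0.375], abs=1e-12)
        assert c.event_times.tolist() == [2.0, 6.0]
        assert c.at_risk.tolist() == [4, 2]

    def test_hand_greenwood(self):
        c = I.km_estimate(TOY_D, TOY_E)
        # Var at t=2: 0.75^2 * 1/(4*3); SE = 0.2165
        assert np.sqrt(c.greenwood_var[0]) == pytest.approx(0.216506, abs=1e-6)

    def test_no_events_flat(self):
        c = I.km_estimate([3.0, 5.0], [False, False])
        assert c.survival_at(4.0) == 1.0 and c.variance_at(4.0) == 0.0

    def test_matches_empirical_without_censoring(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(10.0, 200)
        c = I.km_estimate(d, np.ones(200, bool))
        for t in (2.0, 5.0, 15.0):
            assert c.survival_at(t) == pytest.approx((d > t).mean(), abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        d = rng.exponential(10.0, 150)
        e = rng.random(150) < 0.7
        c = I.km_estimate(d, e)
        kmf = KaplanMeierFitter().fit(d, e)
        for t in (1.0, 5.0, 12.0):
            assert c.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)


class TestFixedTimeContrast:
    def test_identical_samples(self):
        ca = I.km_estimate(TOY_D, TOY_E)
        res = I.fixed_time_contrast(ca, ca, 4.0)
        assert res["difference"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_z(self):
        a = SurvivalCurve(np.array([12.0]), np.array([10]), np.array([1]),
                          np.array([0.9]), np.array([0.001]), 10, 20.0)
        b = SurvivalCurve(np.array([12.0]), np.array([10]), np.array([2]),
                          np.array([0.8]), np.array([0.002]), 10, 20.0)
        res = I.fixed_time_contrast(a, b, 12.0)
        assert res["z"] == pytest.approx(0.1 / np.sqrt(0.003), abs=1e-9)

    def test_beyond_support_raises(self):
        c = I.km_estimate(TOY_D, TOY_E)
        with pytest.raises(ValueError, match="support"):
            I.fixed_time_contrast(c, c, 9.0)

    def test_cloglog_variant_same_sign(self):
        rng = np.random.default_rng(8)
        da = rng.exponential(30, 80)
        db = rng.exponential(15, 80)
        ca = I.km_estimate(da, np.ones(80, bool))
        cb = I.km_estimate(db, np.ones(80, bool))
        ident = I.fixed_time_contrast(ca, cb, 10.0)
        clog = I.fixed_time_contrast(ca, cb, 10.0, transform="cloglog")
        # S_A > S_B: positive on the survival scale, negative on ln(-ln S)
        assert ident["z"] > 0 and clog["z"] < 0
        assert ident["p"] < 0.05 and clog["p"] < 0.05


class TestRMST:
    def test_hand_area(self):
        c = I.km_estimate(TOY_D, TOY_E)
        area, _ = I.rmst(c, 8.0)
        assert area == pytest.approx(5.75, abs=1e-12)

    def test_compare_identical_groups(self):
        r = I.rmst_compare(TOY_D, TOY_E, TOY_D, TOY_E)
        assert r.difference == 0.0 and r.p_value == pytest.approx(1.0)
        assert r.tau == 8.0

    def test_flat_curve_attains_tau(self):
        r = I.rmst_compare([10.0, 12.0], [False, False], TOY_D, TOY_E, tau=8.0)
        assert r.rmst_a == pytest.approx(8.0)

    def test_point_estimate_matches_lifelines(self):
        rng = np.random.default_rng(5)
        d = rng.exponential(20.0, 120)
        e = rng.random(120) < 0.8
        area, _ = I.rmst(I.km_estimate(d, e), 25.0)
        kmf = KaplanMeierFitter().fit(d, e)
        assert area == pytest.approx(
            float(restricted_mean_survival_time(kmf, t=25.0)), rel=1e-9)

    def test_variance_matches_r_survival(self, tmp_path):
        """Greenwood plug-in RMST SE agrees with R survival's se(rmean)."""
        import subprocess
        rng = np.random.default_rng(5)
        d = rng.exponential(20.0, 120)
        e = rng.random(120) < 0.8
        area, var = I.rmst(I.km_estimate(d, e), 25.0)
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([d, e.astype(int)]), delimiter=",",
                   header="time,event", comments="")
        script = tmp_path / "rmst.R"
        script.write_text(
            "suppressMessages(library(survival))\n"
            f"d <- read.csv('{csv}')\n"
            "f <- survfit(Surv(time, event) ~ 1, data=d)\n"
            "s <- summary(f, rmean=25.0)$table\n"
            "cat(sprintf('%.10f %.10f', s[['rmean']], s[['se(rmean)']]))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.split()
        assert area == pytest.approx(float(out[0]), abs=1e-8)
        assert np.sqrt(var) == pytest.approx(float(out[1]), abs=1e-8)

    @given(st.integers(0, 1000))
    def test_bounded_and_monotone_in_tau(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(10.0, 30)
        e = rng.random(30) < 0.7
        c = I.km_estimate(d, e)
        taus = [2.0, 5.0, 9.0]
        areas = [I.rmst(c, t)[0] for t in taus]
        assert all(a <= t + 1e-12 for a, t in zip(areas, taus))
        assert areas == sorted(areas)


class TestLogRank:
    def test_duplicated_groups_null(self):
        chi2, p = I.log_rank(TOY_D, TOY_E, TOY_D, TOY_E)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_zero_events_undefined(self):
        with pytest.raises(ValueError):
            I.log_rank([1.0], [False], [2.0], [False])

    def test_hand_o_minus_e(self):
        # group A fails at 1,2; group B at 3,4 — brute-force O-E over risk sets
        da, db = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        ea = eb = np.array([True, True])
        d = np.concatenate([da, db]); g = np.array([0, 0, 1, 1])
        o_e, v = 0.0, 0.0
        for t in sorted(d):
            risk = d >= t
            n, n1 = risk.sum(), (risk & (g == 1)).sum()
            dd = 1
            d1 = int((d == t).argmax() >= 2)
            o_e += d1 - dd * n1 / n
            if n > 1:
                v += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
        chi2, _ = I.log_rank(da, ea, db, eb)
        assert chi2 == pytest.approx(o_e * o_e / v, abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(11)
        da, db = rng.exponential(20, 70), rng.exponential(12, 60)
        ea, eb = rng.random(70) < 0.8, rng.random(60) < 0.8
        chi2, p = I.log_rank(da, ea, db, eb)
        ll = logrank_test(da, db, ea, eb)
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-9)
        assert p == pytest.approx(ll.p_value, rel=1e-9)


def test_km_converges_to_exponential():
    rng = np.random.default_rng(21)
    lam, n = 0.05, 4000
    d = rng.exponential(1 / lam, n)
    c = I.km_estimate(d, np.ones(n, bool))
    for t in (5.0, 15.0, 30.0):
        assert c.survival_at(t) == pytest.approx(np.exp(-lam * t), abs=4 / np.sqrt(n))
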