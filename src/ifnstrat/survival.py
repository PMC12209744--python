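"""Kaplan-Meier estimation, Greenwood variance, RMST and the log-rank test.

The product-limit estimator and its Greenwood plug-in variance are
implemented directly because downstream pieces (fixed-time contrasts, the
restricted-mean difference and its plug-in variance, relative risks versus
the whole cohort) consume the per-step variances, which packaged KM fits do
not expose.  lifelines serves as an independent cross-check in the test
suite.

Conventions: subjects censored exactly at an event time are still at risk
for that event (the standard convention); the restricted mean survival time
(RMST) up to tau is the area under the KM step function on [0, tau]; for a
two-group comparison tau defaults to the smaller of the two maximum
observed times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "RMSTResult",
    "km_estimate",
    "fixed_time_contrast",
    "rmst",
    "rmst_compare",
    "log_rank",
    "event_probability",
]


@dataclass
class SurvivalCurve:
    """KM step function with Greenwood variance at each event time."""

    event_times: np.ndarray     # distinct times with >= 1 event, ascending
    at_risk: np.ndarray         # risk-set size just before each event time
    events: np.ndarray          # events at each time
    survival: np.ndarray        # S(t) just after each event time
    greenwood_var: np.ndarray   # Var[S(t)] at each event time
    n_subjects: int = 0
    max_observed_time: float = 0.0

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.event_times, "at_risk": self.at_risk, "events": self.events,
            "survival": self.survival, "greenwood_var": self.greenwood_var,
        })


def _as_arrays(durations, observed) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(durations, dtype=float)
    e = np.asarray(observed, dtype=bool)
    if d.shape != e.shape or d.ndim != 1:
        raise ValueError("durations and observed must be 1-d arrays of equal length")
    if d.size == 0:
        raise ValueError("need at least one subject")
    if np.any(d < 0):
        raise ValueError("negative duration")
    return d, e


def km_estimate(durations, observed) -> SurvivalCurve:
    """Product-limit estimate with Greenwood variance.

    ``observed`` is True where the endpoint occurred, False for censoring.
    Greenwood: Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i)).
    """
    d, e = _as_arrays(durations, observed)
    if np.all(d <= 0):
        raise ValueError("all observation times are <= 0")
    order = np.argsort(d, kind="mergesort")
    d, e = d[order], e[order]
    times = np.unique(d[e])
    n = d.size
    at_risk = np.empty(times.size, dtype=int)
    events = np.empty(times.size, dtype=int)
    surv = np.empty(times.size)
    gw = np.empty(times.size)
    s = 1.0
    acc = 0.0
    for k, t in enumerate(times):
        n_i = int(np.sum(d >= t))
        d_i = int(np.sum((d == t) & e))
        at_risk[k] = n_i
        events[k] = d_i
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            acc += d_i / (n_i * (n_i - d_i))
        else:
            acc = np.inf if d_i > 0 else acc
        surv[k] = s
        gw[k] = (s * s * acc) if s > 0 else 0.0
    return SurvivalCurve(event_times=times, at_risk=at_risk, events=events,
                         survival=surv, greenwood_var=gw, n_subjects=n,
                         max_observed_time=float(d.max()))


def event_probability(curve: SurvivalCurve, t: float) -> tuple[float, float]:
    """Cumulative event probability 1 - S(t) with its Greenwood variance."""
    return 1.0 - curve.survival_at(t), curve.variance_at(t)


def fixed_time_contrast(curve_a: SurvivalCurve, curve_b: SurvivalCurve, t: float,
                        transform: str = "identity") -> dict:
    """Compare S_A(t) and S_B(t) with a Greenwood-based normal test.

    ``transform='identity'`` (default, the difference in KM estimates):
    z = (S_A - S_B) / sqrt(var_A + var_B).  ``transform='cloglog'`` tests
    the difference on the ln(-ln S) scale with delta-method variances.
    """
    for c in (curve_a, curve_b):
        if t > c.max_observed_time:
            raise ValueError(f"t={t} lies beyond the observed support ({c.max_observed_time})")
    sa, sb = curve_a.survival_at(t), curve_b.survival_at(t)
    va, vb = curve_a.variance_at(t), curve_b.variance_at(t)
    if transform == "identity":
        diff = sa - sb
        se = np.sqrt(va + vb)
    elif transform == "cloglog":
        if not (0 < sa < 1 and 0 < sb < 1):
            raise ValueError("cloglog transform undefined at S in {0, 1}")
        diff = np.log(-np.log(sa)) - np.log(-np.log(sb))
        ga = va / (sa * np.log(sa)) ** 2
        gb = vb / (sb * np.log(sb)) ** 2
        se = np.sqrt(ga + gb)
    else:
        raise ValueError(f"unknown transform '{transform}'")
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    return {"t": t, "survival_a": sa, "survival_b": sb, "difference": sa - sb,
            "se": se, "z": float(z), "p": float(p), "transform": transform}


def rmst(curve: SurvivalCurve, tau: float) -> tuple[float, float]:
    """Restricted mean survival time on [0, tau] and its plug-in variance.

    RMST = integral of the KM step function; the variance is the standard
    Greenwood-weighted plug-in
    Var = sum_{t_i <= tau} A_i^2 d_i / (n_i (n_i - d_i)) with
    A_i = integral_{t_i}^{tau} S(u) du.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    times = curve.event_times[curve.event_times <= tau]
    # area under the step function
    knots = np.concatenate([[0.0], times, [tau]])
    heights = np.concatenate([[1.0], curve.survival[: times.size]])
    widths = np.diff(knots)
    area = float(np.sum(heights * widths))
    # plug-in variance
    var = 0.0
    for k in range(times.size):
        # area from t_k to tau under S
        sub_knots = np.concatenate([[times[k]], times[k + 1:], [tau]])
        sub_heights = curve.survival[k: times.size]
        a_k = float(np.sum(sub_heights * np.diff(sub_knots)))
        n_i, d_i = curve.at_risk[k], curve.events[k]
        if n_i > d_i:
            var += a_k * a_k * d_i / (n_i * (n_i - d_i))
    return area, var


@dataclass
class RMSTResult:
    tau: float
    rmst_a: float
    rmst_b: float
    var_a: float
    var_b: float
    difference: float
    ci_95: tuple[float, float]
    p_value: float


def rmst_compare(durations_a, observed_a, durations_b, observed_b,
                 tau: float | None = None) -> RMSTResult:
    """Between-group restricted-mean comparison.

    tau defaults to the smaller of the two maximum observed times; groups
    are treated as independent, with a normal approximation for the
    difference.
    """
    ca = km_estimate(durations_a, observed_a)
    cb = km_estimate(durations_b, observed_b)
    if tau is None:
        tau = min(ca.max_observed_time, cb.max_observed_time)
    if tau <= 0:
        raise ValueError("tau must be positive")
    ra, va = rmst(ca, tau)
    rb, vb = rmst(cb, tau)
    diff = ra - rb
    se = np.sqrt(va + vb)
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = diff / se
        p = 2.0 * stats.norm.sf(abs(z))
    ci = (diff - 1.959963984540054 * se, diff + 1.959963984540054 * se)
    return RMSTResult(tau=float(tau), rmst_a=ra, rmst_b=rb, var_a=va, var_b=vb,
                      difference=diff, ci_95=ci, p_value=float(p))


def log_rank(durations_a, observed_a, durations_b, observed_b) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, p-value).

    Standard O-E form with hypergeometric variance over the pooled risk
    sets.  Raises if no event is observed in either group.
    """
    da, ea = _as_arrays(durations_a, observed_a)
    db, eb = _as_arrays(durations_b, observed_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank statistic undefined with zero events")
    d = np.concatenate([da, db])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(da.size, bool), np.ones(db.size, bool)])
    times = np.unique(d[e])
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        at_risk = d >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        dd = int(((d == t) & e).sum())
        d1 = int(((d == t) & e & g).sum())
        if n == 0:
            continue
        o_minus_e += d1 - dd * n1 / n
        if n > 1:
            var += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
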