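"""Cox proportional-hazards modelling and time-dependent discrimination.

Fits are delegated to lifelines' ``CoxPHFitter`` (Efron tie handling, the
natural choice for visit-grid data where tied event times are common).  On
top of that this module provides:

* a natural-cubic-spline expansion for a smooth covariate with an exact
  linear/nonlinear decomposition (the nonlinear basis columns are
  orthogonalised against the linear term, so the coefficient on the linear
  column is the linear-component log-HR; the nonlinear contribution is
  tested by a likelihood-ratio test against the linear restriction),
* a univariable screen with Benjamini-Hochberg q-values,
* the two pre-specified multivariable models (spline IFN score,
  categorical IFN class; both adjusted for ILD, PAH, mRSS, DU disease and
  age),
* complementary log-log curves for a visual proportional-hazards check,
* incident/dynamic time-dependent ROC with bootstrap standard errors and a
  pair-weighted concordance index.

td-ROC convention: at each event time the incident cases are the subjects
failing exactly then and the dynamic controls those still at risk after it;
AUC(t) is the comparable-pair-weighted average of the per-event-time AUCs
over event times <= t, and the C-index is the same average over all event
times.  All three are invariant under strictly increasing transformations
of the marker.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .survival import km_estimate

__all__ = [
    "CollinearityError",
    "CoxFit",
    "DiscriminationResult",
    "natural_spline_basis",
    "fit_cox",
    "univariable_screen",
    "multivariable_models",
    "ph_cloglog",
    "td_roc",
]

_Z95 = stats.norm.ppf(0.975)


class CollinearityError(ValueError):
    """The design matrix is rank deficient; names the offending terms."""


@dataclass
class CoxFit:
    terms: list[str]
    coef: dict[str, float]
    hr: dict[str, float]
    ci_95: dict[str, tuple[float, float]]
    p: dict[str, float]
    loglik: float
    n: int
    n_events: int
    spline_term: str | None = None
    spline_linear_hr: float | None = None
    spline_linear_ci: tuple[float, float] | None = None
    spline_linear_p: float | None = None
    spline_nonlinear_p: float | None = None
    monotone_warning: bool = False
    dropped_constant: list[str] = field(default_factory=list)
    linear_predictor: np.ndarray | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            lo, hi = self.ci_95[t]
            rows.append({"term": t, "coef": self.coef[t], "hr": self.hr[t],
                         "ci_lo": lo, "ci_hi": hi, "p": self.p[t]})
        return pd.DataFrame(rows)


def natural_spline_basis(x: np.ndarray, df: int = 4,
                         knots: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis -> (linear column, nonlinear columns).

    ``df`` counts total spline degrees of freedom (linear term included),
    so df=4 yields one linear and three nonlinear columns.  Knots sit at
    equally spaced quantiles of ``x`` (boundary knots at min/max).  The
    nonlinear columns are residualised against [1, x] so they carry no
    linear component.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2 (one linear + >=1 nonlinear column)")
    n_knots = df + 1
    if knots is None:
        qs = np.linspace(0, 1, n_knots)
        knots = np.quantile(x, qs)
        knots = np.unique(knots)
    if knots.size < 3:
        raise ValueError("too few distinct knots; covariate nearly constant")
    k_last = knots[-1]
    k_pen = knots[-2]

    def d(xv, kk):
        return (np.maximum(xv - kk, 0.0) ** 3 - np.maximum(xv - k_last, 0.0) ** 3) / (k_last - kk)

    cols = [d(x, knots[j]) - d(x, k_pen) for j in range(knots.size - 2)]
    nl = np.column_stack(cols)
    # strip any linear component so the x-column owns it exactly
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, nl, rcond=None)
    nl = nl - design @ beta
    scale = nl.std(axis=0)
    scale[scale == 0] = 1.0
    return x, nl / scale


def _check_design(X: pd.DataFrame, strict_constant: bool = False) -> list[str]:
    """Return constant columns; raise on rank deficiency among non-constant ones."""
    const = [c for c in X.columns if np.ptp(X[c].to_numpy(dtype=float)) == 0.0]
    live = [c for c in X.columns if c not in const]
    if strict_constant and const:
        raise CollinearityError(f"constant covariate column(s): {', '.join(const)}")
    if live:
        M = X[live].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        if np.linalg.matrix_rank(M) < len(live):
            raise CollinearityError(f"collinear covariates among: {', '.join(live)}")
    return const


def fit_cox(data: pd.DataFrame, duration_col: str = "ttcw_months",
            event_col: str = "event_observed", covariates: list[str] | None = None,
            smooth: str | None = None, smooth_df: int = 4,
            strict_constant: bool = False) -> CoxFit:
    """Cox partial-likelihood fit (Efron ties) with an optional spline term.

    ``smooth`` names one continuous covariate to enter as a natural cubic
    spline (``smooth_df`` total df); its linear-component HR/CI/p and the
    LRT p-value of the nonlinear component are reported separately.
    Zero-variance covariates are dropped with coefficient 0 / HR 1 (or, with
    ``strict_constant=True``, raise :class:`CollinearityError`); monotone
    partial likelihoods are flagged and refit with a light ridge penalty so
    the reported coefficient is finite.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    work = data[[duration_col, event_col, *covariates]].copy()
    for c in covariates:
        if work[c].dtype == bool:
            work[c] = work[c].astype(float)
    n_events = int(work[event_col].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")

    dropped = _check_design(work[covariates], strict_constant=strict_constant)
    live = [c for c in covariates if c not in dropped]

    nl_cols: list[str] = []
    if smooth is not None:
        if smooth not in live:
            raise ValueError(f"smooth covariate '{smooth}' not among (non-constant) covariates")
        _, nl = natural_spline_basis(work[smooth].to_numpy(dtype=float), df=smooth_df)
        for j in range(nl.shape[1]):
            col = f"{smooth}_nl{j + 1}"
            work[col] = nl[:, j]
            nl_cols.append(col)

    def _fit(cols: list[str], penalizer: float = 0.0):
        cph = CoxPHFitter(penalizer=penalizer)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cph.fit(work[[duration_col, event_col, *cols]],
                    duration_col=duration_col, event_col=event_col,
                    fit_options={"precision": 1e-12, "max_steps": 500})
        conv = any(
            issubclass(w.category, ConvergenceWarning)
            and re.search(r"separation|norm\(delta\)|failed to converge|diverg",
                          str(w.message))
            for w in wlist
        )
        return cph, conv

    monotone = False
    fit_cols = live + nl_cols
    if fit_cols:
        try:
            cph, conv = _fit(fit_cols)
            big = bool(np.any(np.abs(cph.params_.to_numpy()) > 10))
            if conv or big:
                monotone = True
                cph, _ = _fit(fit_cols, penalizer=0.1)
                warnings.warn("monotone or ill-conditioned partial likelihood; "
                              "coefficients capped with a ridge penalty", stacklevel=2)
        except ConvergenceError:
            monotone = True
            cph, _ = _fit(fit_cols, penalizer=0.1)
            warnings.warn("partial likelihood diverged; coefficients capped with a "
                          "ridge penalty", stacklevel=2)
        params = cph.params_
        ses = cph.standard_errors_
        lls_full = float(cph.log_likelihood_)
        lp = cph.predict_partial_hazard(work).to_numpy()
        lp = np.log(lp)
    else:
        params = pd.Series(dtype=float)
        ses = pd.Series(dtype=float)
        lls_full = float("nan")
        lp = np.zeros(len(work))

    coef, hr, ci, pvals = {}, {}, {}, {}
    for c in covariates:
        if c in dropped:
            coef[c], hr[c], ci[c], pvals[c] = 0.0, 1.0, (1.0, 1.0), 1.0
        else:
            b, se = float(params[c]), float(ses[c])
            coef[c] = b
            hr[c] = float(np.exp(b))
            ci[c] = (float(np.exp(b - _Z95 * se)), float(np.exp(b + _Z95 * se)))
            pvals[c] = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else 1.0

    out = CoxFit(terms=list(covariates), coef=coef, hr=hr, ci_95=ci, p=pvals,
                 loglik=lls_full, n=len(work), n_events=n_events,
                 monotone_warning=monotone, dropped_constant=dropped,
                 linear_predictor=lp)

    if smooth is not None:
        out.spline_term = smooth
        out.spline_linear_hr = hr[smooth]
        out.spline_linear_ci = ci[smooth]
        out.spline_linear_p = pvals[smooth]
        # LRT of the nonlinear restriction (all nl columns zero)
        cph_lin, _ = _fit(live)
        lr = 2.0 * (lls_full - float(cph_lin.log_likelihood_))
        out.spline_nonlinear_p = float(stats.chi2.sf(max(lr, 0.0), df=len(nl_cols)))
    return out


def univariable_screen(data: pd.DataFrame, covariates: list[str],
                       duration_col: str = "ttcw_months",
                       event_col: str = "event_observed") -> pd.DataFrame:
    """One Cox fit per covariate with Benjamini-Hochberg q-values.

    A covariate whose fit fails contributes a row with the error noted and
    is excluded from the multiplicity correction; the screen never aborts.
    """
    rows = []
    for c in covariates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit_cox(data, duration_col, event_col, [c])
            lo, hi = f.ci_95[c]
            rows.append({"covariate": c, "hr": f.hr[c], "ci_lo": lo, "ci_hi": hi,
                         "p": f.p[c], "error": ""})
        except Exception as exc:  # propagate per covariate without aborting
            rows.append({"covariate": c, "hr": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "p": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    qs = np.full(len(table), np.nan)
    if ok.any():
        qs[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["q"] = qs
    return table


_ADJUSTERS = ["ild", "pah", "mrss", "du_disease", "age"]


def multivariable_models(data: pd.DataFrame, duration_col: str = "ttcw_months",
                         event_col: str = "event_observed") -> tuple[CoxFit, CoxFit]:
    """The two pre-specified multivariable models.

    Model 1: spline IFN score + ILD + PAH + mRSS + DU disease + age.
    Model 2: IFN class (high vs low) + the same adjusters.
    Constant covariate columns raise :class:`CollinearityError`.
    """
    work = data.copy()
    if "ifn_high" not in work.columns:
        if "ifn_class" not in work.columns:
            raise ValueError("need an 'ifn_high' or 'ifn_class' column")
        work["ifn_high"] = (work["ifn_class"] == "high").astype(float)
    m1 = fit_cox(work, duration_col, event_col, ["ifn_score", *_ADJUSTERS],
                 smooth="ifn_score", strict_constant=True)
    m2 = fit_cox(work, duration_col, event_col, ["ifn_high", *_ADJUSTERS],
                 strict_constant=True)
    return m1, m2


def ph_cloglog(groups: dict[str, tuple[np.ndarray, np.ndarray]],
               parallel_tol: float = 0.4) -> dict:
    """Complementary log-log curves ln(-ln S(t)) per group.

    Points with S in {0, 1} are dropped.  For two groups a parallelism
    summary is returned: the curves are evaluated on their common event-time
    grid, restricted to the stable mid-range S in [0.1, 0.9] (the transform
    is wildly variable in the tails), and the maximum deviation of the
    vertical offset from its mean is reported; under proportional hazards
    the offset is constant and the deviation shrinks toward 0.
    """
    curves = {}
    km = {}
    for name, (dur, obs) in groups.items():
        c = km_estimate(dur, obs)
        km[name] = c
        keep = (c.survival > 0) & (c.survival < 1)
        curves[name] = pd.DataFrame({
            "t": c.event_times[keep],
            "cloglog": np.log(-np.log(c.survival[keep])),
        })
    out: dict = {"curves": curves}
    if len(groups) == 2:
        (na, ca), (nb, cb) = km.items()
        lo = max(ca.event_times.min(), cb.event_times.min())
        hi = min(ca.max_observed_time, cb.max_observed_time)
        grid = np.unique(np.concatenate([ca.event_times, cb.event_times]))
        grid = grid[(grid >= lo) & (grid <= hi)]
        offs = []
        for t in grid:
            sa, sb = ca.survival_at(t), cb.survival_at(t)
            if 0.1 <= sa <= 0.9 and 0.1 <= sb <= 0.9:
                offs.append(np.log(-np.log(sa)) - np.log(-np.log(sb)))
        if offs:
            offs = np.asarray(offs)
            dev = float(np.max(np.abs(offs - offs.mean())))
            out["offset_deviation"] = dev
            out["non_parallel"] = bool(dev > parallel_tol)
    return out


@dataclass
class DiscriminationResult:
    auc_at: dict[float, tuple[float, float]]   # t -> (AUC, bootstrap SE)
    c_index: float
    c_index_se: float
    n_bootstrap: int


def _auc_terms(durations: np.ndarray, observed: np.ndarray,
               marker: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-event-time concordant pair mass and pair counts."""
    times = np.unique(durations[observed])
    conc = np.zeros(times.size)
    pairs = np.zeros(times.size)
    for k, t in enumerate(times):
        cases = marker[(durations == t) & observed]
        controls = marker[durations > t]
        if cases.size == 0 or controls.size == 0:
            continue
        diff = cases[:, None] - controls[None, :]
        conc[k] = np.sum(diff > 0) + 0.5 * np.sum(diff == 0)
        pairs[k] = cases.size * controls.size
    return times, conc, pairs


def _auc_c(durations, observed, marker, times_at):
    ts, conc, pairs = _auc_terms(durations, observed, marker)
    aucs = {}
    for t in times_at:
        mask = ts <= t
        tot = pairs[mask].sum()
        aucs[t] = conc[mask].sum() / tot if tot > 0 else np.nan
    tot_all = pairs.sum()
    c = conc.sum() / tot_all if tot_all > 0 else np.nan
    return aucs, c


def td_roc(durations, observed, marker, times=(12.0, 24.0, 36.0),
           n_bootstrap: int = 1000, seed: int = 0) -> DiscriminationResult:
    """Incident/dynamic time-dependent ROC and pair-weighted C-index.

    ``marker`` is a baseline risk score (raw IFN score or a Cox model's
    linear predictor).  Bootstrap SEs resample subjects stratified by event
    status with a fixed seed.  Raises if no event occurs by max(times).
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(observed, dtype=bool)
    m = np.asarray(marker, dtype=float)
    times = [float(t) for t in times]
    if not np.any(e & (d <= max(times))):
        raise ValueError(f"no events by t={max(times)}; AUC undefined")
    aucs, c = _auc_c(d, e, m, times)

    rng = np.random.default_rng(seed)
    idx_ev = np.flatnonzero(e)
    idx_ce = np.flatnonzero(~e)
    boot_auc = {t: [] for t in times}
    boot_c = []
    for _ in range(n_bootstrap):
        take = np.concatenate([
            rng.choice(idx_ev, size=idx_ev.size, replace=True),
            rng.choice(idx_ce, size=idx_ce.size, replace=True),
        ])
        a_b, c_b = _auc_c(d[take], e[take], m[take], times)
        for t in times:
            boot_auc[t].append(a_b[t])
        boot_c.append(c_b)
    auc_at = {}
    for t in times:
        vals = np.asarray(boot_auc[t], dtype=float)
        vals = vals[np.isfinite(vals)]
        se = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        auc_at[t] = (float(aucs[t]), se)
    cb = np.asarray(boot_c, dtype=float)
    cb = cb[np.isfinite(cb)]
    c_se = float(cb.std(ddof=1)) if cb.size > 1 else float("nan")
    return DiscriminationResult(auc_at=auc_at, c_index=float(c), c_index_se=c_se,
                                n_bootstrap=n_bootstrap)
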