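"""End-to-end orchestration: simulate -> score -> adjudicate -> analyze.

``run_all`` chains every stage of the analysis on a synthetic cohort and
returns a report bundle mirroring the shape of a cohort paper's outputs:
baseline comparison tables, the adjudicated outcomes, KM curves with
fixed-time contrasts and the restricted-mean comparison, univariable and
multivariable Cox models with time-dependent discrimination, the clinical x
serologic stratification with relative risks, and the trial power design.
Everything is deterministic given the configuration seed.

``baseline_table`` implements the standard Table-1 machinery: per-variable
test selection (Shapiro-Wilk normality and an F-test of variance homogeneity
gate t-test vs Wilcoxon for continuous variables; the minimum-expected-count
rule gates Fisher vs chi-square for categorical ones) with
Benjamini-Hochberg q-values across the table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import survival as surv
from .adjudication import AdjudicationRules, adjudicate_cohort
from .coxmodel import multivariable_models, td_roc, univariable_screen
from .io import ORGAN_FLAGS
from .power import PowerSpec, design_summary
from .scoring import classify_panels, derive_threshold, score_panels
from .simulate import SimConfig, generate_cohort, generate_controls
from .stratify import assign_strata, rr_vs_overall, upset_counts

__all__ = ["RunConfig", "baseline_table", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    sim: SimConfig = None  # type: ignore[assignment]
    rules: AdjudicationRules = field(default_factory=AdjudicationRules)
    timepoints: tuple = (12.0, 24.0, 36.0, 60.0, 120.0)
    rr_horizons: tuple = (24.0, 36.0, 48.0)
    n_bootstrap: int = 1000

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if any(t > 120 for t in self.timepoints):
            raise ValueError("analysis timepoints must be <= 120 months")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}), seed=raw.get("seed", 0)) \
            if "sim" in raw else None
        rules = AdjudicationRules(**raw.pop("rules", {}))
        return cls(seed=raw.get("seed", 0), sim=sim, rules=rules,
                   timepoints=tuple(raw.get("timepoints", (12, 24, 36, 60, 120))),
                   rr_horizons=tuple(raw.get("rr_horizons", (24, 36, 48))),
                   n_bootstrap=int(raw.get("n_bootstrap", 1000)))


_CONTINUOUS = ["age", "disease_duration", "mrss", "fvc_pct", "dlco_pct"]
_CATEGORICAL = ["sex", "ana", "aca", "scl70", "ro52", "ild", "pah", "du_disease",
                "calcinosis", "upper_gi", "mmf", "era", "pde5i", "iloprost",
                "ccb", "hcq", "aspirin", "ace"]


def _continuous_test(x: np.ndarray, y: np.ndarray) -> tuple[str, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        return "constant", np.nan
    normal = True
    for v in (x, y):
        if len(v) >= 3 and np.ptp(v) > 0:
            if stats.shapiro(v).pvalue < 0.05:
                normal = False
    if normal:
        equal_var = True
        if np.var(x, ddof=1) > 0 and np.var(y, ddof=1) > 0:
            f = np.var(x, ddof=1) / np.var(y, ddof=1)
            dfx, dfy = len(x) - 1, len(y) - 1
            p_f = 2 * min(stats.f.sf(f, dfx, dfy), stats.f.cdf(f, dfx, dfy))
            equal_var = p_f >= 0.05
        return ("t-test" if equal_var else "welch",
                float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue))
    return "wilcoxon", float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _categorical_test(x: pd.Series, group: np.ndarray) -> tuple[str, float]:
    tab = pd.crosstab(x, group)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return "constant", np.nan
    expected = stats.contingency.expected_freq(tab.to_numpy())
    if tab.shape == (2, 2) and (expected < 5).any():
        return "fisher", float(stats.fisher_exact(tab.to_numpy())[1])
    return "chi2", float(stats.chi2_contingency(tab.to_numpy(), correction=False)[1])


def baseline_table(baseline: pd.DataFrame, group: pd.Series | np.ndarray,
                   extra_continuous: pd.DataFrame | None = None) -> pd.DataFrame:
    """Two-group baseline comparison with per-variable test selection.

    ``group`` is a binary label per subject (e.g. event status or IFN
    class).  ``extra_continuous`` can add columns (e.g. the IFN score)
    aligned with ``baseline``.  Returns variable, test, p and BH q; constant
    variables are skipped with a note and excluded from the correction.
    """
    group = np.asarray(group)
    if len(group) != len(baseline):
        raise ValueError("group must label every subject")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("grouping must have exactly two levels")
    g0 = group == levels[0]
    work = baseline.copy()
    continuous = list(_CONTINUOUS)
    if extra_continuous is not None:
        for c in extra_continuous.columns:
            work[c] = extra_continuous[c].to_numpy()
            continuous.append(c)
    rows = []
    for var in continuous:
        x = work.loc[g0, var].to_numpy(dtype=float)
        y = work.loc[~g0, var].to_numpy(dtype=float)
        test, p = _continuous_test(x, y)
        rows.append({"variable": var, "test": test, "p": p,
                     "note": "constant variable; test skipped" if test == "constant" else ""})
    for var in _CATEGORICAL:
        if var not in work.columns:
            continue
        test, p = _categorical_test(work[var], group)
        rows.append({"variable": var, "test": test, "p": p,
                     "note": "constant variable; test skipped" if test == "constant" else ""})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    q = np.full(len(table), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["q"] = q
    return table


_UNIVARIABLE_COVARIATES = ["age", "male", "aca", "scl70", "ro52", "disease_duration",
                           "mrss", "fvc_pct", "dlco_pct", "upper_gi", "ild",
                           "du_disease", "calcinosis", "pah", "mmf", "era",
                           "ifn_high"]


def run_all(config: RunConfig | None = None, out_dir: str | Path | None = None,
            replicate: int = 0) -> dict:
    """Run the full pipeline on one synthetic cohort; optionally write files.

    Stages: generate controls and cohort; derive the IFN threshold from the
    controls and classify patients; adjudicate the composite endpoint;
    KM/contrast/RMST/log-rank by IFN group; univariable screen and the two
    multivariable Cox models with time-dependent ROC; stratification with
    relative risks; the power design.  Any stage failure aborts with the
    stage named.  Deterministic given the seed.
    """
    config = config or RunConfig()
    report: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        controls = generate_controls(config.sim, replicate=replicate)
        baseline, panels, visits, truth = generate_cohort(config.sim, replicate=replicate)

        stage = "score"
        hc_scores = score_panels(controls)["ifn_score"]
        model = derive_threshold(hc_scores)
        scores = classify_panels(panels, model)
        report["threshold"] = model.to_dict()
        report["n_high"] = int((scores["ifn_class"] == "high").sum())
        report["n_low"] = int((scores["ifn_class"] == "low").sum())

        stage = "adjudicate"
        outcomes = adjudicate_cohort(baseline, visits, config.rules)
        report["n_events"] = int((~outcomes["censored"]).sum())

        stage = "survival"
        merged = outcomes.merge(scores, on="subject_id")
        merged["event_observed"] = ~merged["censored"]
        hi = merged["ifn_class"] == "high"
        dur = merged["ttcw_months"].to_numpy()
        obs = merged["event_observed"].to_numpy()
        curve_all = surv.km_estimate(dur, obs)
        curve_hi = surv.km_estimate(dur[hi], obs[hi])
        curve_lo = surv.km_estimate(dur[~hi], obs[~hi])
        tmax = min(curve_hi.max_observed_time, curve_lo.max_observed_time)
        contrasts = [surv.fixed_time_contrast(curve_hi, curve_lo, t)
                     for t in config.timepoints if t <= tmax]
        rmst_res = surv.rmst_compare(dur[hi], obs[hi], dur[~hi], obs[~hi])
        chi2, p_lr = surv.log_rank(dur[hi], obs[hi], dur[~hi], obs[~hi])
        report["survival"] = {
            "overall_event_prob": {t: surv.event_probability(curve_all, t)[0]
                                   for t in config.timepoints},
            "contrasts": contrasts,
            "rmst": {"tau": rmst_res.tau, "high": rmst_res.rmst_a,
                     "low": rmst_res.rmst_b, "difference": rmst_res.difference,
                     "ci_95": rmst_res.ci_95, "p": rmst_res.p_value},
            "log_rank": {"chi2": chi2, "p": p_lr},
        }

        stage = "cox"
        data = merged.merge(baseline, on="subject_id")
        data["male"] = (data["sex"] == "male").astype(float)
        data["ifn_high"] = (data["ifn_class"] == "high").astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            screen = univariable_screen(data, _UNIVARIABLE_COVARIATES)
            m1, m2 = multivariable_models(data)
            roc = td_roc(data["ttcw_months"], data["event_observed"],
                         m1.linear_predictor, times=(12.0, 24.0, 36.0),
                         n_bootstrap=config.n_bootstrap, seed=config.seed + 7)
        report["univariable"] = screen
        report["multivariable"] = {
            "model1_spline": {"hr": m1.hr, "p": m1.p,
                              "spline_linear_hr": m1.spline_linear_hr,
                              "spline_nonlinear_p": m1.spline_nonlinear_p},
            "model2_categorical": {"hr": m2.hr, "ci": m2.ci_95, "p": m2.p},
        }
        report["discrimination"] = {
            "auc_at": roc.auc_at, "c_index": roc.c_index,
            "c_index_se": roc.c_index_se,
        }

        stage = "stratify"
        strata = assign_strata(baseline, scores)
        counts = upset_counts(strata, outcomes)
        aligned = outcomes.merge(strata, on="subject_id")
        rr_high = rr_vs_overall(aligned, (aligned["risk_group"] == "high_risk").to_numpy(),
                                horizons=config.rr_horizons, ci="delta")
        rr_low = rr_vs_overall(aligned, (aligned["risk_group"] == "low_risk").to_numpy(),
                               horizons=config.rr_horizons, ci="delta")
        report["strata_counts"] = counts
        report["rr"] = {"high_risk": rr_high, "low_risk": rr_low}

        stage = "power"
        report["power"] = design_summary(PowerSpec())

        stage = "baseline_table"
        extra = data[["ifn_score"]]
        report["table1_by_event"] = baseline_table(
            data, np.where(data["event_observed"], "event", "no_event"), extra)
        report["table1_by_ifn"] = baseline_table(data, data["ifn_class"], extra)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    if out_dir is not None:
        _write_report(report, scores, outcomes, strata, counts, Path(out_dir))
    report["_tables"] = {"baseline": baseline, "panels": panels, "visits": visits,
                         "truth": truth, "outcomes": outcomes, "scores": scores,
                         "strata": strata, "controls": controls}
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__") and not isinstance(obj, (str, bytes)):
        try:
            return _jsonable(vars(obj))
        except TypeError:
            return str(obj)
    return obj


def _write_report(report, scores, outcomes, strata, counts, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out_dir / "scores.csv", index=False)
    out = outcomes.copy()
    out["censored"] = out["censored"].astype(int)
    out.to_csv(out_dir / "outcomes.csv", index=False)
    strata.to_csv(out_dir / "strata.csv", index=False)
    counts.to_csv(out_dir / "strata_counts.csv", index=False)
    slim = {k: v for k, v in report.items() if k != "_tables"}
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_jsonable(slim), fh, indent=2)
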