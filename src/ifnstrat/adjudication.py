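"""Composite Morbi-mortality endpoint adjudication on longitudinal records.

The time to clinical worsening (TTCW) is the time from the serum-sample
baseline to the first of: SSc-related death; new right-heart-catheter PAH;
new or progressive ILD (FVC%-predicted drop >= 10 points within 12 months,
or a 5-9 point drop with a concurrent >= 15% relative DLco decline); a major
cardiac complication (EF < 45%, haemodynamically relevant pericardial
effusion, treated arrhythmia, or device need); scleroderma renal crisis;
severe gastrointestinal failure (enteral nutrition >= 3 weeks, parenteral
feeding, or admission for (pseudo-)obstruction); severe digital vasculopathy
requiring hospitalization; or skin worsening (mRSS increase >= 5 units and
>= 25% over baseline).  Death unrelated to SSc censors a subject; subjects
with no qualifying event are censored at their last visit, capped at 120
months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OUTCOME_COLUMNS

__all__ = [
    "AdjudicationRules",
    "AdjudicationError",
    "detect_ild_progression",
    "detect_skin_worsening",
    "detect_flag_events",
    "adjudicate_first_event",
    "adjudicate_cohort",
    "filter_complete_5yr",
    "SEVERITY_ORDER",
]


class AdjudicationError(ValueError):
    """Contract violation in the longitudinal input."""


@dataclass(frozen=True)
class AdjudicationRules:
    """Thresholds of the composite-event rules (all in clinical units).

    The minor FVC band is applied as ``fvc_abs_drop_minor_lo <= drop <
    fvc_abs_drop_major`` so that a continuous drop of e.g. 9.5 points is not
    lost between the published 5-9 band and the >= 10 major rule.
    """

    fvc_abs_drop_major: float = 10.0   # percent-predicted points
    fvc_abs_drop_minor_lo: float = 5.0
    dlco_rel_drop: float = 0.15        # relative decline
    window_months: float = 12.0
    mrss_abs_increase: float = 5.0     # units, inclusive
    mrss_rel_increase: float = 0.25    # relative to baseline, inclusive
    ef_threshold: float = 45.0
    enteral_weeks: float = 3.0
    horizon_months: float = 120.0

    def __post_init__(self) -> None:
        if self.fvc_abs_drop_minor_lo >= self.fvc_abs_drop_major:
            raise ValueError("minor FVC band must lie below the major threshold")
        for name in ("fvc_abs_drop_major", "dlco_rel_drop", "window_months",
                     "mrss_abs_increase", "mrss_rel_increase", "horizon_months"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Fixed tie-break order for simultaneous component events (most severe first).
SEVERITY_ORDER = [
    "ssc_death",
    "pah",
    "ild_progression",
    "cardiac",
    "renal_crisis",
    "gi",
    "digital_vasculopathy",
    "skin_worsening",
]

_CARDIAC_FLAGS = ["cardiac_ef_lt45", "pericardial_effusion_impairing",
                  "arrhythmia_treated", "cardiac_device"]
_GI_FLAGS = ["enteral_nutrition_3wk", "parenteral_feeding", "gi_obstruction_admission"]


def _check_sorted(visits: pd.DataFrame) -> None:
    t = visits["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise AdjudicationError("visits must be sorted by time")


def detect_ild_progression(visits: pd.DataFrame, rules: AdjudicationRules | None = None) -> float | None:
    """Earliest time at which the ILD-progression rule fires, else None.

    Scans every ordered visit pair (t1, t2) with t2 - t1 <= the 12-month
    window and both FVC values recorded.  The pair qualifies if the absolute
    FVC%-predicted drop is >= 10 points, or lies in the minor band [5, 10)
    with a concurrent relative DLco decline >= 15% between the same visits.
    Returns the qualifying t2 (event recorded when observed).
    """
    rules = rules or AdjudicationRules()
    _check_sorted(visits)
    t = visits["t"].to_numpy(dtype=float)
    fvc = visits["fvc_pct"].to_numpy(dtype=float)
    dlco = visits["dlco_pct"].to_numpy(dtype=float)
    best: float | None = None
    n = len(visits)
    for j in range(n):
        if np.isnan(fvc[j]):
            continue
        for i in range(j):
            if t[j] - t[i] > rules.window_months or np.isnan(fvc[i]):
                continue
            drop = fvc[i] - fvc[j]
            hit = False
            if drop >= rules.fvc_abs_drop_major:
                hit = True
            elif rules.fvc_abs_drop_minor_lo <= drop < rules.fvc_abs_drop_major:
                if not np.isnan(dlco[i]) and not np.isnan(dlco[j]) and dlco[i] > 0:
                    if (dlco[i] - dlco[j]) / dlco[i] >= rules.dlco_rel_drop:
                        hit = True
            if hit and (best is None or t[j] < best):
                best = float(t[j])
    return best


def detect_skin_worsening(baseline_mrss: float, visits: pd.DataFrame,
                          rules: AdjudicationRules | None = None) -> float | None:
    """Earliest visit where mRSS rises >= 5 units and >= 25% over baseline.

    Both thresholds are inclusive; with a baseline of 0 any >= 5-unit
    increase qualifies (the relative condition is treated as satisfied).
    """
    rules = rules or AdjudicationRules()
    if baseline_mrss is None or np.isnan(baseline_mrss) or baseline_mrss < 0:
        raise ValueError("baseline mRSS must be a non-negative number")
    _check_sorted(visits)
    for t, m in zip(visits["t"], visits["mrss"]):
        if m is None or np.isnan(m):
            continue
        if m < 0:
            raise ValueError("negative mRSS at a visit")
        inc = m - baseline_mrss
        if inc >= rules.mrss_abs_increase and (
            baseline_mrss == 0 or inc / baseline_mrss >= rules.mrss_rel_increase
        ):
            return float(t)
    return None


def detect_flag_events(baseline: pd.Series, visits: pd.DataFrame) -> list[tuple[str, float]]:
    """Map visit flags to (event_type, time) pairs.

    ``new_pah_rhc`` counts only for subjects without PAH at baseline (the
    endpoint requires *new* PAH).  Any cardiac flag maps to 'cardiac', any
    GI flag to 'gi'.  ``nonssc_death`` is returned as the pseudo-type
    'nonssc_death' so the adjudicator can censor there; it is not a
    component event.
    """
    _check_sorted(visits)
    out: list[tuple[str, float]] = []
    death_seen_at: float | None = None
    for _, row in visits.iterrows():
        t = float(row["t"])
        if death_seen_at is not None and t > death_seen_at:
            raise AdjudicationError("visit flag recorded after a death flag")
        if row["new_pah_rhc"] and not bool(baseline["pah"]):
            out.append(("pah", t))
        if row["renal_crisis"]:
            out.append(("renal_crisis", t))
        if any(row[f] for f in _CARDIAC_FLAGS):
            out.append(("cardiac", t))
        if any(row[f] for f in _GI_FLAGS):
            out.append(("gi", t))
        if row["digital_vasculopathy_admission"]:
            out.append(("digital_vasculopathy", t))
        if row["ssc_death"]:
            out.append(("ssc_death", t))
            death_seen_at = t
        if row["nonssc_death"]:
            out.append(("nonssc_death", t))
            death_seen_at = t
    return out


def adjudicate_first_event(baseline: pd.Series, visits: pd.DataFrame,
                           rules: AdjudicationRules | None = None) -> dict:
    """First-event adjudication for one subject.

    Returns ``{"subject_id", "event", "ttcw_months", "censored"}``.  The
    earliest qualifying time wins; exact ties are broken by the fixed
    severity order (death > PAH > ILD > cardiac > renal > GI > digital >
    skin).  A non-SSc death before any component event censors the subject
    there; otherwise censoring falls at min(last visit, 120 months).
    """
    rules = rules or AdjudicationRules()
    sid = baseline["subject_id"]
    if len(visits) == 0:
        warnings.warn(f"subject '{sid}': empty visit stream; censored at 0", stacklevel=2)
        return {"subject_id": sid, "event": "none", "ttcw_months": 0.0, "censored": True}
    visits = visits.sort_values("t", kind="mergesort").reset_index(drop=True)

    candidates: list[tuple[float, str]] = []
    t_ild = detect_ild_progression(visits, rules)
    if t_ild is not None:
        candidates.append((t_ild, "ild_progression"))
    t_skin = detect_skin_worsening(float(baseline["mrss"]), visits, rules)
    if t_skin is not None:
        candidates.append((t_skin, "skin_worsening"))
    nonssc_at: float | None = None
    for etype, t in detect_flag_events(baseline, visits):
        if etype == "nonssc_death":
            nonssc_at = t if nonssc_at is None else min(nonssc_at, t)
        else:
            candidates.append((t, etype))

    last_t = float(visits["t"].iloc[-1])
    censor_time = min(last_t, rules.horizon_months)
    if nonssc_at is not None:
        censor_time = min(censor_time, nonssc_at)
        candidates = [(t, e) for (t, e) in candidates if t <= nonssc_at]
    candidates = [(t, e) for (t, e) in candidates if t <= rules.horizon_months]

    if candidates:
        t_min = min(t for t, _ in candidates)
        simultaneous = [e for t, e in candidates if t == t_min]
        event = min(simultaneous, key=SEVERITY_ORDER.index)
        return {"subject_id": sid, "event": event, "ttcw_months": float(t_min),
                "censored": False}
    return {"subject_id": sid, "event": "none", "ttcw_months": float(censor_time),
            "censored": True}


def adjudicate_cohort(baseline: pd.DataFrame, visits: pd.DataFrame,
                      rules: AdjudicationRules | None = None) -> pd.DataFrame:
    """Adjudicate every subject -> outcomes table (subject order preserved)."""
    rules = rules or AdjudicationRules()
    groups = dict(tuple(visits.groupby("subject_id", sort=False)))
    empty = visits.iloc[0:0]
    rows = [
        adjudicate_first_event(row, groups.get(row["subject_id"], empty), rules)
        for _, row in baseline.iterrows()
    ]
    return pd.DataFrame(rows, columns=OUTCOME_COLUMNS)


def filter_complete_5yr(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity filter: keep subjects with an event, or >= 60 months event-free.

    Drops exactly the subjects censored before 60 months; censoring at 60
    months is retained (boundary inclusive).
    """
    keep = ~(outcomes["censored"] & (outcomes["ttcw_months"] < 60.0))
    return outcomes[keep].reset_index(drop=True)
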