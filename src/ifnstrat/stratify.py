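"""Clinical x serologic risk stratification and relative risks vs the cohort.

Clinical involvement classes: "acral" (mRSS strictly above 4 or digital-ulcer
disease), "cardiopulmonary" (PAH or ILD at baseline), "dual" (both) or
"none".  Crossing the four classes with the IFN high/low class yields eight
strata; subjects with at least one clinical involvement *and* a high IFN
score form the "high risk" group, everyone else "low risk".

Relative risks compare a group's KM cumulative incidence at a fixed horizon
with the overall cohort's.  Because every group is a subset of the cohort the
two estimates share subjects; confidence intervals therefore default to a
subject-level bootstrap, with an independence/delta-method approximation
available as a cheap alternative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survival import km_estimate

__all__ = [
    "assign_strata",
    "upset_counts",
    "rr_vs_overall",
    "INVOLVEMENT_CLASSES",
]

INVOLVEMENT_CLASSES = ["none", "acral", "cardiopulmonary", "dual"]


def assign_strata(baseline: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each subject an involvement class, IFN class and risk group.

    ``scores`` must carry subject_id and ifn_class.  mRSS > 4 is strict
    (a score of exactly 4 does not qualify as acral).
    """
    df = baseline[["subject_id", "mrss", "du_disease", "pah", "ild"]].merge(
        scores[["subject_id", "ifn_class"]], on="subject_id", validate="one_to_one"
    )
    acral = (df["mrss"] > 4) | df["du_disease"]
    cardio = df["pah"] | df["ild"]
    involvement = np.select(
        [acral & cardio, acral, cardio],
        ["dual", "acral", "cardiopulmonary"],
        default="none",
    )
    high_risk = (df["ifn_class"] == "high") & (involvement != "none")
    return pd.DataFrame({
        "subject_id": df["subject_id"],
        "acral": acral.to_numpy(),
        "cardiopulmonary": cardio.to_numpy(),
        "involvement": involvement,
        "ifn_class": df["ifn_class"].to_numpy(),
        "risk_group": np.where(high_risk, "high_risk", "low_risk"),
    })


def upset_counts(strata: pd.DataFrame, outcomes: pd.DataFrame,
                 event_threshold: float = 0.5) -> pd.DataFrame:
    """Per-stratum subject count, event count and event rate.

    Returns one row per (involvement x ifn_class) stratum present in the
    cohort, flagging strata whose event rate exceeds the 50% threshold.
    The counts partition the cohort (they sum to n).
    """
    df = strata.merge(outcomes[["subject_id", "censored"]], on="subject_id",
                      validate="one_to_one")
    df["event"] = ~df["censored"]
    rows = []
    for (inv, cls), grp in df.groupby(["involvement", "ifn_class"], sort=False):
        n = len(grp)
        ev = int(grp["event"].sum())
        rate = ev / n
        rows.append({"involvement": inv, "ifn_class": cls, "n": n,
                     "events": ev, "event_rate": rate,
                     "exceeds_threshold": rate > event_threshold})
    out = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(INVOLVEMENT_CLASSES)}
    return out.sort_values(
        ["involvement", "ifn_class"],
        key=lambda s: s.map(order) if s.name == "involvement" else s,
    ).reset_index(drop=True)


def _cuminc(durations, observed, t):
    curve = km_estimate(durations, observed)
    return 1.0 - curve.survival_at(t), curve.variance_at(t)


def rr_vs_overall(outcomes: pd.DataFrame, group_mask: np.ndarray,
                  horizons=(24.0, 36.0, 48.0), ci: str = "bootstrap",
                  n_bootstrap: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Relative risk of a subgroup vs the overall cohort at fixed horizons.

    RR(t) = (1 - S_group(t)) / (1 - S_overall(t)) from the KM curves.
    ``ci='bootstrap'`` resamples subjects (group and overall jointly, which
    respects their overlap); ``ci='delta'`` uses the delta method on log RR
    with Greenwood variances treating the two estimates as independent — an
    approximation, since the group is part of the cohort.
    Raises if the overall cohort has zero incidence at a horizon.
    """
    dur = outcomes["ttcw_months"].to_numpy(dtype=float)
    obs = (~outcomes["censored"]).to_numpy(dtype=bool)
    mask = np.asarray(group_mask, dtype=bool)
    if mask.shape != dur.shape:
        raise ValueError("group_mask must align with the outcomes table")
    if mask.sum() == 0:
        raise ValueError("empty group")
    rows = []
    rng = np.random.default_rng(seed)
    boot_idx = None
    if ci == "bootstrap":
        n = dur.size
        boot_idx = rng.integers(0, n, size=(n_bootstrap, n))
    for t in horizons:
        inc_g, var_g = _cuminc(dur[mask], obs[mask], t)
        inc_o, var_o = _cuminc(dur, obs, t)
        if inc_o <= 0:
            raise ValueError(f"overall cumulative incidence is zero at t={t}; RR undefined")
        rr = inc_g / inc_o
        if mask.all():
            lo = hi = rr  # group == cohort: RR is identically 1
        elif ci == "delta":
            if inc_g <= 0:
                lo, hi = 0.0, np.inf
            else:
                se_log = np.sqrt(var_g / inc_g ** 2 + var_o / inc_o ** 2)
                lo = rr * np.exp(-1.959963984540054 * se_log)
                hi = rr * np.exp(+1.959963984540054 * se_log)
        elif ci == "bootstrap":
            vals = []
            for b in range(n_bootstrap):
                take = boot_idx[b]
                m_b = mask[take]
                if m_b.sum() == 0:
                    continue
                ig, _ = _cuminc(dur[take][m_b], obs[take][m_b], t)
                io, _ = _cuminc(dur[take], obs[take], t)
                if io > 0:
                    vals.append(ig / io)
            lo, hi = np.percentile(vals, [2.5, 97.5]) if vals else (np.nan, np.nan)
        else:
            raise ValueError(f"unknown ci method '{ci}'")
        rows.append({"horizon": float(t), "incidence_group": inc_g,
                     "incidence_overall": inc_o, "rr": rr,
                     "ci_lo": float(lo), "ci_hi": float(hi), "ci_method": ci})
    return pd.DataFrame(rows)
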