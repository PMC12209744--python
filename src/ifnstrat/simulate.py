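"""Synthetic lcSSc cohort generator.

The study's patient-level data are not deposited, so every downstream stage
is exercised on cohorts drawn from a stated statistical world:

* healthy-control panels whose ln-score is N(4.97, 0.27^2) and patient
  panels with score N(5.45, 0.46^2) (~45% of patients land above the
  mean + 2 SD control threshold of ~5.51),
* per-chemokine ln concentrations equal to the subject's score plus fixed
  analyte offsets (calibrated to the published patient ln means) plus
  mean-zero noise constrained to preserve the score exactly,
* baseline covariates drawn at the published cohort prevalences,
* a latent first-event time from an exponential hazard carrying the
  configured IFN-high log-HR (default HR 2.0, the design value) plus
  clinical-covariate log-HRs mirroring the published multivariable
  associations (ILD, PAH, DU disease, mRSS),
* an event type drawn from the published first-event mix, realized in the
  6-monthly visit stream so that exactly the intended adjudication rule
  fires at the event visit (an ILD truth bends the FVC trajectory, a skin
  truth the mRSS, flag truths set the corresponding visit flag),
* administrative censoring from staggered entry (median ~89 months,
  IQR ~9, capped at 120 months).

The latent truth table (true event type, realized grid time, latent
continuous time, IFN score and the population-threshold IFN class) enables
generator/adjudicator recovery tests.  All randomness flows from one seeded
generator; a replicate index offsets the stream deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (BASELINE_COLUMNS, CHEMOKINES, PANEL_COLUMNS, VISIT_COLUMNS,
                 VISIT_FLAGS)

__all__ = ["SimConfig", "generate_controls", "generate_cohort"]


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


# Published patient per-chemokine ln means re-expressed as offsets from the
# cohort mean score 5.425 = mean(6.14, 3.78, 5.82, 6.93, 5.99, 3.89).
_DEFAULT_LOADING = {
    "ccl2": 6.14 - 5.425,
    "ccl8": 3.78 - 5.425,
    "ccl19": 5.82 - 5.425,
    "cxcl9": 6.93 - 5.425,
    "cxcl10": 5.99 - 5.425,
    "cxcl11": 3.89 - 5.425,
}

# First-event mix (counts out of 47): PAH 13, SSc death 9, ILD progression 6,
# cardiac 6, skin 5, GI 4, digital vasculopathy 3, renal crisis 1.
_DEFAULT_EVENT_MIX = {
    "pah": 13 / 47,
    "ssc_death": 9 / 47,
    "ild_progression": 6 / 47,
    "cardiac": 6 / 47,
    "skin_worsening": 5 / 47,
    "gi": 4 / 47,
    "digital_vasculopathy": 3 / 47,
    "renal_crisis": 1 / 47,
}

_DEFAULT_PREVALENCES = {
    "ana": 0.95, "aca": 0.67, "scl70": 0.081, "ro52": 0.23, "rnapol3": 0.027,
    "u1rnp": 0.054, "ild": 0.24, "pah": 0.06, "du_disease": 0.39,
    "calcinosis": 0.36, "upper_gi": 0.64, "sjogren_overlap": 0.10,
    "mmf": 0.087, "era": 0.047, "pde5i": 0.16, "iloprost": 0.17, "ccb": 0.63,
    "hcq": 0.17, "aspirin": 0.20, "ace": 0.34,
}

# Multivariable-scale clinical log-hazard ratios realized by the generator.
_DEFAULT_CLINICAL_LOG_HRS = {
    "ild": math.log(3.0),
    "pah": math.log(3.5),
    "du_disease": math.log(1.8),
    "mrss": math.log(1.12),   # per unit
}

_EVENT_FLAG = {
    "pah": "new_pah_rhc",
    "ssc_death": "ssc_death",
    "cardiac": "arrhythmia_treated",
    "gi": "gi_obstruction_admission",
    "digital_vasculopathy": "digital_vasculopathy_admission",
    "renal_crisis": "renal_crisis",
}


@dataclass(frozen=True)
class SimConfig:
    """The stated world of the synthetic cohort (all defaults published)."""

    seed: int = 0
    n_controls: int = 72
    n_patients: int = 149
    control_score_mean: float = 4.97
    control_score_sd: float = 0.27
    patient_score_mean: float = 5.45   # Table-1 value; the text's 5.50 is configurable
    patient_score_sd: float = 0.46
    chemokine_loading: dict = field(default_factory=lambda: dict(_DEFAULT_LOADING))
    chemokine_noise_sd: float = 0.40
    prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    mrss_mean: float = 2.09
    mrss_sd: float = 2.63
    fvc_mean: float = 109.0
    fvc_sd: float = 20.0
    dlco_mean: float = 67.0
    dlco_sd: float = 15.0
    age_mean: float = 60.0
    age_sd: float = 16.0
    female_fraction: float = 0.96
    disease_duration_median: float = 8.0
    base_hazard_per_month: float = 0.00132
    ifn_log_hr: float = math.log(2.0)       # design value, HR 2.0 high vs low
    clinical_log_hrs: dict = field(default_factory=lambda: dict(_DEFAULT_CLINICAL_LOG_HRS))
    event_mix: dict = field(default_factory=lambda: dict(_DEFAULT_EVENT_MIX))
    censor_median_months: float = 89.0
    censor_iqr_months: float = 9.0
    censor_min_months: float = 48.0
    horizon_months: float = 120.0
    visit_interval_months: float = 6.0
    fvc_noise_sd: float = 1.2
    dlco_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 1:
            raise ConfigError("cohort sizes too small")
        for name in ("control_score_sd", "patient_score_sd", "mrss_sd",
                     "visit_interval_months"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for k, v in self.prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"prevalence '{k}' outside [0, 1]")
        if abs(sum(self.event_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("event_mix must sum to 1")
        # typical-worst-case per-interval event probability must stay below 1
        # (mrss taken at mean + 3 SD; the realized per-subject hazards are
        # re-checked at generation time)
        worst_lp = max(self.ifn_log_hr, 0.0) + sum(
            max(b, 0.0) * (self.mrss_mean + 3 * self.mrss_sd if k == "mrss" else 1.0)
            for k, b in self.clinical_log_hrs.items()
        )
        if self.base_hazard_per_month * math.exp(worst_lp) * self.visit_interval_months > 1.0:
            raise ConfigError("hazard model implies per-visit event probability > 1")

    @property
    def population_threshold(self) -> float:
        """The control-population mean + 2 SD boundary (~5.51 by default)."""
        return self.control_score_mean + 2.0 * self.control_score_sd


def _rng(config: SimConfig, stream: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), int(replicate), stream])


def _panels(rng: np.random.Generator, ids: list[str], scores: np.ndarray,
            config: SimConfig) -> pd.DataFrame:
    n = len(ids)
    offsets = np.array([config.chemokine_loading[c] for c in CHEMOKINES])
    noise = rng.normal(0.0, config.chemokine_noise_sd, size=(n, len(CHEMOKINES)))
    noise -= noise.mean(axis=1, keepdims=True)   # preserve the score exactly
    ln_conc = scores[:, None] + offsets[None, :] + noise
    df = pd.DataFrame(np.exp(ln_conc), columns=CHEMOKINES)
    df.insert(0, "subject_id", ids)
    df["sample_months_from_baseline"] = 0.0
    return df[PANEL_COLUMNS]


def generate_controls(config: SimConfig | None = None, replicate: int = 0) -> pd.DataFrame:
    """Healthy-control chemokine panel table (n_controls rows).

    Each control's score is drawn N(control_score_mean, control_score_sd^2)
    and the six ln concentrations are allocated around it, so the computed
    score of every generated panel equals its drawn score.
    """
    config = config or SimConfig()
    rng = _rng(config, stream=1, replicate=replicate)
    ids = [f"HC{i + 1:03d}" for i in range(config.n_controls)]
    scores = rng.normal(config.control_score_mean, config.control_score_sd,
                        size=config.n_controls)
    return _panels(rng, ids, scores, config)


def _draw_baseline(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]
    rows: dict = {"subject_id": ids}
    rows["age"] = np.round(np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 95), 1)
    rows["sex"] = np.where(rng.random(n) < config.female_fraction, "female", "male")
    rows["disease_duration"] = np.round(
        rng.gamma(shape=1.6, scale=config.disease_duration_median / 1.6 / 0.81, size=n), 1)
    for flag, p in config.prevalences.items():
        rows[flag] = rng.random(n) < p
    mrss = np.maximum(np.round(rng.normal(config.mrss_mean, config.mrss_sd, n)), 0)
    rows["mrss"] = np.clip(mrss, 0, 51).astype(int)
    rows["fvc_pct"] = np.round(np.clip(rng.normal(config.fvc_mean, config.fvc_sd, n), 40, 160), 1)
    rows["dlco_pct"] = np.round(np.clip(rng.normal(config.dlco_mean, config.dlco_sd, n), 20, 140), 1)
    return pd.DataFrame(rows)[BASELINE_COLUMNS]


def _draw_event_types(rng: np.random.Generator, baseline: pd.DataFrame,
                      config: SimConfig) -> np.ndarray:
    """Event type per subject; baseline-PAH subjects never draw a PAH event."""
    types = list(config.event_mix)
    probs = np.array([config.event_mix[t] for t in types])
    out = np.empty(len(baseline), dtype=object)
    no_pah_probs = probs.copy()
    if "pah" in types:
        no_pah_probs[types.index("pah")] = 0.0
        no_pah_probs = no_pah_probs / no_pah_probs.sum()
    for i, has_pah in enumerate(baseline["pah"].to_numpy()):
        p = no_pah_probs if has_pah else probs
        out[i] = types[rng.choice(len(types), p=p)]
    return out


def generate_cohort(config: SimConfig | None = None, replicate: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (baseline, panels, visits, truth) tables for one cohort.

    The visit stream realizes the latent first event so that the composite
    adjudication rules recover the intended event type at the event visit:
    between-visit FVC/DLco/mRSS noise is kept well inside the rule
    thresholds, and the event visit is the last visit of an event subject
    (subjects are censored at their first event).
    """
    config = config or SimConfig()
    rng = _rng(config, stream=2, replicate=replicate)
    baseline = _draw_baseline(rng, config)
    n = len(baseline)

    scores = rng.normal(config.patient_score_mean, config.patient_score_sd, size=n)
    panels = _panels(rng, list(baseline["subject_id"]), scores, config)
    ifn_high = scores > config.population_threshold

    linpred = config.ifn_log_hr * ifn_high.astype(float)
    for cov, beta in config.clinical_log_hrs.items():
        linpred = linpred + beta * baseline[cov].to_numpy(dtype=float)
    rate = config.base_hazard_per_month * np.exp(linpred)
    if np.any(rate * config.visit_interval_months > 1.0):
        raise ConfigError("hazard model implies per-visit event probability > 1 "
                          "for a generated subject")
    latent_t = rng.exponential(1.0 / rate)

    # administrative censoring: staggered entry, median ~89, IQR ~9, cap 120
    sd = config.censor_iqr_months / 1.349
    a = (config.censor_min_months - config.censor_median_months) / sd
    b = (config.horizon_months - config.censor_median_months) / sd
    censor = stats.truncnorm.rvs(a, b, loc=config.censor_median_months, scale=sd,
                                 size=n, random_state=rng)

    event_types = _draw_event_types(rng, baseline, config)

    dt = config.visit_interval_months
    visit_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(n):
        sid = baseline["subject_id"].iloc[i]
        fvc0 = baseline["fvc_pct"].iloc[i]
        dlco0 = baseline["dlco_pct"].iloc[i]
        mrss0 = int(baseline["mrss"].iloc[i])
        last_grid = math.floor(min(censor[i], config.horizon_months) / dt) * dt
        t_event = math.ceil(max(latent_t[i], dt) / dt) * dt
        has_event = t_event <= last_grid
        end = t_event if has_event else last_grid
        etype = event_types[i] if has_event else "none"

        grid = np.arange(0.0, end + dt / 2, dt)
        fvc = fvc0 + rng.normal(0.0, config.fvc_noise_sd, size=grid.size)
        fvc[0] = fvc0
        dlco = dlco0 + rng.normal(0.0, config.dlco_noise_sd, size=grid.size)
        dlco[0] = dlco0
        mrss = np.full(grid.size, mrss0, dtype=float)
        flags = {f: np.zeros(grid.size, dtype=bool) for f in VISIT_FLAGS}

        if has_event:
            k = grid.size - 1
            if etype == "ild_progression":
                fvc[k] = fvc[k - 1] - 12.0
            elif etype == "skin_worsening":
                mrss[k] = mrss0 + max(5, math.ceil(0.25 * mrss0))
            else:
                flags[_EVENT_FLAG[etype]][k] = True

        for k, t in enumerate(grid):
            row = {"subject_id": sid, "t": float(t),
                   "fvc_pct": round(float(fvc[k]), 1),
                   "dlco_pct": round(float(dlco[k]), 1),
                   "mrss": float(mrss[k])}
            for f in VISIT_FLAGS:
                row[f] = bool(flags[f][k])
            visit_rows.append(row)

        truth_rows.append({
            "subject_id": sid, "true_event": etype,
            "true_time": float(end), "latent_time": float(latent_t[i]),
            "censor_time": float(last_grid), "ifn_score": float(scores[i]),
            "ifn_high": bool(ifn_high[i]),
        })

    visits = pd.DataFrame(visit_rows)[VISIT_COLUMNS]
    truth = pd.DataFrame(truth_rows)
    return baseline, panels, visits, truth
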