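"""Canonical data model and delimited-text IO for the lcSSc cohort.

The cohort bundle holds four (optionally five) comma-separated tables:

* ``controls`` — healthy-control chemokine panels (pg/mL),
* ``baseline`` — one row per patient: demographics, autoantibodies, organ
  involvement, skin score, lung function and treatments at the serum-sample
  baseline,
* ``panels`` — the patients' chemokine panels,
* ``visits`` — the ~6-monthly longitudinal stream (FVC%, DLco%, mRSS and
  event-qualifying flags),
* ``outcomes`` — adjudicated first-event table (may be absent until the
  endpoint has been adjudicated).

Time is measured in months since the serum-sample baseline everywhere.
Booleans are serialized as 0/1, decimals with ``.``, and the column order is
fixed so that write/read round-trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ReferentialError",
    "CohortBundle",
    "read_cohort",
    "write_cohort",
    "CHEMOKINES",
    "PANEL_COLUMNS",
    "BASELINE_COLUMNS",
    "VISIT_COLUMNS",
    "VISIT_FLAGS",
    "OUTCOME_COLUMNS",
    "EVENT_TYPES",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong dtype."""


class ValidationError(ValueError):
    """A row violates a documented invariant."""


class ReferentialError(ValueError):
    """A child row references a subject absent from the baseline table."""


#: The six type-I-IFN-inducible serum chemokines entering the score.
CHEMOKINES = ["ccl2", "ccl8", "ccl19", "cxcl9", "cxcl10", "cxcl11"]

PANEL_COLUMNS = ["subject_id", *CHEMOKINES, "sample_months_from_baseline"]

AUTOANTIBODY_FLAGS = ["ana", "aca", "scl70", "ro52", "rnapol3", "u1rnp"]
ORGAN_FLAGS = ["ild", "pah", "du_disease", "calcinosis", "upper_gi", "sjogren_overlap"]
TREATMENT_FLAGS = ["mmf", "era", "pde5i", "iloprost", "ccb", "hcq", "aspirin", "ace"]

BASELINE_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "disease_duration",
    *AUTOANTIBODY_FLAGS,
    *ORGAN_FLAGS,
    "mrss",
    "fvc_pct",
    "dlco_pct",
    *TREATMENT_FLAGS,
]

#: Morbi-mortality component flags recordable at a visit.  ``nonssc_death``
#: is not a component event: it censors the subject at that visit.
VISIT_FLAGS = [
    "new_pah_rhc",
    "renal_crisis",
    "cardiac_ef_lt45",
    "pericardial_effusion_impairing",
    "arrhythmia_treated",
    "cardiac_device",
    "enteral_nutrition_3wk",
    "parenteral_feeding",
    "gi_obstruction_admission",
    "digital_vasculopathy_admission",
    "ssc_death",
    "nonssc_death",
]

VISIT_COLUMNS = ["subject_id", "t", "fvc_pct", "dlco_pct", "mrss", *VISIT_FLAGS]

EVENT_TYPES = [
    "pah",
    "ssc_death",
    "ild_progression",
    "cardiac",
    "skin_worsening",
    "gi",
    "digital_vasculopathy",
    "renal_crisis",
    "none",
]

OUTCOME_COLUMNS = ["subject_id", "event", "ttcw_months", "censored"]

_BOOL_BASELINE = AUTOANTIBODY_FLAGS + ORGAN_FLAGS + TREATMENT_FLAGS


@dataclass
class CohortBundle:
    """Validated in-memory cohort: controls, baseline, panels, visits, outcomes."""

    controls: pd.DataFrame
    baseline: pd.DataFrame
    panels: pd.DataFrame
    visits: pd.DataFrame
    outcomes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.controls = _validate_panels(self.controls, "controls")
        self.panels = _validate_panels(self.panels, "panels")
        self.baseline = _validate_baseline(self.baseline)
        self.visits = _validate_visits(self.visits, set(self.baseline["subject_id"]))
        if self.outcomes is not None:
            self.outcomes = _validate_outcomes(self.outcomes)

    @property
    def n_patients(self) -> int:
        return len(self.baseline)


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table}: missing required column '{c}'")


def _validate_panels(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.copy()
    if "sample_months_from_baseline" not in df.columns:
        df["sample_months_from_baseline"] = 0.0
    _require_columns(df, PANEL_COLUMNS, table)
    df = df[PANEL_COLUMNS]
    if df["subject_id"].astype(str).str.len().eq(0).any():
        raise ValidationError(f"{table}: empty subject_id")
    for c in CHEMOKINES:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{table}: non-positive or missing {c} concentration at row {row}"
            )
        df[c] = vals.astype(float)
    return df.reset_index(drop=True)


def _validate_baseline(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, BASELINE_COLUMNS, "baseline")
    df = df[BASELINE_COLUMNS].copy()
    if df["subject_id"].duplicated().any():
        raise ValidationError("baseline: duplicated subject_id")
    bad_sex = ~df["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValidationError(
            f"baseline: sex must be 'female' or 'male' (row {int(np.flatnonzero(bad_sex)[0])})"
        )
    mrss = pd.to_numeric(df["mrss"], errors="coerce")
    if ((mrss < 0) | (mrss > 51) | mrss.isna()).any():
        raise ValidationError("baseline: mrss must lie in [0, 51]")
    df["mrss"] = mrss.astype(int)
    for c in ("fvc_pct", "dlco_pct"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if ((vals <= 0) | (vals >= 200) | vals.isna()).any():
            raise ValidationError(f"baseline: {c} must lie in (0, 200)")
        df[c] = vals.astype(float)
    for c in _BOOL_BASELINE:
        df[c] = df[c].astype(float).astype(bool)
    for c in ("age", "disease_duration"):
        df[c] = pd.to_numeric(df[c]).astype(float)
    return df.reset_index(drop=True)


def _validate_visits(df: pd.DataFrame, known_ids: set) -> pd.DataFrame:
    _require_columns(df, VISIT_COLUMNS, "visits")
    df = df[VISIT_COLUMNS].copy()
    unknown = ~df["subject_id"].isin(known_ids)
    if unknown.any():
        sid = df.loc[unknown, "subject_id"].iloc[0]
        raise ReferentialError(f"visits: subject '{sid}' not present in baseline table")
    df["t"] = pd.to_numeric(df["t"]).astype(float)
    if (df["t"] < 0).any():
        raise ValidationError("visits: t must be >= 0")
    for c in ("fvc_pct", "dlco_pct", "mrss"):
        df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)
    for c in VISIT_FLAGS:
        df[c] = df[c].fillna(0).astype(float).astype(bool)
    df = df.sort_values(["subject_id", "t"], kind="mergesort").reset_index(drop=True)
    # a death flag must be unique within a subject and terminate the stream
    death = df["ssc_death"] | df["nonssc_death"]
    for sid, grp in df[death].groupby("subject_id", sort=False):
        if len(grp) > 1:
            raise ValidationError(f"visits: multiple death flags for subject '{sid}'")
        t_death = grp["t"].iloc[0]
        later = df[(df["subject_id"] == sid) & (df["t"] > t_death)]
        if len(later):
            raise ValidationError(f"visits: visit after death flag for subject '{sid}'")
    return df


def _validate_outcomes(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, OUTCOME_COLUMNS, "outcomes")
    df = df[OUTCOME_COLUMNS].copy()
    if (~df["event"].isin(EVENT_TYPES)).any():
        raise ValidationError("outcomes: unknown event type")
    df["ttcw_months"] = pd.to_numeric(df["ttcw_months"]).astype(float)
    df["censored"] = df["censored"].astype(float).astype(bool)
    if (df["censored"] != (df["event"] == "none")).any():
        raise ValidationError("outcomes: censored must hold exactly when event == 'none'")
    if (df["ttcw_months"] > 120).any():
        raise ValidationError("outcomes: ttcw_months must be <= 120")
    return df.reset_index(drop=True)


_TABLES = {
    "controls": "controls.csv",
    "baseline": "baseline.csv",
    "panels": "panels.csv",
    "visits": "visits.csv",
    "outcomes": "outcomes.csv",
}


def read_cohort(
    directory: str | Path | None = None,
    *,
    controls: str | Path | None = None,
    baseline: str | Path | None = None,
    panels: str | Path | None = None,
    visits: str | Path | None = None,
    outcomes: str | Path | None = None,
) -> CohortBundle:
    """Read and validate a cohort bundle from CSV files.

    Either pass ``directory`` holding the conventional file names
    (``controls.csv`` etc.) or explicit per-table paths.  ``outcomes.csv``
    is optional in both modes.
    """
    paths: dict[str, Path | None] = {
        "controls": controls, "baseline": baseline, "panels": panels,
        "visits": visits, "outcomes": outcomes,
    }
    if directory is not None:
        d = Path(directory)
        for key, fname in _TABLES.items():
            if paths[key] is None:
                p = d / fname
                if key == "outcomes" and not p.exists():
                    continue
                paths[key] = p
    for key in ("controls", "baseline", "panels", "visits"):
        if paths[key] is None:
            raise FileNotFoundError(f"no path given for required table '{key}'")
    frames: dict[str, pd.DataFrame | None] = {}
    for key, p in paths.items():
        if p is None:
            frames[key] = None
            continue
        frames[key] = pd.read_csv(p, dtype={"subject_id": str})
    return CohortBundle(
        controls=frames["controls"],
        baseline=frames["baseline"],
        panels=frames["panels"],
        visits=frames["visits"],
        outcomes=frames["outcomes"],
    )


def write_cohort(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write a validated bundle as CSV tables; returns the written paths.

    Booleans go out as 0/1, missing optional measurements as empty cells.
    ``read_cohort(write_cohort(x)) == x`` field-by-field for valid bundles.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for key, fname in _TABLES.items():
        df = getattr(bundle, key)
        if df is None:
            continue
        out = df.copy()
        for c in out.columns:
            if out[c].dtype == bool:
                out[c] = out[c].astype(int)
        p = d / fname
        out.to_csv(p, index=False)
        written[key] = p
    return written
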