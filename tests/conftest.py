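import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import ifnstrat as I
from ifnstrat.io import VISIT_FLAGS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_visits(rows):
    """Build a visit table from dicts of the non-default fields."""
    base = {"subject_id": "S1", "t": 0.0, "fvc_pct": np.nan, "dlco_pct": np.nan,
            "mrss": np.nan, **{f: False for f in VISIT_FLAGS}}
    return pd.DataFrame([{**base, **r} for r in rows])


def make_baseline_row(**kw):
    row = {"subject_id": "S1", "age": 60.0, "sex": "female",
           "disease_duration": 8.0, "ana": True, "aca": True, "scl70": False,
           "ro52": False, "rnapol3": False, "u1rnp": False, "ild": False,
           "pah": False, "du_disease": False, "calcinosis": False,
           "upper_gi": False, "sjogren_overlap": False, "mrss": 2,
           "fvc_pct": 109.0, "dlco_pct": 67.0, "mmf": False, "era": False,
           "pde5i": False, "iloprost": False, "ccb": False, "hcq": False,
           "aspirin": False, "ace": False}
    row.update(kw)
    return pd.Series(row)


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    cfg = I.SimConfig(seed=42, n_patients=60, n_controls=24)
    baseline, panels, visits, truth = I.generate_cohort(cfg)
    controls = I.generate_controls(cfg)
    return {"config": cfg, "baseline": baseline, "panels": panels,
            "visits": visits, "truth": truth, "controls": controls}


@pytest.fixture(scope="session")
def small_outcomes(small_cohort):
    return I.adjudicate_cohort(small_cohort["baseline"], small_cohort["visits"])
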