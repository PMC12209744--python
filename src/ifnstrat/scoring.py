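"""Six-chemokine type-I IFN score, healthy-control threshold, classification.

The score of a serum sample is the mean of the natural logarithms of the
concentrations (pg/mL) of CCL2, CCL8, CCL19, CXCL9, CXCL10 and CXCL11.  The
"high" threshold is the healthy-control mean plus two sample standard
deviations; patients strictly above the threshold are classified high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import CHEMOKINES

__all__ = [
    "ScoringError",
    "ThresholdModel",
    "compute_ifn_score",
    "score_panels",
    "derive_threshold",
    "classify",
    "classify_panels",
]


class ScoringError(ValueError):
    """A panel cannot be scored (missing or non-positive analyte)."""


@dataclass(frozen=True)
class ThresholdModel:
    """Healthy-control reference: threshold = hc_mean + 2 * hc_sd (sample SD)."""

    hc_mean: float
    hc_sd: float
    threshold: float
    n_controls: int

    @classmethod
    def from_summary(cls, hc_mean: float, hc_sd: float, n_controls: int = 2) -> "ThresholdModel":
        """Build a model from summary statistics (e.g. a published mean/SD)."""
        if hc_sd < 0:
            raise ValueError("hc_sd must be non-negative")
        return cls(hc_mean=float(hc_mean), hc_sd=float(hc_sd),
                   threshold=float(hc_mean) + 2.0 * float(hc_sd),
                   n_controls=int(n_controls))

    def to_dict(self) -> dict:
        return {"hc_mean": self.hc_mean, "hc_sd": self.hc_sd,
                "threshold": self.threshold, "n_controls": self.n_controls}


def compute_ifn_score(panel: Mapping[str, float] | pd.Series) -> float:
    """IFN score of one panel: (1/6) * sum of ln concentrations.

    Order-invariant in the analytes; adding a factor c to every
    concentration multiplicatively shifts the score by ln c.

    Raises :class:`ScoringError` naming the offending analyte if any of the
    six concentrations is missing, non-finite or not strictly positive.
    """
    total = 0.0
    for analyte in CHEMOKINES:
        try:
            value = float(panel[analyte])
        except (KeyError, TypeError, ValueError):
            raise ScoringError(f"missing concentration for analyte '{analyte}'") from None
        if not np.isfinite(value) or value <= 0:
            raise ScoringError(f"non-positive concentration for analyte '{analyte}': {value!r}")
        total += np.log(value)
    return total / len(CHEMOKINES)


def score_panels(panels: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a panel table -> DataFrame[subject_id, ifn_score]."""
    arr = panels[CHEMOKINES].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        bad = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[0]
        raise ScoringError(
            f"non-positive concentration for analyte '{CHEMOKINES[bad[1]]}' at row {bad[0]}"
        )
    scores = np.log(arr).mean(axis=1)
    return pd.DataFrame({"subject_id": panels["subject_id"].to_numpy(), "ifn_score": scores})


def derive_threshold(hc_scores: Iterable[float]) -> ThresholdModel:
    """Derive the high/low threshold from healthy-control scores.

    threshold = mean + 2 * SD with the n-1 (sample) standard deviation.
    Requires at least two controls; identical controls yield SD 0 and a
    degenerate threshold equal to the mean, with a warning.
    """
    scores = np.asarray(list(hc_scores), dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 healthy-control scores to derive a threshold")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite healthy-control score")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        warnings.warn("healthy-control scores have zero variance; threshold equals the mean",
                      stacklevel=2)
    return ThresholdModel(hc_mean=mean, hc_sd=sd, threshold=mean + 2.0 * sd,
                          n_controls=int(scores.size))


def classify(score: float, model: ThresholdModel) -> str:
    """Classify a score as 'high' (strictly above threshold) or 'low'.

    A score exactly on the threshold is 'low': the rule is "above" and the
    score is continuous, so ties carry no probability mass.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return "high" if score > model.threshold else "low"


def classify_panels(panels: pd.DataFrame, model: ThresholdModel) -> pd.DataFrame:
    """Score and classify a panel table -> DataFrame[subject_id, ifn_score, ifn_class]."""
    out = score_panels(panels)
    out["ifn_class"] = np.where(out["ifn_score"] > model.threshold, "high", "low")
    return out
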