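"""Event-driven sample-size design for a two-arm time-to-worsening trial.

Implements the transparent Schoenfeld closed form for the required number of
events under a log-rank comparison, an incidence-based conversion from
events to per-arm sample size, and the multiplicative censoring inflation.
The arm-2 event probability defaults to the proportional-hazards transform
P2 = 1 - (1 - P1)^HR of the arm-1 cumulative incidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "PowerSpec",
    "schoenfeld_events",
    "sample_size_from_events",
    "censoring_inflation",
    "design_summary",
]


@dataclass(frozen=True)
class PowerSpec:
    """Design assumptions for the event-driven TTCW comparison."""

    hr: float = 2.0                     # hypothesized hazard ratio, arm 2 vs arm 1
    alpha: float = 0.05                 # two-sided
    power: float = 0.80
    allocation: float = 0.5             # fraction allocated to arm 1
    control_event_prob: float = 0.40    # arm-1 cumulative incidence over follow-up
    censoring_allowance: float = 0.25
    accrual_max_months: float = 120.0

    def __post_init__(self) -> None:
        if self.hr <= 0 or self.hr == 1.0:
            raise ValueError("hr must be positive and different from 1")
        for name in ("alpha", "power", "allocation", "control_event_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.censoring_allowance < 1.0:
            raise ValueError("censoring_allowance must lie in [0, 1)")


def schoenfeld_events(hr: float, alpha: float = 0.05, power: float = 0.80,
                      allocation: float = 0.5) -> int:
    """Required events: ceil[(z_{1-a/2} + z_pow)^2 / (p(1-p) ln^2 HR)].

    Symmetric in HR vs 1/HR; strictly decreasing in abs(ln HR) and
    increasing in power.
    """
    if hr <= 0 or hr == 1.0:
        raise ValueError("hazard ratio of 1 requires infinitely many events")
    if not (0 < alpha < 1 and 0 < power < 1 and 0 < allocation < 1):
        raise ValueError("alpha, power and allocation must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    d = (z_a + z_b) ** 2 / (allocation * (1.0 - allocation) * math.log(hr) ** 2)
    return math.ceil(d)


def sample_size_from_events(events: int, p1: float, p2: float | None = None,
                            hr: float | None = None,
                            allocation: float = 0.5) -> dict:
    """Per-arm sample size from the required events and event probabilities.

    n_total = events / (a*p1 + (1-a)*p2), split by allocation and rounded up
    per arm.  If ``p2`` is omitted it is derived from ``p1`` and ``hr`` via
    the proportional-hazards transform P2 = 1 - (1 - P1)^HR.
    """
    if p2 is None:
        if hr is None:
            raise ValueError("give either p2 or hr")
        p2 = 1.0 - (1.0 - p1) ** hr
    if not (0.0 < p1 <= 1.0 and 0.0 < p2 <= 1.0):
        raise ValueError("event probabilities must lie in (0, 1]; zero makes the design infeasible")
    expected_rate = allocation * p1 + (1.0 - allocation) * p2
    n_total = events / expected_rate
    n1 = math.ceil(n_total * allocation)
    n2 = math.ceil(n_total * (1.0 - allocation))
    return {"events": int(events), "p1": p1, "p2": p2, "n_arm1": n1, "n_arm2": n2,
            "n_total": n1 + n2}


def censoring_inflation(total_n: int, allowance: float) -> int:
    """Inflate a sample size for anticipated censoring: ceil(n * (1 + c))."""
    if not 0.0 <= allowance < 1.0:
        raise ValueError("allowance must lie in [0, 1)")
    # round first: 100 * 1.1 = 110.00000000000001 must not ceil to 111
    return math.ceil(round(total_n * (1.0 + allowance), 9))


def design_summary(spec: PowerSpec | None = None) -> dict:
    """Events, per-arm n and censoring-inflated total for a design spec."""
    spec = spec or PowerSpec()
    events = schoenfeld_events(spec.hr, spec.alpha, spec.power, spec.allocation)
    sizes = sample_size_from_events(events, spec.control_event_prob, hr=spec.hr,
                                    allocation=spec.allocation)
    inflated = censoring_inflation(sizes["n_total"], spec.censoring_allowance)
    return {"spec": spec, "required_events": events, **sizes,
            "n_total_inflated": inflated}
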