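"""Health-economic quantities: discounting, QALY gain, the incremental
cost-effectiveness ratio (ICER) and dominance classification.

The ICER follows the full-horizon convention in which costs and effects are
discounted by the same factor (avoiding the Keeler-Cretin paradox):

    ICER = (ATT_cost + intervention_cost)
           / (delta_EQ5D * horizon_years * (1 + rate)^-horizon_years)

with defaults of a 2-year horizon, 3 % annual discount rate and a €1,500
programme cost (training plus coaching; the optional €100 x 2 exercise
bonus is excluded by default but can be added via ``extra_cost``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError

DEFAULT_INTERVENTION_COST = 1500.0
DEFAULT_DISCOUNT_RATE = 0.03
DEFAULT_HORIZON_YEARS = 2

DOMINANCE_CLASSES = (
    "dominant", "cost_effective_NE", "dominated", "inferior_SW", "indeterminate",
)


@dataclass(frozen=True)
class EconomicResult:
    att_cost: float
    intervention_cost: float
    delta_eq5d: float
    horizon_years: int
    discount_rate: float
    incremental_cost: float
    qaly_gain: float
    icer: float               # NaN when delta_eq5d == 0
    icer_defined: bool
    dominance: str


def discount_factor(rate: float, horizon_years: int = DEFAULT_HORIZON_YEARS) -> float:
    """Full-horizon discount factor (1 + rate)^-horizon_years."""
    if rate < 0:
        raise ConfigError("discount rate must be >= 0")
    if horizon_years < 1:
        raise ConfigError("horizon must be >= 1 year")
    return (1.0 + rate) ** (-horizon_years)


def classify_dominance(incremental_cost: float, qaly_gain: float) -> str:
    """Cost-effectiveness-plane quadrant of (effect, cost).

    dominant: cheaper and more effective (SE quadrant);
    cost_effective_NE: costlier and more effective;
    dominated: costlier and less effective (NW);
    inferior_SW: cheaper and less effective;
    indeterminate: on an axis.
    """
    if qaly_gain > 0 and incremental_cost < 0:
        return "dominant"
    if qaly_gain > 0 and incremental_cost > 0:
        return "cost_effective_NE"
    if qaly_gain < 0 and incremental_cost > 0:
        return "dominated"
    if qaly_gain < 0 and incremental_cost < 0:
        return "inferior_SW"
    return "indeterminate"


def icer(att_cost: float, intervention_cost: float = DEFAULT_INTERVENTION_COST,
         delta_eq5d: float = 0.0, horizon_years: int = DEFAULT_HORIZON_YEARS,
         rate: float = DEFAULT_DISCOUNT_RATE,
         extra_cost: float = 0.0) -> EconomicResult:
    """Incremental cost-effectiveness ratio from a discounted cost ATT and an
    EQ-5D arm contrast.

    ``att_cost`` is the (already discounted) DiD cost effect; the programme
    cost enters the numerator separately.  ``extra_cost`` allows exploratory
    additions such as the exercise bonus.  With ``delta_eq5d == 0`` the
    ratio is undefined; the result is flagged and dominance falls back to
    the cost sign alone.
    """
    inc = att_cost + intervention_cost + extra_cost
    qaly = delta_eq5d * horizon_years * discount_factor(rate, horizon_years)
    if delta_eq5d == 0.0:
        dominance = ("dominant" if inc < 0
                     else "dominated" if inc > 0 else "indeterminate")
        return EconomicResult(
            att_cost=att_cost,
            intervention_cost=intervention_cost + extra_cost,
            delta_eq5d=delta_eq5d,
            horizon_years=horizon_years,
            discount_rate=rate,
            incremental_cost=inc,
            qaly_gain=qaly,
            icer=float("nan"),
            icer_defined=False,
            dominance=dominance,
        )
    return EconomicResult(
        att_cost=att_cost,
        intervention_cost=intervention_cost + extra_cost,
        delta_eq5d=delta_eq5d,
        horizon_years=horizon_years,
        discount_rate=rate,
        incremental_cost=inc,
        qaly_gain=qaly,
        icer=inc / qaly,
        icer_defined=True,
        dominance=classify_dominance(inc, qaly),
    )


def net_monetary_benefit(incremental_cost, qaly_gain, wtp: float):
    """NMB = wtp x QALY gain - incremental cost; positive means
    cost-effective at the willingness-to-pay threshold ``wtp``."""
    if np.any(np.asarray(wtp) < 0):
        raise ConfigError("willingness-to-pay must be >= 0")
    return wtp * np.asarray(qaly_gain) - np.asarray(incremental_cost)
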