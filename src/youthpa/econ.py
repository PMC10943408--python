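"""Economic valuation of life-course records.

Payer perspective: discounted direct medical costs.  Societal perspective
adds productivity losses, proxied by ``daily wage x (1 - utility weight) x
duration``, accrued by everyone regardless of age or employment.  All flows
are discounted to the cohort reference year (2023) at 3%/year and reported in
2023 USD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifecourse import DEATH_STATE, LifeCourseRecord
from .params import EVENT_TYPES, MarkovParamSet

PERSPECTIVES = ("payer", "societal")
DAYS_PER_YEAR_ECON = 365.0


@dataclass(frozen=True)
class EconParams:
    discount_rate: float = 0.03
    reference_year: int = 2023
    perspective: str = "societal"

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")


@dataclass
class EconSummary:
    """Discounted totals for one record."""

    direct_medical_cost: float
    productivity_loss: float
    qalys: float
    life_years: float

    @property
    def payer_total(self) -> float:
        return self.direct_medical_cost

    @property
    def societal_total(self) -> float:
        return self.direct_medical_cost + self.productivity_loss

    def total(self, perspective: str) -> float:
        if perspective == "payer":
            return self.payer_total
        if perspective == "societal":
            return self.societal_total
        raise ValueError(f"unknown perspective {perspective!r}")


def productivity_loss(daily_wage: float, utility_weight: float,
                      duration_days: float) -> float:
    """Presenteeism proxy: wage x (1 - utility) x duration."""
    if not 0.0 <= utility_weight <= 1.0:
        raise ValueError("utility weight must lie in [0, 1]")
    if duration_days < 0:
        raise ValueError("duration must be >= 0")
    return daily_wage * (1.0 - utility_weight) * duration_days


def discount(amount, years_from_reference, params: EconParams):
    """Net present value at the configured annual rate."""
    years = np.asarray(years_from_reference, dtype=float)
    if (years < 0).any():
        raise ValueError("years_from_reference must be >= 0")
    out = np.asarray(amount, dtype=float) / (1.0 + params.discount_rate) ** years
    return float(out) if out.ndim == 0 else out


def year_utility(state: int, events, params: MarkovParamSet) -> float:
    """Utility weight for one cycle: state utility minus event disutilities,
    floored at zero."""
    disutil = sum(params.event_disutility[t]
                  for t in range(len(EVENT_TYPES)) if events[t])
    return max(float(params.state_utility[state]) - disutil, 0.0)


def summarize(record: LifeCourseRecord, params: MarkovParamSet,
              econ: EconParams) -> EconSummary:
    """Discounted costs, productivity losses, QALYs and life-years for one
    adult record.

    Mirrors the batch engine's accrual convention: event costs accrue in the
    cycle of the event regardless of survival; state cost, utility, the
    productivity loss and the life-year accrue only in cycles the agent
    survives.  Childhood years (utility 1, no medical cost) contribute no
    incremental accrual and are excluded.
    """
    direct = 0.0
    prod = 0.0
    qalys = 0.0
    life_years = 0.0
    for cycle, (state, events) in enumerate(zip(record.states, record.events)):
        years = record.years_from_reference_at_entry + cycle
        ecost = sum(params.event_cost[t]
                    for t in range(len(EVENT_TYPES)) if events[t])
        direct += discount(ecost, years, econ)
        if state == DEATH_STATE:
            continue
        qw = year_utility(state, events, params)
        direct += discount(params.state_cost[state], years, econ)
        prod += discount(
            productivity_loss(params.daily_wage, qw, DAYS_PER_YEAR_ECON),
            years, econ)
        qalys += discount(qw, years, econ)
        life_years += 1.0
    return EconSummary(direct_medical_cost=direct, productivity_loss=prod,
                       qalys=qalys, life_years=life_years)
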