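"""Per-cycle cost and utility accrual, discounting, and currency handling.

Conventions (pinned by tests):

* Costs are payer-perspective 2017 international dollars; the PPP rate
  converts to yuan (Int$1.00 = 3.54 yuan by default).
* Costs and utilities accrue for the full cycle in which the individual is
  alive at cycle start.  A cycle in which death fires contributes zero
  utility and zero life-years but still accrues the drug and state costs
  (and the fatal event's cost when one is configured).
* Discounting is annual at cycle granularity with cycle 0 undiscounted.
* A serious adverse event replaces 1 week of the year at utility 0.5:
  w -> w - (w - 0.5) * (7 / 365.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .errors import ConfigurationError

__all__ = [
    "CostParams",
    "UtilityParams",
    "DiscountSpec",
    "cycle_cost",
    "cycle_utility",
    "discount",
    "ppp_convert",
]

DAYS_PER_YEAR = 365.25


@dataclass
class CostParams:
    annual_drug_cost: dict = field(
        default_factory=lambda: {"intensive": 420.0, "standard": 150.0}
    )
    acute_event_cost: dict = field(
        default_factory=lambda: {"mi": 4200.0, "stroke": 5300.0, "hf": 3500.0, "cvd_death": 0.0}
    )
    chronic_annual_cost: dict = field(
        default_factory=lambda: {
            "acute_mi": 850.0,
            "post_mi": 850.0,
            "acute_stroke": 1500.0,
            "post_stroke": 1500.0,
            "acute_hf": 1000.0,
            "post_hf": 1000.0,
        }
    )
    sae_cost: float = 500.0
    ppp_rate: float = 3.54  # yuan per Int$

    def validate(self) -> None:
        costs = (
            list(self.annual_drug_cost.values())
            + list(self.acute_event_cost.values())
            + list(self.chronic_annual_cost.values())
            + [self.sae_cost]
        )
        if any(c < 0 for c in costs):
            raise ConfigurationError("costs must be non-negative")
        if self.ppp_rate <= 0:
            raise ConfigurationError("ppp_rate must be positive")


@dataclass
class UtilityParams:
    # (age_low, age_high, male, female) bands for hypertensive individuals
    baseline_bands: list = field(
        default_factory=lambda: [
            (0, 54, 0.93, 0.92),
            (55, 64, 0.91, 0.90),
            (65, 74, 0.88, 0.87),
            (75, 200, 0.84, 0.82),
        ]
    )
    event_utility: dict = field(
        default_factory=lambda: {"post_mi": 0.84, "post_stroke": 0.75, "post_hf": 0.78}
    )
    acute_event_decrement: dict = field(
        default_factory=lambda: {"mi": 0.12, "stroke": 0.20, "hf": 0.15}
    )
    sae_utility_value: float = 0.5
    sae_duration_weeks: float = 1.0

    def baseline_utility(self, age: float, sex: str) -> float:
        for lo, hi, m, f in self.baseline_bands:
            if lo <= age <= hi:
                return m if sex == "male" else f
        return self.baseline_bands[-1][2 if sex == "male" else 3]

    def validate(self) -> None:
        for lo, hi, m, f in self.baseline_bands:
            if not (0.0 <= m <= 1.0 and 0.0 <= f <= 1.0):
                raise ConfigurationError("baseline utilities must lie in [0, 1]")
        for v in self.event_utility.values():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("event utilities must lie in [0, 1]")
        if not 0.0 <= self.sae_utility_value <= 1.0:
            raise ConfigurationError("SAE utility must lie in [0, 1]")


@dataclass
class DiscountSpec:
    rate: float = 0.03
    base_year: int = 0

    def validate(self) -> None:
        if self.rate < 0:
            raise ConfigurationError("discount rate must be >= 0")


def cycle_cost(
    state: str,
    events: Iterable[str],
    sae: bool,
    strategy: str,
    cp: CostParams,
) -> float:
    """Total cost accrued during one alive-at-start cycle.

    drug cost (strategy-specific) + acute costs of events fired this cycle
    + chronic annual cost of the occupied state + SAE cost when one occurred.
    """
    total = cp.annual_drug_cost[strategy]
    total += cp.chronic_annual_cost.get(state, 0.0)
    for ev in events:
        total += cp.acute_event_cost.get(ev, 0.0)
    if sae:
        total += cp.sae_cost
    return total


def cycle_utility(
    age: float,
    sex: str,
    state: str,
    events: Iterable[str],
    sae: bool,
    up: UtilityParams,
) -> float:
    """QALY weight for one cycle; death states and death cycles contribute 0."""
    if state in ("cvd_death", "noncvd_death"):
        return 0.0
    events = set(events)
    if "cvd_death" in events or "noncvd_death" in events:
        return 0.0
    base = up.baseline_utility(age, sex)
    if state in up.event_utility:
        base = min(base, up.event_utility[state])
    elif state.startswith("acute_"):
        base = base - up.acute_event_decrement.get(state.removeprefix("acute_"), 0.0)
    if sae:
        frac = up.sae_duration_weeks * 7.0 / DAYS_PER_YEAR
        base = base - (base - up.sae_utility_value) * frac
    return min(max(base, 0.0), 1.0)


def discount(amount: float, cycle_index: int, ds: DiscountSpec) -> float:
    """Present value of ``amount`` accruing at ``cycle_index`` (cycle 0 undiscounted)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    return amount / (1.0 + ds.rate) ** (cycle_index - ds.base_year)


def ppp_convert(int_dollars: float, cp: CostParams) -> float:
    """International dollars to yuan at the configured PPP rate."""
    return int_dollars * cp.ppp_rate
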