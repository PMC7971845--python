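"""Transition-probability machinery: annualization, relative risks, hazards.

Primary MI/stroke/HF incidence comes from pluggable Cox-form multi-year
risk equations annualized to the 1-year cycle; treatment effects are
relative risks applied in the hazard (rate) domain so any RR keeps the
result inside [0, 1); background non-CVD mortality comes from a life table
with a configurable CVD-death fraction carved out of total mortality.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import equations
from .economics import CostParams, DiscountSpec, UtilityParams
from .errors import ConfigurationError, DomainError
from .population import Individual

__all__ = [
    "LifeTable",
    "ChronicProbs",
    "ModelParams",
    "AnnualHazards",
    "annualize_risk",
    "apply_relative_risk",
    "primary_hazards",
    "default_params",
    "make_gompertz_life_table",
]

EVENT_TYPES = ("mi", "stroke", "hf")


def annualize_risk(p_multi: float, years: float) -> float:
    """Convert a ``years``-horizon cumulative risk to a per-year probability.

    Returns 1 - (1 - p_multi)^(1/years); compounding the result over
    ``years`` cycles recovers p_multi exactly.
    """
    if not 0.0 <= p_multi < 1.0:
        raise DomainError("p_multi must lie in [0, 1)")
    if years <= 0:
        raise DomainError("years must be positive")
    return 1.0 - (1.0 - p_multi) ** (1.0 / years)


def apply_relative_risk(p_annual: float, rr: float) -> float:
    """Scale an annual probability by a relative risk in the rate domain.

    Returns 1 - (1 - p_annual)^rr, i.e. hazard multiplication; rr = 1 is the
    identity and the result stays in [0, 1) for any rr > 0.
    """
    if not 0.0 <= p_annual < 1.0:
        raise DomainError("p_annual must lie in [0, 1)")
    if rr <= 0:
        raise DomainError("relative risk must be positive")
    return 1.0 - (1.0 - p_annual) ** rr


class LifeTable:
    """Age x sex annual all-cause death probabilities (qx).

    Ages beyond the last row use the terminal row; a terminal qx of 1.0
    makes the table a proper closed cohort table.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(f"life table needs columns {sorted(required)}")
        if len(frame) == 0:
            raise ConfigurationError("life table is empty")
        if ((frame["qx"] < 0) | (frame["qx"] > 1)).any():
            raise ConfigurationError("life-table qx values must lie in [0, 1]")
        self._qx = {}
        self._max_age = {}
        for sex, grp in frame.groupby("sex"):
            grp = grp.sort_values("age")
            ages = grp["age"].to_numpy(dtype=int)
            qx = grp["qx"].to_numpy(dtype=float)
            self._qx[sex] = dict(zip(ages, qx))
            self._max_age[sex] = int(ages.max())
        self.frame = frame.reset_index(drop=True)

    def qx(self, age: float, sex: str) -> float:
        table = self._qx[sex]
        a = min(int(age), self._max_age[sex])
        a = max(a, min(table))
        return table[a]

    def qx_array(self, ages: np.ndarray, sex: str) -> np.ndarray:
        return np.array([self.qx(a, sex) for a in ages])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def make_gompertz_life_table(
    a_male: float = 4.2e-5,
    b_male: float = 0.095,
    a_female: float = 2.2e-5,
    b_female: float = 0.099,
    max_age: int = 105,
) -> LifeTable:
    """Smooth Gompertz qx table (placeholder for a national life table)."""
    rows = []
    for sex, a, b in (("male", a_male, b_male), ("female", a_female, b_female)):
        for age in range(0, max_age + 1):
            qx = min(a * math.exp(b * age), 1.0)
            if age == max_age:
                qx = 1.0
            rows.append({"age": age, "sex": sex, "qx": qx})
    return LifeTable(pd.DataFrame(rows))


@dataclass
class ChronicProbs:
    """Annual transition probabilities out of one event state."""

    secondary_event: float = 0.0
    cvd_death: float = 0.0
    noncvd_death: Optional[float] = None  # None -> background life table

    def validate(self) -> None:
        for v in (self.secondary_event, self.cvd_death):
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError("chronic probabilities must lie in [0, 1]")
        if self.noncvd_death is not None and not 0.0 <= self.noncvd_death <= 1.0:
            raise ConfigurationError("chronic probabilities must lie in [0, 1]")


@dataclass
class AnnualHazards:
    """Per-cycle event/death probabilities for one individual-cycle."""

    p_mi: float
    p_stroke: float
    p_hf: float
    p_cvd_death: float
    p_noncvd_death: float
    p_sae: float


@dataclass
class ModelParams:
    """Single source of truth for every transition probability, RR, cost and
    utility in the model.  Shipped defaults are plausible placeholders."""

    rr_treatment: dict = field(
        default_factory=lambda: {
            "mi": 0.83,
            "stroke": 0.89,
            "hf": 0.62,
            "cvd_death": 0.57,
            "sae": 1.88,
        }
    )
    chronic_probs: dict = field(
        default_factory=lambda: {
            "acute_mi": ChronicProbs(0.10, 0.08),
            "post_mi": ChronicProbs(0.03, 0.02),
            "acute_stroke": ChronicProbs(0.08, 0.10),
            "post_stroke": ChronicProbs(0.03, 0.03),
            "acute_hf": ChronicProbs(0.06, 0.12),
            "post_hf": ChronicProbs(0.03, 0.05),
        }
    )
    secondary_event_mix: dict = field(
        default_factory=lambda: {"mi": 1 / 3, "stroke": 1 / 3, "hf": 1 / 3}
    )
    sae_prob_standard: float = 0.02
    cvd_death_fraction: float = 0.40  # share of life-table mortality that is CVD
    life_table: LifeTable = field(default_factory=make_gompertz_life_table)
    risk_equations: dict = field(
        default_factory=lambda: {ev: equations.placeholder_event_equation(ev) for ev in EVENT_TYPES}
    )
    horizon_age_cap: int = 100
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    psa_distributions: dict = field(default_factory=dict)
    dsa_ranges: dict = field(default_factory=dict)

    def validate(self) -> None:
        for k, rr in self.rr_treatment.items():
            if rr <= 0:
                raise ConfigurationError(f"rr_treatment[{k}] must be positive")
        for state, cp in self.chronic_probs.items():
            cp.validate()
        if not 0.0 <= self.sae_prob_standard <= 1.0:
            raise ConfigurationError("sae_prob_standard must lie in [0, 1]")
        if not 0.0 <= self.cvd_death_fraction <= 1.0:
            raise ConfigurationError("cvd_death_fraction must lie in [0, 1]")
        mix_total = sum(self.secondary_event_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigurationError("secondary_event_mix must sum to 1")
        self.discount.validate()
        self.costs.validate()
        self.utilities.validate()
        for path, (lo, hi) in self.dsa_ranges.items():
            base = self.get_value(path)
            if not lo <= base <= hi:
                raise ConfigurationError(
                    f"DSA range [{lo}, {hi}] for {path!r} excludes base value {base}"
                )

    # -- dotted-path access (used by DSA and PSA) --------------------------

    def get_value(self, path: str):
        obj = self
        for part in path.split("."):
            if isinstance(obj, dict):
                obj = obj[part]
            else:
                obj = getattr(obj, part)
        return obj

    def with_value(self, path: str, value) -> "ModelParams":
        new = self.copy()
        parts = path.split(".")
        obj = new
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
        if isinstance(obj, dict):
            obj[parts[-1]] = value
        else:
            setattr(obj, parts[-1], value)
        return new

    def with_values(self, mapping: dict) -> "ModelParams":
        new = self.copy()
        for path, value in mapping.items():
            new = new.with_value(path, value)
        return new

    def copy(self) -> "ModelParams":
        memo = {id(self.life_table): self.life_table}  # life table is immutable in use
        return copy.deepcopy(self, memo)

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rr_treatment": dict(self.rr_treatment),
            "chronic_probs": {
                s: {
                    "secondary_event": c.secondary_event,
                    "cvd_death": c.cvd_death,
                    "noncvd_death": c.noncvd_death,
                }
                for s, c in self.chronic_probs.items()
            },
            "secondary_event_mix": dict(self.secondary_event_mix),
            "sae_prob_standard": self.sae_prob_standard,
            "cvd_death_fraction": self.cvd_death_fraction,
            "horizon_age_cap": self.horizon_age_cap,
            "discount": {"rate": self.discount.rate},
            "costs": {
                "annual_drug_cost": dict(self.costs.annual_drug_cost),
                "acute_event_cost": dict(self.costs.acute_event_cost),
                "chronic_annual_cost": dict(self.costs.chronic_annual_cost),
                "sae_cost": self.costs.sae_cost,
                "ppp_rate": self.costs.ppp_rate,
            },
            "utilities": {
                "baseline_bands": [list(b) for b in self.utilities.baseline_bands],
                "event_utility": dict(self.utilities.event_utility),
                "acute_event_decrement": dict(self.utilities.acute_event_decrement),
                "sae_utility_value": self.utilities.sae_utility_value,
                "sae_duration_weeks": self.utilities.sae_duration_weeks,
            },
            "psa_distributions": copy.deepcopy(self.psa_distributions),
            "dsa_ranges": {k: list(v) for k, v in self.dsa_ranges.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, life_table: Optional[LifeTable] = None) -> "ModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = default_params()
        if life_table is not None:
            params.life_table = life_table
        params.rr_treatment.update(raw.get("rr_treatment", {}))
        for state, block in raw.get("chronic_probs", {}).items():
            params.chronic_probs[state] = ChronicProbs(
                secondary_event=block.get("secondary_event", 0.0),
                cvd_death=block.get("cvd_death", 0.0),
                noncvd_death=block.get("noncvd_death"),
            )
        if "secondary_event_mix" in raw:
            params.secondary_event_mix = dict(raw["secondary_event_mix"])
        for scalar in ("sae_prob_standard", "cvd_death_fraction", "horizon_age_cap"):
            if scalar in raw:
                setattr(params, scalar, raw[scalar])
        if "discount" in raw:
            params.discount = DiscountSpec(rate=raw["discount"].get("rate", 0.03))
        cb = raw.get("costs", {})
        params.costs.annual_drug_cost.update(cb.get("annual_drug_cost", {}))
        params.costs.acute_event_cost.update(cb.get("acute_event_cost", {}))
        params.costs.chronic_annual_cost.update(cb.get("chronic_annual_cost", {}))
        params.costs.sae_cost = cb.get("sae_cost", params.costs.sae_cost)
        params.costs.ppp_rate = cb.get("ppp_rate", params.costs.ppp_rate)
        ub = raw.get("utilities", {})
        if "baseline_bands" in ub:
            params.utilities.baseline_bands = [tuple(b) for b in ub["baseline_bands"]]
        params.utilities.event_utility.update(ub.get("event_utility", {}))
        params.utilities.acute_event_decrement.update(ub.get("acute_event_decrement", {}))
        params.utilities.sae_utility_value = ub.get(
            "sae_utility_value", params.utilities.sae_utility_value
        )
        params.utilities.sae_duration_weeks = ub.get(
            "sae_duration_weeks", params.utilities.sae_duration_weeks
        )
        params.psa_distributions = raw.get("psa_distributions", params.psa_distributions)
        params.dsa_ranges = {k: tuple(v) for k, v in raw.get("dsa_ranges", {}).items()}
        params.validate()
        return params


def default_params() -> ModelParams:
    """Placeholder base-case parameter set with DSA ranges and PSA distributions."""
    p = ModelParams()
    p.dsa_ranges = {
        "costs.annual_drug_cost.intensive": (210.0, 840.0),
        "rr_treatment.cvd_death": (0.38, 0.85),
        "rr_treatment.stroke": (0.63, 1.25),
        "rr_treatment.hf": (0.45, 0.84),
        "rr_treatment.sae": (1.20, 2.60),
        "costs.sae_cost": (250.0, 1000.0),
        "costs.chronic_annual_cost.post_stroke": (750.0, 3000.0),
        "utilities.sae_utility_value": (0.30, 0.70),
    }
    p.psa_distributions = {
        "rr_treatment.mi": {"family": "lognormal", "mu": math.log(0.83), "sigma": 0.12},
        "rr_treatment.stroke": {"family": "lognormal", "mu": math.log(0.89), "sigma": 0.12},
        "rr_treatment.hf": {"family": "lognormal", "mu": math.log(0.62), "sigma": 0.12},
        "rr_treatment.cvd_death": {"family": "lognormal", "mu": math.log(0.57), "sigma": 0.12},
        "rr_treatment.sae": {"family": "lognormal", "mu": math.log(1.88), "sigma": 0.10},
        "costs.annual_drug_cost.intensive": {"family": "gamma", "shape": 25.0, "scale": 420.0 / 25.0},
        "costs.sae_cost": {"family": "gamma", "shape": 25.0, "scale": 500.0 / 25.0},
        "sae_prob_standard": {"family": "beta", "a": 4.0, "b": 196.0},
        "utilities.sae_utility_value": {"family": "beta", "a": 5.0, "b": 5.0},
    }
    return p


def primary_hazards(
    ind: Individual,
    strategy: str,
    params: ModelParams,
    age: Optional[float] = None,
) -> AnnualHazards:
    """Well-state per-cycle hazards for one individual at ``age``.

    Covariates are frozen at baseline except age.  Under the intensive
    strategy each event/death/SAE probability is rate-domain scaled by the
    corresponding treatment relative risk.
    """
    if strategy not in ("intensive", "standard"):
        raise ValueError(f"unknown strategy {strategy!r}")
    age = float(ind.age) if age is None else float(age)
    intensive = strategy == "intensive"

    out = {}
    for ev in EVENT_TYPES:
        eq = params.risk_equations[ev]
        risk = eq.risk(
            sex=ind.sex,
            age=age,
            sbp=ind.sbp,
            on_bp_treatment=ind.on_bp_treatment,
            total_chol=ind.total_chol,
            hdl_chol=ind.hdl_chol,
            smoker=ind.smoker,
            diabetes=ind.diabetes,
        )
        p = annualize_risk(risk, eq.horizon_years)
        # rr == 1 must be a bit-exact no-op so common random numbers cancel
        if intensive and params.rr_treatment[ev] != 1.0:
            p = apply_relative_risk(p, params.rr_treatment[ev])
        out[ev] = p

    qx = params.life_table.qx(age, ind.sex)
    p_cvd = min(qx * params.cvd_death_fraction, 1.0 - 1e-12)
    if intensive and params.rr_treatment["cvd_death"] != 1.0:
        p_cvd = apply_relative_risk(p_cvd, params.rr_treatment["cvd_death"])
    p_noncvd = qx * (1.0 - params.cvd_death_fraction)

    p_sae = params.sae_prob_standard
    if intensive and params.rr_treatment["sae"] != 1.0 and p_sae < 1.0:
        p_sae = apply_relative_risk(p_sae, params.rr_treatment["sae"])

    return AnnualHazards(
        p_mi=out["mi"],
        p_stroke=out["stroke"],
        p_hf=out["hf"],
        p_cvd_death=p_cvd,
        p_noncvd_death=p_noncvd,
        p_sae=p_sae,
    )
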