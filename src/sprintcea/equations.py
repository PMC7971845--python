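"""Sex-specific Cox-form risk equations.

The continuous ("general clinical practice") 10-year cardiovascular risk
equation has the form

    risk = 1 - S0 ** exp(sum(beta_j * x_j) - m)

where the covariates are log-transformed age, systolic blood pressure
(separate coefficients for treated and untreated), total and HDL
cholesterol, plus smoking and diabetes indicators, S0 is the baseline
10-year survival and m the risk-factor sum evaluated at the derivation
cohort's means.  The published general-CVD coefficient tables are shipped
here verbatim; the event-specific MI/stroke/HF tables used by the
microsimulation reuse the same covariate structure with placeholder
baseline survivals (clearly labelled — swap in calibrated tables via the
parameter file for real analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "CoxRiskEquation",
    "GENERAL_CVD_EQUATION",
    "placeholder_event_equation",
    "PLACEHOLDER_EVENT_S0",
]


@dataclass(frozen=True)
class SexCoefficients:
    """One sex's coefficient row of a Cox-form risk equation."""

    ln_age: float
    ln_total_chol: float
    ln_hdl_chol: float
    ln_sbp_untreated: float
    ln_sbp_treated: float
    smoker: float
    diabetes: float
    mean_terms: float  # sum(beta * x) at cohort means
    s0: float  # baseline survival at the equation horizon


@dataclass(frozen=True)
class CoxRiskEquation:
    """A sex-stratified Cox-form multi-year risk equation.

    ``horizon_years`` is the horizon of the returned cumulative risk.
    ``age_range`` is the derivation validity range; ages outside it are
    clamped before entering the linear predictor.
    """

    male: SexCoefficients
    female: SexCoefficients
    horizon_years: float = 10.0
    age_range: tuple[float, float] = (30.0, 74.0)
    include_diabetes: bool = True

    def linear_predictor(
        self,
        *,
        sex: str,
        age: float,
        sbp: float,
        on_bp_treatment: bool,
        total_chol: float,
        hdl_chol: float,
        smoker: bool,
        diabetes: bool,
    ) -> float:
        if total_chol <= 0 or hdl_chol <= 0:
            raise DomainError("cholesterol values must be positive")
        if sbp <= 0:
            raise DomainError("SBP must be positive")
        c = self.male if sex == "male" else self.female
        age = min(max(age, self.age_range[0]), self.age_range[1])
        sbp_coef = c.ln_sbp_treated if on_bp_treatment else c.ln_sbp_untreated
        lp = (
            c.ln_age * math.log(age)
            + c.ln_total_chol * math.log(total_chol)
            + c.ln_hdl_chol * math.log(hdl_chol)
            + sbp_coef * math.log(sbp)
            + c.smoker * float(smoker)
        )
        if self.include_diabetes:
            lp += c.diabetes * float(diabetes)
        return lp

    def risk(self, **covariates) -> float:
        """Cumulative risk over ``horizon_years``, strictly inside (0, 1)."""
        c = self.male if covariates["sex"] == "male" else self.female
        lp = self.linear_predictor(**covariates)
        r = 1.0 - c.s0 ** math.exp(lp - c.mean_terms)
        # survival powers keep r in (0,1) for finite input; clamp guards overflow
        return min(max(r, 1e-15), 1.0 - 1e-15)


# Published general-CVD coefficient tables (sex-specific Cox model on
# log-transformed risk factors; 10-year horizon).
GENERAL_CVD_EQUATION = CoxRiskEquation(
    male=SexCoefficients(
        ln_age=3.06117,
        ln_total_chol=1.12370,
        ln_hdl_chol=-0.93263,
        ln_sbp_untreated=1.93303,
        ln_sbp_treated=1.99881,
        smoker=0.65451,
        diabetes=0.57367,
        mean_terms=23.9802,
        s0=0.88936,
    ),
    female=SexCoefficients(
        ln_age=2.32888,
        ln_total_chol=1.20904,
        ln_hdl_chol=-0.70833,
        ln_sbp_untreated=2.76157,
        ln_sbp_treated=2.82263,
        smoker=0.52873,
        diabetes=0.69154,
        mean_terms=26.1931,
        s0=0.95012,
    ),
)

# PLACEHOLDER event-specific baseline survivals: same covariate structure as
# the general-CVD table but with event-specific 10-year baseline survival.
# These stand in for the calibrated MI/stroke/HF equations, whose exact
# coefficients are not redistributable; replace via ModelParams for real use.
PLACEHOLDER_EVENT_S0 = {
    "mi": {"male": 0.975, "female": 0.988},
    "stroke": {"male": 0.972, "female": 0.982},
    "hf": {"male": 0.978, "female": 0.986},
}


def placeholder_event_equation(event: str) -> CoxRiskEquation:
    """Cox-form 10-year equation for one primary event type (placeholder S0)."""
    s0 = PLACEHOLDER_EVENT_S0[event]
    g = GENERAL_CVD_EQUATION
    return CoxRiskEquation(
        male=SexCoefficients(
            **{
                **{f: getattr(g.male, f) for f in g.male.__dataclass_fields__},
                "s0": s0["male"],
            }
        ),
        female=SexCoefficients(
            **{
                **{f: getattr(g.female, f) for f in g.female.__dataclass_fields__},
                "s0": s0["female"],
            }
        ),
    )
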