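"""Multistep SPRINT-eligibility screening and the sequential-criterion funnel.

Steps, applied in order:

1. age >= 50 years;
2. SBP 130-180 mm Hg — by default regardless of the number of
   antihypertensive medication classes (the relaxed criterion used when
   class counts are unavailable); the original medication-stratified
   windows (130-180 on <=1 class, 130-170 on <=2, 130-160 on <=3,
   130-150 on <=4) are available behind ``strict_medication_rule``;
3. at least one high-CVD-risk condition: CHD history, eGFR 20-59
   mL/min/1.73 m^2, 10-year general-CVD risk >= 15%, or age >= 75;
4. no exclusion: diabetes, stroke history, heart failure, ESRD.

All bounds are inclusive. All four risk conditions are evaluated even once
one is met so the result reports the full condition set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .equations import GENERAL_CVD_EQUATION
from .errors import DomainError, EstimateError, MissingFieldError
from .population import Individual, weighted_proportion

__all__ = [
    "EligibilityResult",
    "FunnelRow",
    "FunnelTable",
    "framingham_cvd_risk",
    "estimate_egfr",
    "sprint_eligible",
    "build_funnel",
    "is_hypertensive",
]

RISK_CONDITIONS = ("chd_history", "egfr_20_59", "framingham_ge_15", "age_ge_75")
EXCLUSIONS = ("diabetes", "stroke_history", "heart_failure", "esrd")


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    failed_step: Optional[int]  # ordinal of first failed criterion, or None
    risk_conditions_met: frozenset
    exclusions_hit: frozenset
    framingham_risk: Optional[float]


def framingham_cvd_risk(ind: Individual) -> float:
    """10-year general-CVD risk from the sex-specific continuous Cox equation.

    Age is clamped into the equation's derivation range [30, 74] before the
    linear predictor is formed; the separate age >= 75 eligibility criterion
    makes the clamp immaterial for screening decisions.
    """
    for f in ("total_chol", "hdl_chol"):
        v = getattr(ind, f)
        if v is None:
            raise MissingFieldError(f, "framingham_cvd_risk")
        if v <= 0:
            raise DomainError(f"{f} must be positive")
    return GENERAL_CVD_EQUATION.risk(
        sex=ind.sex,
        age=float(ind.age),
        sbp=ind.sbp,
        on_bp_treatment=ind.on_bp_treatment,
        total_chol=ind.total_chol,
        hdl_chol=ind.hdl_chol,
        smoker=ind.smoker,
        diabetes=ind.diabetes,
    )


def estimate_egfr(creatinine: float, age: float, sex: str) -> float:
    """CKD-EPI 2009 creatinine equation (no race term), mL/min/1.73 m^2."""
    if creatinine is None or creatinine <= 0:
        raise DomainError("serum creatinine must be positive")
    kappa = 0.7 if sex == "female" else 0.9
    alpha = -0.329 if sex == "female" else -0.411
    ratio = creatinine / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
    if sex == "female":
        egfr *= 1.018
    return egfr


def _resolved_egfr(ind: Individual) -> Optional[float]:
    """Individual.egfr wins; otherwise derive from creatinine when available."""
    if ind.egfr is not None:
        return ind.egfr
    if ind.creatinine is not None:
        return estimate_egfr(ind.creatinine, ind.age, ind.sex)
    return None


def _sbp_window_ok(ind: Individual, strict: bool) -> bool:
    if not strict:
        return 130.0 <= ind.sbp <= 180.0
    n = ind.n_bp_med_classes
    if n is None:
        raise MissingFieldError("n_bp_med_classes", "sbp_window (strict rule)")
    if n <= 1:
        hi = 180.0
    elif n == 2:
        hi = 170.0
    elif n == 3:
        hi = 160.0
    elif n == 4:
        hi = 150.0
    else:
        return False
    return 130.0 <= ind.sbp <= hi


def sprint_eligible(ind: Individual, strict_medication_rule: bool = False) -> EligibilityResult:
    """Apply the four sequential criteria; record the first failed step."""
    failed: Optional[int] = None

    if ind.age < 50:
        failed = 1
    if failed is None and not _sbp_window_ok(ind, strict_medication_rule):
        failed = 2

    conditions = set()
    risk: Optional[float] = None
    if ind.hist_chd:
        conditions.add("chd_history")
    egfr = _resolved_egfr(ind)
    if egfr is not None and 20.0 <= egfr <= 59.0:
        conditions.add("egfr_20_59")
    risk = framingham_cvd_risk(ind)
    if risk >= 0.15:
        conditions.add("framingham_ge_15")
    if ind.age >= 75:
        conditions.add("age_ge_75")
    if failed is None and not conditions:
        failed = 3

    exclusions = set()
    if ind.diabetes:
        exclusions.add("diabetes")
    if ind.hist_stroke:
        exclusions.add("stroke_history")
    if ind.hist_hf:
        exclusions.add("heart_failure")
    if ind.esrd:
        exclusions.add("esrd")
    if failed is None and exclusions:
        failed = 4

    return EligibilityResult(
        eligible=failed is None,
        failed_step=failed,
        risk_conditions_met=frozenset(conditions),
        exclusions_hit=frozenset(exclusions),
        framingham_risk=risk,
    )


def is_hypertensive(ind: Individual) -> bool:
    """SBP >= 140 or DBP >= 90 or on antihypertensive treatment."""
    return ind.sbp >= 140.0 or ind.dbp >= 90.0 or ind.on_bp_treatment


@dataclass(frozen=True)
class FunnelRow:
    label: str
    proportion: float
    ci_low: float
    ci_high: float
    millions: float


@dataclass
class FunnelTable:
    rows: list = field(default_factory=list)
    subgroup_rows: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [r.__dict__ for r in self.rows + self.subgroup_rows]
        )


_SEQUENTIAL: list[tuple[str, Callable[[Individual], bool]]] = [
    ("all respondents (age >= 45)", lambda ind: True),
    ("age >= 50", lambda ind: ind.age >= 50),
    ("SBP 130-180 mm Hg", lambda ind: 130.0 <= ind.sbp <= 180.0),
    (">= 1 high-CVD-risk condition", lambda ind: len(sprint_eligible(ind).risk_conditions_met) > 0),
    ("no exclusion (eligible)", lambda ind: sprint_eligible(ind).eligible),
]


def build_funnel(pop: Sequence[Individual], population_scale: float) -> FunnelTable:
    """Weighted funnel of the sequential criteria plus hypertension subgroups.

    ``population_scale`` is the total represented population in millions;
    with mean-1 weights each row's millions = weighted proportion * scale.
    """
    pop = list(pop)
    if not pop:
        raise EstimateError("cannot build a funnel on an empty population")

    table = FunnelTable()
    predicates: list[Callable[[Individual], bool]] = []
    for label, pred in _SEQUENTIAL:
        predicates.append(pred)
        conj = list(predicates)
        est = weighted_proportion(pop, lambda ind, c=conj: all(p(ind) for p in c))
        table.rows.append(
            FunnelRow(
                label=label,
                proportion=est.proportion,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                millions=est.proportion * population_scale,
            )
        )

    eligible_flags = {id(ind): sprint_eligible(ind).eligible for ind in pop}
    subgroups = [
        ("hypertensive", is_hypertensive),
        ("non-hypertensive (SBP 130-139)", lambda i: not is_hypertensive(i) and 130.0 <= i.sbp <= 139.0),
        ("treated hypertensive", lambda i: is_hypertensive(i) and i.on_bp_treatment),
        ("untreated", lambda i: not i.on_bp_treatment),
    ]
    for label, in_group in subgroups:
        members = [ind for ind in pop if in_group(ind)]
        if not members:
            continue
        within = weighted_proportion(members, lambda i: eligible_flags[id(i)])
        share = weighted_proportion(pop, lambda i, g=in_group: g(i) and eligible_flags[id(i)])
        table.subgroup_rows.append(
            FunnelRow(
                label=f"eligible among {label}",
                proportion=within.proportion,
                ci_low=within.ci_low,
                ci_high=within.ci_high,
                millions=share.proportion * population_scale,
            )
        )
    return table
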