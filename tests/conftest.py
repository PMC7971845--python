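import pandas as pd
import pytest

from sprintcea.economics import CostParams, DiscountSpec, UtilityParams
from sprintcea.equations import CoxRiskEquation, SexCoefficients
from sprintcea.population import Individual, PopulationSpec, generate_population
from sprintcea.risk_models import ChronicProbs, LifeTable, ModelParams, default_params


def make_individual(**overrides) -> Individual:
    base = dict(
        id="X0",
        age=62,
        sex="male",
        sbp=145.0,
        dbp=85.0,
        on_bp_treatment=False,
        smoker=False,
        total_chol=200.0,
        hdl_chol=48.0,
        hist_chd=False,
        hist_stroke=False,
        hist_hf=False,
        diabetes=False,
        esrd=False,
        survey_weight=1.0,
        creatinine=0.9,
    )
    base.update(overrides)
    return Individual(**base)


def constant_risk_equation(p10: float) -> CoxRiskEquation:
    """Degenerate Cox equation: identical constant 10-year risk for everyone."""
    c = SexCoefficients(
        ln_age=0.0,
        ln_total_chol=0.0,
        ln_hdl_chol=0.0,
        ln_sbp_untreated=0.0,
        ln_sbp_treated=0.0,
        smoker=0.0,
        diabetes=0.0,
        mean_terms=0.0,
        s0=1.0 - p10,
    )
    return CoxRiskEquation(male=c, female=c)


def flat_life_table(q: float, max_age: int = 110) -> LifeTable:
    rows = [
        {"age": a, "sex": s, "qx": q}
        for s in ("male", "female")
        for a in range(0, max_age + 1)
    ]
    return LifeTable(pd.DataFrame(rows))


def toy_params(
    *,
    p10_mi: float = 0.0,
    p10_stroke: float = 0.0,
    p10_hf: float = 0.0,
    qx: float = 0.0,
    cvd_death_fraction: float = 0.0,
    sae_prob: float = 0.0,
    horizon_age_cap: int = 100,
    discount_rate: float = 0.0,
    flat_utility: float = 1.0,
) -> ModelParams:
    """Time-homogeneous toy parameterization for analytic oracles."""
    p = ModelParams()
    p.risk_equations = {
        "mi": constant_risk_equation(p10_mi),
        "stroke": constant_risk_equation(p10_stroke),
        "hf": constant_risk_equation(p10_hf),
    }
    p.life_table = flat_life_table(qx)
    p.cvd_death_fraction = cvd_death_fraction
    p.sae_prob_standard = sae_prob
    p.rr_treatment = {k: 1.0 for k in p.rr_treatment}
    p.chronic_probs = {
        s: ChronicProbs(0.0, 0.0) for s in p.chronic_probs
    }
    p.horizon_age_cap = horizon_age_cap
    p.discount = DiscountSpec(rate=discount_rate)
    p.costs = CostParams(
        annual_drug_cost={"intensive": 0.0, "standard": 0.0},
        acute_event_cost={"mi": 0.0, "stroke": 0.0, "hf": 0.0, "cvd_death": 0.0},
        chronic_annual_cost={k: 0.0 for k in p.costs.chronic_annual_cost},
        sae_cost=0.0,
    )
    p.utilities = UtilityParams(
        baseline_bands=[(0, 200, flat_utility, flat_utility)],
        event_utility={"post_mi": flat_utility, "post_stroke": flat_utility, "post_hf": flat_utility},
        acute_event_decrement={"mi": 0.0, "stroke": 0.0, "hf": 0.0},
    )
    return p


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    p = default_params()
    p.validate()
    return p


@pytest.fixture(scope="session")
def small_population():
    return generate_population(PopulationSpec(n=2000, seed=11))


@pytest.fixture(scope="session")
def eligible_cohort(small_population):
    from sprintcea.eligibility import sprint_eligible

    return [ind for ind in small_population if sprint_eligible(ind).eligible]
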