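"""Individual-level annual-cycle microsimulation over the 9-state model.

States: well (on treatment), three acute event states (MI, stroke, HF),
their three chronic post-event states, and two absorbing death states
(CVD, non-CVD).  An event fired during a cycle moves the individual into
the acute state for the following cycle (the first, highest-risk year
after the event, during which further events may occur); absent further
events the acute state hands over to the matching post state, so acute
states never persist two consecutive cycles.

Each cycle consumes exactly two uniform draws (one categorical
event/death draw, one SAE draw) from a per-individual stream keyed by
(master seed, individual index), so both strategies replay identical
streams — common random numbers.  With all treatment relative risks at 1
and equal arm costs every per-individual delta is exactly zero.

Competing events are resolved by a single categorical draw over
{MI, stroke, HF, CVD death, non-CVD death, none}; if the probabilities
sum beyond 1 they are renormalized and a warning is emitted.  SAEs are
drawn independently and do not alter event risks.  Treatment relative
risks apply to primary events, to CVD death in every state, and to the
SAE probability; secondary-event probabilities are taken from the
chronic-state table unmodified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .economics import cycle_cost, cycle_utility
from .errors import EstimateError, InternalConsistencyError
from .population import Individual
from .risk_models import EVENT_TYPES, LifeTable, ModelParams, apply_relative_risk

__all__ = [
    "HEALTH_STATES",
    "Trajectory",
    "StrategyResult",
    "Comparison",
    "bootstrap_individuals",
    "simulate_individual",
    "run_strategy",
    "compare_strategies",
    "validate_against_life_table",
    "life_table_expectancy",
]

HEALTH_STATES = (
    "well",
    "acute_mi",
    "post_mi",
    "acute_stroke",
    "post_stroke",
    "acute_hf",
    "post_hf",
    "cvd_death",
    "noncvd_death",
)
_DEATHS = ("cvd_death", "noncvd_death")
_FIVE_YEAR_EVENTS = ("mi", "stroke", "hf", "cvd_death")


@dataclass
class Trajectory:
    """One simulated life course (per-cycle records optional for speed)."""

    baseline_age: int
    sex: str
    strategy: str
    n_cycles: int
    discounted_cost: float
    discounted_qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    life_years: float
    events_by_type: dict
    first_event_cycle: dict  # event type -> cycle index of first occurrence
    death_cause: Optional[str]  # None = alive at the horizon cap
    death_cycle: Optional[int]
    n_sae: int
    cycles: Optional[list] = None  # (age, state, event, sae, cost, utility)


@dataclass
class StrategyResult:
    """Cohort aggregates for one treatment arm."""

    strategy: str
    n_individuals: int
    mean_cost: float
    mean_qaly: float
    mean_life_years: float
    mean_undiscounted_cost: float
    mean_undiscounted_qaly: float
    five_year_cuminc: dict
    lifetime_event_counts: dict
    survival_curve: np.ndarray
    cum_cvd_death_curve: np.ndarray
    cum_noncvd_death_curve: np.ndarray
    per_individual_cost: np.ndarray
    per_individual_qaly: np.ndarray
    per_individual_ly: np.ndarray
    baseline_ages: np.ndarray
    baseline_sexes: list

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_individuals": self.n_individuals,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "mean_life_years": self.mean_life_years,
            "mean_undiscounted_cost": self.mean_undiscounted_cost,
            "mean_undiscounted_qaly": self.mean_undiscounted_qaly,
            "five_year_cuminc": dict(self.five_year_cuminc),
            "lifetime_event_counts": dict(self.lifetime_event_counts),
            "survival_curve": self.survival_curve.tolist(),
        }


def bootstrap_individuals(
    pop: Sequence[Individual], n: int, seed
) -> list[Individual]:
    """Draw ``n`` individuals with replacement, probability ~ survey weight."""
    pop = list(pop)
    if not pop:
        raise EstimateError("cannot bootstrap from an empty population")
    rng = np.random.default_rng(seed)
    w = np.array([ind.survey_weight for ind in pop], dtype=float)
    idx = rng.choice(len(pop), size=n, replace=True, p=w / w.sum())
    return [pop[i] for i in idx]


class _HazardCache:
    """Per-(params, strategy) cache of age-indexed hazard arrays."""

    def __init__(self, params: ModelParams, strategy: str):
        self.params = params
        self.strategy = strategy
        self.intensive = strategy == "intensive"
        self._by_ind: dict = {}
        # rr == 1 guards keep the arms bit-identical under common random numbers
        p_sae = params.sae_prob_standard
        if self.intensive and params.rr_treatment["sae"] != 1.0 and p_sae < 1.0:
            p_sae = apply_relative_risk(p_sae, params.rr_treatment["sae"])
        self.p_sae = p_sae
        # chronic-state rows: (p_sec_mi, p_sec_stroke, p_sec_hf, p_cvd, p_noncvd or None)
        mix = params.secondary_event_mix
        self.chronic = {}
        for state, cp in params.chronic_probs.items():
            p_cvd = cp.cvd_death
            if self.intensive and params.rr_treatment["cvd_death"] != 1.0 and p_cvd < 1.0:
                p_cvd = apply_relative_risk(p_cvd, params.rr_treatment["cvd_death"])
            self.chronic[state] = (
                cp.secondary_event * mix.get("mi", 0.0),
                cp.secondary_event * mix.get("stroke", 0.0),
                cp.secondary_event * mix.get("hf", 0.0),
                p_cvd,
                cp.noncvd_death,
            )

    def arrays(self, ind: Individual):
        key = (ind.id, ind.age)
        hit = self._by_ind.get(key)
        if hit is not None:
            return hit
        params = self.params
        # one cycle per year of age from baseline up to (not including) the cap,
        # so an event-free individual accrues exactly cap - age life-years
        ages = np.arange(ind.age, params.horizon_age_cap, dtype=float)
        out = {}
        for ev in EVENT_TYPES:
            eq = params.risk_equations[ev]
            c = eq.male if ind.sex == "male" else eq.female
            a = np.clip(ages, eq.age_range[0], eq.age_range[1])
            sbp_coef = c.ln_sbp_treated if ind.on_bp_treatment else c.ln_sbp_untreated
            lp = (
                c.ln_age * np.log(a)
                + c.ln_total_chol * math.log(ind.total_chol)
                + c.ln_hdl_chol * math.log(ind.hdl_chol)
                + sbp_coef * math.log(ind.sbp)
                + c.smoker * float(ind.smoker)
            )
            if eq.include_diabetes:
                lp = lp + c.diabetes * float(ind.diabetes)
            risk = 1.0 - c.s0 ** np.exp(lp - c.mean_terms)
            risk = np.clip(risk, 1e-15, 1.0 - 1e-15)
            p = 1.0 - (1.0 - risk) ** (1.0 / eq.horizon_years)
            if self.intensive and params.rr_treatment[ev] != 1.0:
                p = 1.0 - (1.0 - p) ** params.rr_treatment[ev]
            out[ev] = p
        qx = params.life_table.qx_array(ages, ind.sex)
        p_cvd = np.minimum(qx * params.cvd_death_fraction, 1.0 - 1e-12)
        if self.intensive and params.rr_treatment["cvd_death"] != 1.0:
            p_cvd = 1.0 - (1.0 - p_cvd) ** params.rr_treatment["cvd_death"]
        p_noncvd = qx * (1.0 - params.cvd_death_fraction)
        result = (out["mi"], out["stroke"], out["hf"], p_cvd, p_noncvd, len(ages))
        self._by_ind[key] = result
        return result


def _stream(seed, index: int) -> np.random.Generator:
    """Per-individual stream: deterministic, independent, arm-replayable."""
    if isinstance(seed, (tuple, list)):
        entropy = [int(s) for s in seed] + [int(index)]
    else:
        entropy = [int(seed), int(index)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_individual(
    ind: Individual,
    strategy: str,
    params: ModelParams,
    rng: np.random.Generator,
    cache: Optional[_HazardCache] = None,
    record: bool = False,
) -> Trajectory:
    """Run one individual through the model until death or the age cap."""
    if cache is None:
        cache = _HazardCache(params, strategy)
    elif cache.strategy != strategy:
        raise InternalConsistencyError("hazard cache built for the other strategy")
    p_mi_a, p_stroke_a, p_hf_a, p_cvd_a, p_noncvd_a, n_cycles = cache.arrays(ind)
    uniforms = rng.random((n_cycles, 2))
    chronic = cache.chronic
    p_sae = cache.p_sae
    disc = params.discount
    df = 1.0 / (1.0 + disc.rate)

    state = "well"
    d_cost = d_qaly = u_cost = u_qaly = 0.0
    life_years = 0.0
    events_by_type = {ev: 0 for ev in EVENT_TYPES}
    first_event_cycle: dict = {}
    death_cause = None
    death_cycle = None
    n_sae = 0
    records = [] if record else None
    factor = 1.0  # running discount factor (cycle 0 undiscounted)

    for t in range(n_cycles):
        u_event, u_sae = uniforms[t]
        if state == "well":
            p1, p2, p3 = p_mi_a[t], p_stroke_a[t], p_hf_a[t]
            p4, p5 = p_cvd_a[t], p_noncvd_a[t]
        else:
            p1, p2, p3, p4, p5 = chronic[state]
            if p5 is None:
                p5 = p_noncvd_a[t]
        total = p1 + p2 + p3 + p4 + p5
        if total > 1.0:
            warnings.warn(
                "competing-event probabilities exceed 1; renormalizing", RuntimeWarning
            )
            p1, p2, p3, p4, p5 = (p / total for p in (p1, p2, p3, p4, p5))

        c = p1
        if u_event < c:
            outcome = "mi"
        elif u_event < (c := c + p2):
            outcome = "stroke"
        elif u_event < (c := c + p3):
            outcome = "hf"
        elif u_event < (c := c + p4):
            outcome = "cvd_death"
        elif u_event < c + p5:
            outcome = "noncvd_death"
        else:
            outcome = None

        died = outcome in _DEATHS
        sae = (u_sae < p_sae) and not died
        events = set()
        if outcome is not None:
            events.add(outcome)
        age = ind.age + t

        cost = cycle_cost(state, events, sae, strategy, params.costs)
        utility = cycle_utility(age, ind.sex, state, events, sae, params.utilities)
        d_cost += cost * factor
        d_qaly += utility * factor
        u_cost += cost
        u_qaly += utility
        if sae:
            n_sae += 1
        if not died:
            life_years += 1.0
        if outcome in EVENT_TYPES:
            events_by_type[outcome] += 1
        if outcome is not None and outcome not in first_event_cycle:
            first_event_cycle[outcome] = t
        if records is not None:
            records.append((age, state, outcome, sae, cost, utility))

        if died:
            death_cause = outcome
            death_cycle = t
            state = outcome
            break
        if outcome in EVENT_TYPES:
            state = f"acute_{outcome}"
        elif state.startswith("acute_"):
            state = "post_" + state.removeprefix("acute_")
        factor *= df

    return Trajectory(
        baseline_age=ind.age,
        sex=ind.sex,
        strategy=strategy,
        n_cycles=(death_cycle + 1) if death_cycle is not None else n_cycles,
        discounted_cost=d_cost,
        discounted_qaly=d_qaly,
        undiscounted_cost=u_cost,
        undiscounted_qaly=u_qaly,
        life_years=life_years,
        events_by_type=events_by_type,
        first_event_cycle=first_event_cycle,
        death_cause=death_cause,
        death_cycle=death_cycle,
        n_sae=n_sae,
        cycles=records,
    )


def run_strategy(
    cohort: Sequence[Individual],
    strategy: str,
    params: ModelParams,
    seed,
) -> StrategyResult:
    """Simulate every cohort member once and aggregate to a StrategyResult."""
    cohort = list(cohort)
    if not cohort:
        raise EstimateError("cohort is empty")
    cache = _HazardCache(params, strategy)
    n = len(cohort)
    cost = np.empty(n)
    qaly = np.empty(n)
    ly = np.empty(n)
    ucost = np.empty(n)
    uqaly = np.empty(n)
    max_cycles = max(params.horizon_age_cap - ind.age for ind in cohort)
    max_cycles = max(max_cycles, 0)
    death_cycles = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    death_is_cvd = np.zeros(n, dtype=bool)
    counts = {ev: 0 for ev in EVENT_TYPES}
    five_year_hits = {ev: 0 for ev in _FIVE_YEAR_EVENTS}

    for i, ind in enumerate(cohort):
        traj = simulate_individual(ind, strategy, params, _stream(seed, i), cache)
        cost[i] = traj.discounted_cost
        qaly[i] = traj.discounted_qaly
        ly[i] = traj.life_years
        ucost[i] = traj.undiscounted_cost
        uqaly[i] = traj.undiscounted_qaly
        if traj.death_cycle is not None:
            death_cycles[i] = traj.death_cycle
            death_is_cvd[i] = traj.death_cause == "cvd_death"
        for ev, k in traj.events_by_type.items():
            counts[ev] += k
        for ev in _FIVE_YEAR_EVENTS:
            if traj.first_event_cycle.get(ev, np.inf) < 5:
                five_year_hits[ev] += 1

    t_grid = np.arange(max_cycles + 1)
    died_before = death_cycles[:, None] < t_grid[None, :]
    cum_cvd = (died_before & death_is_cvd[:, None]).mean(axis=0)
    cum_noncvd = (died_before & ~death_is_cvd[:, None]).mean(axis=0)
    survival = 1.0 - cum_cvd - cum_noncvd

    return StrategyResult(
        strategy=strategy,
        n_individuals=n,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        mean_life_years=float(ly.mean()),
        mean_undiscounted_cost=float(ucost.mean()),
        mean_undiscounted_qaly=float(uqaly.mean()),
        five_year_cuminc={ev: five_year_hits[ev] / n for ev in _FIVE_YEAR_EVENTS},
        lifetime_event_counts=counts,
        survival_curve=survival,
        cum_cvd_death_curve=cum_cvd,
        cum_noncvd_death_curve=cum_noncvd,
        per_individual_cost=cost,
        per_individual_qaly=qaly,
        per_individual_ly=ly,
        baseline_ages=np.array([ind.age for ind in cohort]),
        baseline_sexes=[ind.sex for ind in cohort],
    )


@dataclass
class Comparison:
    """Paired intensive/standard results simulated with common random numbers."""

    intensive: StrategyResult
    standard: StrategyResult
    d_cost: np.ndarray  # per-individual, intensive - standard
    d_qaly: np.ndarray
    d_ly: np.ndarray
    five_year_rate_difference: dict  # standard - intensive (rate reduction)

    @property
    def mean_d_cost(self) -> float:
        return float(self.d_cost.mean())

    @property
    def mean_d_qaly(self) -> float:
        return float(self.d_qaly.mean())

    @property
    def mean_d_ly(self) -> float:
        return float(self.d_ly.mean())


def compare_strategies(
    cohort: Sequence[Individual], params: ModelParams, seed
) -> Comparison:
    """Simulate both arms with identical per-individual random streams."""
    intensive = run_strategy(cohort, "intensive", params, seed)
    standard = run_strategy(cohort, "standard", params, seed)
    rate_diff = {
        ev: standard.five_year_cuminc[ev] - intensive.five_year_cuminc[ev]
        for ev in _FIVE_YEAR_EVENTS
    }
    return Comparison(
        intensive=intensive,
        standard=standard,
        d_cost=intensive.per_individual_cost - standard.per_individual_cost,
        d_qaly=intensive.per_individual_qaly - standard.per_individual_qaly,
        d_ly=intensive.per_individual_ly - standard.per_individual_ly,
        five_year_rate_difference=rate_diff,
    )


def life_table_expectancy(age: int, sex: str, life_table: LifeTable, age_cap: int = 100) -> float:
    """Expected further life-years from ``age`` under the table alone,
    using the model's cycle convention (a death-year contributes 0)."""
    ages = np.arange(age, age_cap)
    qx = life_table.qx_array(ages, sex)
    surv = np.cumprod(1.0 - qx)
    return float(surv.sum())


def validate_against_life_table(
    result: StrategyResult,
    life_table: LifeTable,
    age_cap: int = 100,
    warn_threshold: float = 1.5,
) -> dict:
    """Compare modeled mean life expectancy with the life table's prediction.

    Report only — no hard failure; ``warning`` flags |difference| beyond the
    configurable threshold (default 1.5 years).
    """
    expected = float(
        np.mean(
            [
                life_table_expectancy(int(a), s, life_table, age_cap)
                for a, s in zip(result.baseline_ages, result.baseline_sexes)
            ]
        )
    )
    diff = result.mean_life_years - expected
    report = {
        "model_life_expectancy": result.mean_life_years,
        "life_table_life_expectancy": expected,
        "difference": diff,
        "abs_difference": abs(diff),
        "warning": abs(diff) > warn_threshold,
    }
    if report["warning"]:
        warnings.warn(
            f"model life expectancy differs from life table by {diff:+.2f} years",
            RuntimeWarning,
        )
    return report
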