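import json

import numpy as np
import pytest

from sprintcea.engine import (
    _stream,
    bootstrap_individuals,
    compare_strategies,
    life_table_expectancy,
    run_strategy,
    simulate_individual,
    validate_against_life_table,
)
from sprintcea.errors import EstimateError
from sprintcea.risk_models import ChronicProbs, LifeTable

from .conftest import flat_life_table, make_individual, toy_params


def markov_cohort_oracle(
    *,
    n_cycles: int,
    e: float,          # well -> acute event probability per cycle
    d_well: tuple,     # (cvd, noncvd) death probs in well
    d_acute: tuple,
    d_post: tuple,
    drug: float,
    event_cost: float,
    cc_acute: float,
    cc_post: float,
    u_well: float,
    u_acute: float,
    u_post: float,
    rate: float,
):
    """Analytic cohort evaluation of the 4-state toy chain
    (well, acute, post, dead) under the engine's accrual conventions."""
    pi = np.array([1.0, 0.0, 0.0])  # well, acute, post
    dw, da, dp = sum(d_well), sum(d_acute), sum(d_post)
    cost = qaly = ly = 0.0
    for t in range(n_cycles):
        disc = 1.0 / (1.0 + rate) ** t
        cost_t = (
            pi[0] * drug
            + pi[1] * (drug + cc_acute)
            + pi[2] * (drug + cc_post)
            + pi[0] * e * event_cost
        )
        alive = pi[0] * (1 - dw) + pi[1] * (1 - da) + pi[2] * (1 - dp)
        qaly_t = pi[0] * (1 - dw) * u_well + pi[1] * (1 - da) * u_acute + pi[2] * (1 - dp) * u_post
        cost += cost_t * disc
        qaly += qaly_t * disc
        ly += alive
        pi = np.array(
            [
                pi[0] * (1 - e - dw),
                pi[0] * e,
                pi[1] * (1 - da) + pi[2] * (1 - dp),
            ]
        )
    return cost, qaly, ly


def oracle_toy_params():
    """Time-homogeneous toy: MI only, flat mortality, flat utility bands."""
    p = toy_params(p10_mi=0.30, qx=0.03, cvd_death_fraction=0.5, discount_rate=0.03)
    p.chronic_probs["acute_mi"] = ChronicProbs(0.0, 0.05)
    p.chronic_probs["post_mi"] = ChronicProbs(0.0, 0.02)
    p.costs.annual_drug_cost = {"intensive": 100.0, "standard": 100.0}
    p.costs.acute_event_cost["mi"] = 1000.0
    p.costs.chronic_annual_cost["acute_mi"] = 300.0
    p.costs.chronic_annual_cost["post_mi"] = 300.0
    p.utilities.baseline_bands = [(0, 200, 0.9, 0.9)]
    p.utilities.acute_event_decrement["mi"] = 0.1
    p.utilities.event_utility["post_mi"] = 0.8
    return p


def oracle_expectations(params, ind, strategy):
    """Independent arithmetic for the toy chain's expected outcomes."""
    e10 = 1.0 - params.risk_equations["mi"].male.s0  # configured 10-year risk
    e = 1.0 - (1.0 - e10) ** 0.1
    if strategy == "intensive":
        e = 1.0 - (1.0 - e) ** params.rr_treatment["mi"]
    qx = params.life_table.qx(ind.age, ind.sex)
    c0 = qx * params.cvd_death_fraction
    n0 = qx * (1.0 - params.cvd_death_fraction)
    if strategy == "intensive":
        c0 = 1.0 - (1.0 - c0) ** params.rr_treatment["cvd_death"]
    ca = params.chronic_probs["acute_mi"].cvd_death
    cp = params.chronic_probs["post_mi"].cvd_death
    if strategy == "intensive":
        ca = 1.0 - (1.0 - ca) ** params.rr_treatment["cvd_death"]
        cp = 1.0 - (1.0 - cp) ** params.rr_treatment["cvd_death"]
    return markov_cohort_oracle(
        n_cycles=params.horizon_age_cap - ind.age,
        e=e,
        d_well=(c0, n0),
        d_acute=(ca, n0),
        d_post=(cp, n0),
        drug=params.costs.annual_drug_cost[strategy],
        event_cost=params.costs.acute_event_cost["mi"],
        cc_acute=params.costs.chronic_annual_cost["acute_mi"],
        cc_post=params.costs.chronic_annual_cost["post_mi"],
        u_well=0.9,
        u_acute=0.8,
        u_post=0.8,
        rate=params.discount.rate,
    )


class TestBootstrap:
    def test_n_zero_gives_empty(self):
        assert bootstrap_individuals([make_individual()], 0, seed=1) == []

    def test_pop_of_one_gives_copies(self):
        ind = make_individual()
        out = bootstrap_individuals([ind], 7, seed=1)
        assert out == [ind] * 7

    def test_weight_proportional_sampling(self):
        a = make_individual(id="a", survey_weight=9.0)
        b = make_individual(id="b", survey_weight=1.0)
        out = bootstrap_individuals([a, b], 10_000, seed=3)
        share = sum(1 for i in out if i.id == "a") / 10_000
        assert abs(share - 0.9) < 0.02

    def test_empty_pop_raises(self):
        with pytest.raises(EstimateError):
            bootstrap_individuals([], 5, seed=1)

    def test_seeded_reproducible(self):
        pop = [make_individual(id=str(i), survey_weight=1 + i) for i in range(5)]
        assert bootstrap_individuals(pop, 50, seed=2) == bootstrap_individuals(pop, 50, seed=2)


class TestSimulateIndividual:
    def test_null_model_reaches_age_cap(self):
        params = toy_params(horizon_age_cap=100)
        ind = make_individual(age=60)
        traj = simulate_individual(ind, "standard", params, _stream(1, 0))
        assert traj.death_cause is None
        assert traj.life_years == 100 - 60

    def test_certain_cvd_death_in_first_cycle(self):
        params = toy_params(qx=1.0, cvd_death_fraction=1.0)
        traj = simulate_individual(make_individual(age=60), "standard", params, _stream(1, 0))
        assert traj.n_cycles == 1
        assert traj.death_cause == "cvd_death"
        assert traj.life_years == 0.0

    def test_geometric_closed_form(self):
        q = 0.20
        params = toy_params(qx=q, cvd_death_fraction=0.0, horizon_age_cap=101)
        ind = make_individual(age=60)
        n = 20_000
        ly = np.array(
            [
                simulate_individual(ind, "standard", params, _stream(5, i)).life_years
                for i in range(n)
            ]
        )
        n_cycles = params.horizon_age_cap - ind.age
        expected = (1 - q) * (1 - (1 - q) ** n_cycles) / q
        se = ly.std(ddof=1) / np.sqrt(n)
        assert abs(ly.mean() - expected) < 3 * se

    def test_acute_states_never_persist_two_cycles(self):
        params = oracle_toy_params()
        params.chronic_probs["acute_mi"] = ChronicProbs(0.3, 0.05)  # secondary events on
        params.secondary_event_mix = {"mi": 1.0, "stroke": 0.0, "hf": 0.0}
        for i in range(200):
            traj = simulate_individual(
                make_individual(age=60), "standard", params, _stream(11, i), record=True
            )
            for rec, nxt in zip(traj.cycles, traj.cycles[1:]):
                state, outcome = rec[1], rec[2]
                if state.startswith("acute_"):
                    if outcome is None:
                        # no intervening event: acute must hand over to post
                        assert nxt[1] == "post_" + state.removeprefix("acute_")
                    elif nxt[1] == state:
                        # re-entry only via a fresh event of the same type
                        assert outcome == state.removeprefix("acute_")

    def test_trajectory_totals_match_per_cycle_tally(self, base_params):
        # brute-force re-tally of recorded cycles equals the running totals
        for i in range(30):
            traj = simulate_individual(
                make_individual(age=58), "intensive", base_params, _stream(13, i), record=True
            )
            cost = sum(c[4] / 1.03 ** t for t, c in enumerate(traj.cycles))
            qaly = sum(c[5] / 1.03 ** t for t, c in enumerate(traj.cycles))
            assert traj.discounted_cost == pytest.approx(cost, rel=1e-12)
            assert traj.discounted_qaly == pytest.approx(qaly, rel=1e-12)
            assert traj.undiscounted_cost == pytest.approx(sum(c[4] for c in traj.cycles))


class TestRunStrategy:
    def test_null_model_zero_five_year_incidence(self):
        params = toy_params()
        cohort = [make_individual(id=str(i), age=60) for i in range(50)]
        res = run_strategy(cohort, "standard", params, seed=1)
        assert all(v == 0.0 for v in res.five_year_cuminc.values())

    def test_doubling_n_preserves_first_half_streams(self, base_params, eligible_cohort):
        cohort = eligible_cohort[:100]
        res1 = run_strategy(cohort, "standard", base_params, seed=9)
        res2 = run_strategy(cohort + eligible_cohort[100:200], "standard", base_params, seed=9)
        np.testing.assert_array_equal(
            res1.per_individual_cost, res2.per_individual_cost[:100]
        )
        np.testing.assert_array_equal(res1.per_individual_ly, res2.per_individual_ly[:100])

    def test_qaly_never_exceeds_life_years(self, base_params, eligible_cohort):
        res = run_strategy(eligible_cohort[:300], "intensive", base_params, seed=2)
        assert np.all(res.per_individual_qaly <= res.per_individual_ly + 1e-12)
        assert res.mean_qaly <= res.mean_life_years

    def test_conservation_alive_plus_deaths_equals_one(self, base_params, eligible_cohort):
        res = run_strategy(eligible_cohort[:300], "standard", base_params, seed=3)
        total = res.survival_curve + res.cum_cvd_death_curve + res.cum_noncvd_death_curve
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_determinism_byte_identical(self, base_params, eligible_cohort):
        cohort = eligible_cohort[:150]
        r1 = run_strategy(cohort, "intensive", base_params, seed=21)
        r2 = run_strategy(cohort, "intensive", base_params, seed=21)
        assert r1.per_individual_cost.tobytes() == r2.per_individual_cost.tobytes()
        assert r1.per_individual_qaly.tobytes() == r2.per_individual_qaly.tobytes()
        assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())

    def test_empty_cohort_raises(self, base_params):
        with pytest.raises(EstimateError):
            run_strategy([], "standard", base_params, seed=1)


class TestMicrosimVsMarkovOracle:
    def test_means_match_analytic_cohort_within_3_se(self):
        params = oracle_toy_params()
        ind = make_individual(age=60)
        n = 20_000
        cohort = [ind] * n
        res = run_strategy(cohort, "standard", params, seed=17)
        cost_o, qaly_o, ly_o = oracle_expectations(params, ind, "standard")
        for got, want, arr in (
            (res.mean_cost, cost_o, res.per_individual_cost),
            (res.mean_qaly, qaly_o, res.per_individual_qaly),
            (res.mean_life_years, ly_o, res.per_individual_ly),
        ):
            se = arr.std(ddof=1) / np.sqrt(n)
            assert abs(got - want) < 3 * se, (got, want, se)


class TestCompareStrategies:
    def test_crn_null_all_deltas_exactly_zero(self, eligible_cohort):
        params = oracle_toy_params()  # rr all 1, equal drug costs
        params.sae_prob_standard = 0.02
        cohort = eligible_cohort[:400]
        comp = compare_strategies(cohort, params, seed=23)
        assert np.all(comp.d_cost == 0.0)
        assert np.all(comp.d_qaly == 0.0)
        assert np.all(comp.d_ly == 0.0)

    def test_cvd_death_rr_below_one_dominates_life_years(self):
        params = oracle_toy_params()
        params.rr_treatment["cvd_death"] = 0.6
        cohort = [make_individual(id=str(i), age=62) for i in range(2000)]
        comp = compare_strategies(cohort, params, seed=29)
        assert np.all(comp.d_ly >= 0.0)  # per-individual dominance under CRN
        assert comp.mean_d_ly > 0.0

    def test_two_cycle_toy_matches_enumeration(self):
        params = oracle_toy_params()
        params.horizon_age_cap = 62  # two cycles from age 60
        params.rr_treatment["mi"] = 0.7
        params.rr_treatment["cvd_death"] = 0.6
        params.costs.annual_drug_cost = {"intensive": 150.0, "standard": 100.0}
        ind = make_individual(age=60)
        n = 40_000
        comp = compare_strategies([ind] * n, params, seed=31)
        ci, qi, _ = oracle_expectations(params, ind, "intensive")
        cs, qs, _ = oracle_expectations(params, ind, "standard")
        for d_arr, want in ((comp.d_cost, ci - cs), (comp.d_qaly, qi - qs)):
            se = d_arr.std(ddof=1) / np.sqrt(n)
            assert abs(d_arr.mean() - want) < 3 * se


class TestLifeTableValidation:
    def test_self_consistency_with_pure_life_table_hazards(self):
        q = 0.05
        params = toy_params(qx=q, cvd_death_fraction=0.0)
        lt = flat_life_table(q)
        cohort = [make_individual(id=str(i), age=65) for i in range(20_000)]
        res = run_strategy(cohort, "standard", params, seed=37)
        report = validate_against_life_table(res, lt)
        se = res.per_individual_ly.std(ddof=1) / np.sqrt(len(cohort))
        assert abs(report["difference"]) < 3 * se
        assert not report["warning"]

    def test_expectancy_closed_form_flat_table(self):
        q = 0.1
        lt = flat_life_table(q)
        le = life_table_expectancy(60, "male", lt, age_cap=100)
        expected = sum((1 - q) ** t for t in range(1, 41))
        assert le == pytest.approx(expected, abs=1e-10)

    def test_report_fields_present_and_finite(self, base_params, eligible_cohort):
        res = run_strategy(eligible_cohort[:200], "standard", base_params, seed=41)
        report = validate_against_life_table(res, base_params.life_table)
        for key in ("model_life_expectancy", "life_table_life_expectancy", "difference"):
            assert np.isfinite(report[key])

    def test_empty_life_table_rejected(self):
        import pandas as pd

        from sprintcea.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            LifeTable(pd.DataFrame(columns=["age", "sex", "qx"]))
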