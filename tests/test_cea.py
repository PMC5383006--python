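import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trastecon import cea


def strategy(p_ddf=1.0, p_met=0.0, p_dead=0.0, p_card=0.0, trast=0.0, mon=0.0, card_cost=0.0):
    return cea.StrategyParams(
        "test", p_card, p_ddf, p_met, p_dead, trast, mon, card_cost
    )


def markov(
    life_table,
    u_ddf=1.0,
    u_met=1.0,
    p_dm=0.0,
    p_md=0.0,
    met_cost=0.0,
    clinic=0.0,
    age_factors=(1.0,) * 5,
    **kw,
):
    return cea.MarkovParams(
        p_ddf_to_met_per_cycle=p_dm,
        p_met_to_dead_per_cycle=p_md,
        life_table=life_table,
        utility_ddf=u_ddf,
        utility_met=u_met,
        age_utility_factors=age_factors,
        met_cost_per_cycle=met_cost,
        clinic_cost_per_year=clinic,
        **kw,
    )


NO_DISCOUNT = cea.DiscountSpec(0.0, 0.25)


class TestDiscounting:
    def test_per_cycle_rate_closed_form(self):
        assert cea.per_cycle_rate(
            cea.DiscountSpec(0.035, 1 / 12)
        ) == pytest.approx(1.035 ** (1 / 12) - 1, abs=1e-12)
        assert cea.per_cycle_rate(cea.DiscountSpec(0.035, 1 / 12)) == pytest.approx(
            0.0028709, abs=1e-7
        )
        assert cea.per_cycle_rate(cea.DiscountSpec(0.0, 0.25)) == 0.0
        assert cea.per_cycle_rate(cea.DiscountSpec(0.035, 0.25)) == pytest.approx(
            1.035 ** 0.25 - 1, abs=1e-12
        )

    def test_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            cea.DiscountSpec(0.5, 0.25)


class TestDecisionTree:
    def test_full_survival_full_utility_gives_five_qalys(self, flat_life_table):
        res = cea.run_decision_tree(
            strategy(), cea.TreeTimingAssumptions(), markov(flat_life_table), NO_DISCOUNT
        )
        assert res.qalys[0] == pytest.approx(5.0)
        assert res.cost[0] == 0.0

    def test_certain_death_accrues_pre_death_states(self, flat_life_table):
        mk = markov(flat_life_table, u_ddf=0.8, u_met=0.5)
        res = cea.run_decision_tree(
            strategy(p_ddf=0, p_met=0, p_dead=1.0),
            cea.TreeTimingAssumptions(),
            mk,
            NO_DISCOUNT,
        )
        # decedents: 1.25 years DDF then 1.25 years metastatic, dead at 2.5
        assert res.qalys[0] == pytest.approx(1.25 * 0.8 + 1.25 * 0.5)

    def test_matches_hand_computed_expected_value(self, flat_life_table):
        """Spreadsheet-style oracle, all branch arithmetic done by hand:
        u_ddf=.8, u_met=.5, event at 2y, split (.5,.3,.2), clinic 400/y for
        3y, met care 1000/cycle, schedule 5000, monitoring 200, 10% cardiac
        events costing 2000 with utility x0.6 for a quarter."""
        timing = cea.TreeTimingAssumptions(
            event_time_years=2.0, cardiac_duration_years=0.25
        )
        mk = markov(flat_life_table, u_ddf=0.8, u_met=0.5, met_cost=1000.0, clinic=400.0)
        res = cea.run_decision_tree(
            strategy(0.5, 0.3, 0.2, p_card=0.1, trast=5000.0, mon=200.0, card_cost=2000.0),
            timing,
            mk,
            NO_DISCOUNT,
        )
        exp_qalys = (
            0.5 * (0.8 * 5)
            + 0.3 * (0.8 * 2 + 0.5 * 3)
            + 0.2 * (0.8 * 1 + 0.5 * 1)
            - 0.1 * (1 - 0.6) * 0.8 * 0.25
        )
        exp_cost = (
            0.5 * 1200.0  # clinic, 12 quarters
            + 0.3 * (800.0 + 12 * 1000.0)  # clinic to 2y, then met care
            + 0.2 * (400.0 + 4 * 1000.0)  # clinic to 1y, met care 1y
            + 5000.0 + 200.0 + 0.1 * 2000.0
        )
        assert res.qalys[0] == pytest.approx(exp_qalys, abs=1e-12)
        assert res.cost[0] == pytest.approx(exp_cost, abs=1e-9)

    def test_invalid_simplex_rejected(self, flat_life_table):
        with pytest.raises(ValueError, match="sum"):
            cea.run_decision_tree(
                strategy(0.5, 0.3, 0.3),
                cea.TreeTimingAssumptions(),
                markov(flat_life_table),
                NO_DISCOUNT,
            )


class TestMarkov:
    def test_no_transitions_yield_years_remaining(self, flat_life_table):
        mk = markov(flat_life_table)
        trace = cea.run_markov((1.0, 0.0, 0.0), mk, NO_DISCOUNT)
        # years 5 through 48 at utility 1
        assert trace.total_qalys[0] == pytest.approx(43.0)

    def test_certain_metastatic_death_lasts_one_cycle(self, flat_life_table):
        mk = markov(flat_life_table, p_md=1.0)
        trace = cea.run_markov((0.0, 1.0, 0.0), mk, NO_DISCOUNT)
        occ = trace.occupancy[..., 0]
        assert occ[0, 1] == pytest.approx(1.0)
        assert occ[1, 1] == pytest.approx(0.0)
        assert occ[1, 2] == pytest.approx(1.0)

    def test_three_cycle_trace_equals_matrix_product_oracle(self):
        """Independent hand-coded transition-matrix oracle, 1e-12."""
        lt = np.full(101, 0.04)
        mk = markov(lt, u_ddf=0.9, u_met=0.6, p_dm=0.05, p_md=0.2)
        disc = cea.DiscountSpec(0.035, 0.25)
        trace = cea.run_markov((0.7, 0.2, 0.1), mk, disc)
        q_c = 1 - (1 - 0.04) ** 0.25
        state = np.array([0.7, 0.2, 0.1])
        expected_q = 0.0
        for i in range(3):
            t = 5.0 + 0.25 * i
            expected_q += (state[0] * 0.9 + state[1] * 0.6) * 0.25 * 1.035 ** (-t)
            p_dm = 0.05 * (20.0 - t) / 15.0
            P = np.array(
                [
                    [(1 - q_c) * (1 - p_dm), (1 - q_c) * p_dm, q_c],
                    [0.0, (1 - q_c) * (1 - 0.2), 1 - (1 - q_c) * (1 - 0.2)],
                    [0.0, 0.0, 1.0],
                ]
            )
            state = state @ P
        np.testing.assert_allclose(
            trace.occupancy[3, :, 0], state, atol=1e-12
        )
        assert trace.cycle_qalys_discounted[:3, 0].sum() == pytest.approx(
            expected_q, abs=1e-12
        )

    def test_trace_conserves_cohort_and_death_is_monotone(self, base_config):
        mk = base_config.markov
        trace = cea.run_markov(
            (0.76, 0.11, 0.13), mk, base_config.discount, cohort_size=100.0
        )
        totals = trace.occupancy.sum(axis=1)[:, 0]
        np.testing.assert_allclose(totals, 100.0, atol=1e-9)
        dead = trace.occupancy[:, 2, 0]
        assert np.all(np.diff(dead) >= -1e-12)
        assert np.all(trace.cycle_qalys >= 0.0)

    def test_met_onset_taper_hits_zero_at_endpoint(self, base_config):
        mk = base_config.markov
        assert mk.p_met_onset(5.0) == pytest.approx(
            np.atleast_1d(mk.p_ddf_to_met_per_cycle)
        )
        assert mk.p_met_onset(20.0) == 0.0
        assert mk.p_met_onset(33.25) == 0.0
        mid = mk.p_met_onset(12.5)[0]
        assert 0.0 < mid < np.atleast_1d(mk.p_ddf_to_met_per_cycle)[0]

    def test_life_table_must_cover_model_ages(self):
        short_lt = np.zeros(60)  # ends before age 100
        mk = markov(short_lt)
        with pytest.raises(ValueError, match="age"):
            cea.run_markov((1.0, 0.0, 0.0), mk, NO_DISCOUNT)

    def test_bad_start_split_rejected(self, flat_life_table):
        with pytest.raises(ValueError, match="sum"):
            cea.run_markov((0.7, 0.2, 0.2), markov(flat_life_table), NO_DISCOUNT)


class TestRunStrategy:
    def test_identical_strategies_identical_results(self, base_config):
        s = base_config.strategies["zero"]
        r1 = cea.run_strategy(s, base_config.timing, base_config.markov, base_config.discount)
        r2 = cea.run_strategy(s, base_config.timing, base_config.markov, base_config.discount)
        assert r1.scalar() == r2.scalar()

    @given(st.floats(0.0, 0.07))
    def test_totals_non_increasing_in_discount_rate(self, base_config, rate):
        s = base_config.strategies["nine_weeks"]
        lo = cea.run_strategy(s, base_config.timing, base_config.markov,
                              cea.DiscountSpec(rate, 0.25))
        hi = cea.run_strategy(s, base_config.timing, base_config.markov,
                              cea.DiscountSpec(min(rate + 0.01, 0.07), 0.25))
        assert hi.scalar()[1] <= lo.scalar()[1] + 1e-12
        assert hi.scalar()[0] <= lo.scalar()[0] + 1e-12

    def test_monthly_cycle_variant_runs_and_stays_close(self, base_config):
        s = base_config.strategies["zero"]
        quarterly = cea.run_strategy(
            s, base_config.timing, base_config.markov, cea.DiscountSpec(0.035, 0.25)
        )
        monthly = cea.run_strategy(
            s, base_config.timing, base_config.markov, cea.DiscountSpec(0.035, 1 / 12)
        )
        assert monthly.scalar()[1] == pytest.approx(quarterly.scalar()[1], rel=0.02)


def test_config_rejects_arm_common_costs(base_config):
    raw = dict(base_config.raw)
    raw["costs"] = dict(raw["costs"], chemotherapy={"value": 100.0})
    with pytest.raises(ValueError, match="common"):
        cea.load_config(raw, life_table=base_config.markov.life_table)


def test_placeholder_detection(base_config):
    raw = {
        "utilities": {"ddf": {"value": None, "source": "placeholder"}},
        "costs": {"met_per_cycle": {"value": 1.0, "source": "reconstructed"}},
    }
    assert cea.unfilled_placeholders(raw) == ["utilities.ddf"]
    assert cea.unfilled_placeholders(base_config.raw) == []
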