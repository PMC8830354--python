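import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miadm.life_table import MortalityTable
from miadm.markov_engine import (
    HealthState as S,
)
from miadm.markov_engine import (
    N_STATES,
    discounted_qalys,
    evaluate_batch,
    evaluate_strategies,
    rank_strategies,
    run_cohort,
    transition_row,
    treatment_outcome_branch,
)
from miadm.strategies import STRATEGY_ORDER

EVENT_RATE_NAMES = (
    "growth_rate_small",
    "rupture_rate_nongrowing",
    "rupture_rate_growing",
    "de_novo_rate",
)
TREATMENT_RISK_NAMES = (
    "mild_after_one",
    "modsev_after_one",
    "mortality_after_one",
    "mild_after_two",
    "modsev_after_two",
    "mortality_after_two",
)


def constant_table(q: float) -> MortalityTable:
    ages = np.arange(57, 100)
    return MortalityTable(ages=ages, q=np.full(len(ages), q))


def zeroed(values: dict, names) -> dict:
    out = dict(values)
    for n in names:
        out[n] = 0.0
    return out


class TestTransitionRows:
    def test_rows_sum_to_one_all_states_all_strategies(self, base_params, fixture_table):
        for sid in STRATEGY_ORDER:
            for state in S:
                row = transition_row(sid, state, 70, base_params, fixture_table)
                assert sum(row.probabilities.values()) == pytest.approx(1.0, abs=1e-12)

    def test_well_mia_rupture_and_growth_arcs(self, base_params, fixture_table):
        """Rupture arc is 0.005*2.08 and growth arc 0.026*3.47 before
        conditioning on surviving background mortality."""
        row = transition_row("natural_history", S.WELL_MIA, 57, base_params, fixture_table)
        q = fixture_table.q_at(57) * (1 - base_params.settings.sah_fraction)
        live = 1 - q
        assert row.probabilities[S.SAH] / live == pytest.approx(0.0104, rel=1e-12)
        assert row.probabilities[S.WELL_GROWING_MIA] / live == pytest.approx(
            (1 - 0.0104) * 0.09022, rel=1e-10
        )

    def test_death_absorbing(self, base_params, fixture_table):
        row = transition_row("treat_two", S.DEATH, 80, base_params, fixture_table)
        assert row.probabilities[S.DEATH] == 1.0

    def test_sah_tunnel_resolves_to_coiling_outcomes(self, base_params, fixture_table):
        row = transition_row("natural_history", S.SAH, 70, base_params, fixture_table)
        assert row.probabilities[S.DEATH] == pytest.approx(0.35)
        assert row.probabilities[S.MILD_DISABILITY] == pytest.approx(0.15)
        assert row.probabilities[S.MOD_SEVERE_DISABILITY] == pytest.approx(0.09)
        assert row.probabilities[S.WELL_BOTH_TREATED] == pytest.approx(0.41)
        assert row.coil_flags[S.WELL_BOTH_TREATED] == 1.0

    def test_growing_detected_only_at_screening_cycles(self, base_params, fixture_table):
        due = transition_row("follow_up_2y", S.WELL_GROWING_MIA, 58, base_params, fixture_table, cycle=2)
        off = transition_row("follow_up_2y", S.WELL_GROWING_MIA, 58, base_params, fixture_table, cycle=3)
        assert due.probabilities[S.WELL_ONE_TREATED] > 0
        assert off.probabilities[S.WELL_ONE_TREATED] == 0.0
        assert off.probabilities[S.WELL_GROWING_MIA] > 0

    def test_cycle_zero_detection_never_fires(self, base_params, fixture_table):
        row = transition_row("follow_up_1y", S.WELL_GROWING_MIA, 57, base_params, fixture_table, cycle=0)
        assert row.probabilities[S.WELL_ONE_TREATED] == 0.0

    def test_disability_states_transition_only_to_self_or_death(self, base_params, fixture_table):
        for state in (S.MILD_DISABILITY, S.MOD_SEVERE_DISABILITY):
            row = transition_row("natural_history", state, 75, base_params, fixture_table)
            positive = {s for s, p in row.probabilities.items() if p > 0}
            assert positive == {state, S.DEATH}


class TestTreatmentBranches:
    def test_treat_two_outcomes(self, base_params):
        b = treatment_outcome_branch("treat_two", base_params)
        assert b["death"] == pytest.approx(0.011)
        assert b["moderate_severe"] == pytest.approx(0.053)
        assert b["mild"] == pytest.approx(0.032)
        assert b["full_recovery"] == pytest.approx(0.904)

    def test_sah_coiling_outcomes(self, base_params):
        b = treatment_outcome_branch("sah_coiling", base_params)
        assert b == pytest.approx(
            {"death": 0.35, "moderate_severe": 0.09, "mild": 0.15, "full_recovery": 0.41}
        )

    def test_zero_risks_give_full_recovery(self, base_params):
        values = zeroed(base_params.base_values(), TREATMENT_RISK_NAMES)
        b = treatment_outcome_branch("treat_one", values)
        assert b["full_recovery"] == 1.0

    def test_unknown_kind_rejected(self, base_params):
        with pytest.raises(ValueError):
            treatment_outcome_branch("clipping", base_params)

    def test_oversummed_branch_rejected(self, base_params):
        values = dict(base_params.base_values())
        values["mortality_after_two"] = 0.99
        with pytest.raises(ValueError, match="sum above 1"):
            treatment_outcome_branch("treat_two", values)


class TestCohortTrace:
    def test_no_event_no_mortality_cohort_stays_well(self, base_params):
        params = base_params.with_settings(sah_fraction=0.0)
        values = zeroed(params.base_values(), EVENT_RATE_NAMES)
        table = constant_table(0.0)
        from miadm.markov_engine import _run_batch
        from miadm.strategies import get_strategy

        _, occ, _ = _run_batch(get_strategy("natural_history"), values, table, params.settings, keep_trace=True)
        assert np.allclose(occ[0, :, S.WELL_MIA], 1.0)

    def test_treat_two_entry_occupancy(self, base_params, fixture_table):
        trace = run_cohort("treat_two", base_params, fixture_table)
        assert trace.occupancy[0, S.DEATH] == pytest.approx(0.011)
        assert trace.occupancy[0, S.MOD_SEVERE_DISABILITY] == pytest.approx(0.053)
        assert trace.occupancy[0, S.MILD_DISABILITY] == pytest.approx(0.032)
        assert trace.occupancy[0, S.WELL_BOTH_TREATED] == pytest.approx(0.904)

    def test_death_occupancy_non_decreasing_all_strategies(self, base_params, fixture_table):
        for sid in STRATEGY_ORDER:
            trace = run_cohort(sid, base_params, fixture_table)
            deaths = trace.occupancy[:, S.DEATH]
            assert np.all(np.diff(deaths) >= -1e-12), sid

    def test_trace_rows_sum_to_one(self, base_params, fixture_table):
        for sid in STRATEGY_ORDER:
            trace = run_cohort(sid, base_params, fixture_table)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)

    def test_trace_has_43_cycles(self, base_params, fixture_table):
        trace = run_cohort("natural_history", base_params, fixture_table)
        assert trace.occupancy.shape == (43, N_STATES)
        df = trace.to_frame()
        assert df["age"].iloc[0] == 57 and df["age"].iloc[-1] == 99


class TestDiscountedQalys:
    def test_all_dead_is_zero(self, base_params, fixture_table):
        trace = run_cohort("natural_history", base_params, fixture_table)
        dead = trace.occupancy * 0
        dead[:, S.DEATH] = 1.0
        from dataclasses import replace

        zero_trace = replace(trace, occupancy=dead, coil_arrivals=dead * 0)
        assert discounted_qalys(zero_trace, base_params).qalys == 0.0

    def test_full_utility_annuity(self, base_params):
        """With no events and no mortality the EV is the closed-form
        43-term discounted annuity sum_{t=0}^{42} 1.03^-t = 24.702..."""
        params = base_params.with_settings(sah_fraction=0.0)
        values = zeroed(params.base_values(), EVENT_RATE_NAMES)
        ev = evaluate_batch("natural_history", values, constant_table(0.0), params.settings)
        expected = sum(1.03 ** -t for t in range(43))
        assert ev[0] == pytest.approx(expected, abs=1e-6)

    def test_survival_annuity_oracle(self, base_params):
        """Collapsed well/death chain with constant annual mortality must
        match the geometric closed form to 1e-10."""
        q = 0.037
        params = base_params.with_settings(sah_fraction=0.0)
        values = zeroed(params.base_values(), EVENT_RATE_NAMES)
        ev = evaluate_batch("natural_history", values, constant_table(q), params.settings)
        expected = sum((1.03 ** -t) * (1 - q) ** t for t in range(43))
        assert ev[0] == pytest.approx(expected, abs=1e-10)

    def test_undiscounted_exceeds_discounted(self, base_params, fixture_table):
        disc = evaluate_strategies(base_params, fixture_table)
        undisc = evaluate_strategies(base_params.with_settings(discount_rate=0.0), fixture_table)
        for sid in STRATEGY_ORDER:
            assert undisc[sid] > disc[sid]

    def test_trace_and_batch_paths_agree(self, base_params, fixture_table):
        for sid in ("natural_history", "treat_two", "follow_up_5y"):
            trace = run_cohort(sid, base_params, fixture_table)
            via_trace = discounted_qalys(trace, base_params).qalys
            via_batch = float(
                evaluate_batch(sid, base_params.base_values(), fixture_table, base_params.settings)[0]
            )
            assert via_trace == pytest.approx(via_batch, abs=1e-12)


class TestStrategyComparison:
    def test_treat_two_best_natural_history_worst(self, base_params, fixture_table):
        evs = evaluate_strategies(base_params, fixture_table)
        ranked = rank_strategies(evs)
        assert ranked[0][0] == "treat_two"
        assert ranked[-1][0] == "natural_history"

    def test_shorter_screening_interval_weakly_better(self, base_params, fixture_table):
        evs = evaluate_strategies(base_params, fixture_table)
        assert evs["follow_up_1y"] >= evs["follow_up_2y"] >= evs["follow_up_5y"]
        assert evs["follow_up_5y"] >= evs["natural_history"]

    def test_qalys_within_annuity_bound(self, base_params, fixture_table):
        bound = sum(1.03 ** -t for t in range(43))
        for ev in evaluate_strategies(base_params, fixture_table).values():
            assert 0.0 <= ev <= bound

    def test_no_disease_limit_equalises_strategies(self, base_params):
        """With no aneurysm events and riskless treatment, all strategies
        agree up to the one-off procedure disutility."""
        params = base_params.with_settings(sah_fraction=0.0)
        values = zeroed(params.base_values(), EVENT_RATE_NAMES + TREATMENT_RISK_NAMES)
        table = constant_table(0.01)
        evs = {
            sid: float(evaluate_batch(sid, values, table, params.settings)[0])
            for sid in STRATEGY_ORDER
        }
        assert evs["natural_history"] == pytest.approx(evs["follow_up_1y"], abs=1e-12)
        assert evs["treat_one"] == pytest.approx(evs["treat_two"], abs=1e-12)
        assert evs["natural_history"] - evs["treat_two"] == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_rupture_rate(self, base_params, fixture_table):
        evs = []
        for r in np.linspace(0.003, 0.009, 5):
            p = base_params.with_value("rupture_rate_nongrowing", float(r))
            evs.append(evaluate_strategies(p, fixture_table, strategy_ids=("natural_history",)))
        vals = [e["natural_history"] for e in evs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_monotone_in_treatment_mortality(self, base_params, fixture_table):
        evs = []
        for m in np.linspace(0.0, 0.031, 5):
            p = base_params.with_value("mortality_after_two", float(m))
            evs.append(evaluate_strategies(p, fixture_table, strategy_ids=("treat_two",)))
        vals = [e["treat_two"] for e in evs]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_riskless_treatment_makes_treat_two_dominant(self, base_params, fixture_table):
        values = zeroed(base_params.base_values(), TREATMENT_RISK_NAMES)
        evs = {
            sid: float(evaluate_batch(sid, values, fixture_table, base_params.settings)[0])
            for sid in STRATEGY_ORDER
        }
        for sid in STRATEGY_ORDER[1:]:
            assert evs["treat_two"] >= evs[sid] - 1e-12

    def test_lethal_treatment_makes_natural_history_better(self, base_params, fixture_table):
        values = dict(base_params.base_values())
        values["mortality_after_two"] = 1.0
        values["modsev_after_two"] = 0.0
        values["mild_after_two"] = 0.0
        evs = {
            sid: float(evaluate_batch(sid, values, fixture_table, base_params.settings)[0])
            for sid in ("natural_history", "treat_two")
        }
        assert evs["natural_history"] > evs["treat_two"]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    growth=st.floats(0.0, 0.5),
    rupture=st.floats(0.0, 0.5),
    rupture_growing=st.floats(0.0, 1.0),
    rr_rupture=st.floats(0.1, 10.0),
    rr_growth=st.floats(0.1, 10.0),
    de_novo=st.floats(0.0, 0.2),
    mort_two=st.floats(0.0, 0.3),
)
def test_conservation_under_fuzzed_parameters(
    growth, rupture, rupture_growing, rr_rupture, rr_growth, de_novo, mort_two
):
    """Occupancy rows sum to 1 for every strategy and cycle under arbitrary
    admissible event rates."""
    from miadm import build_fixture_table, load_base_parameters
    from miadm.markov_engine import _run_batch
    from miadm.strategies import get_strategy

    params = load_base_parameters()
    table = build_fixture_table()
    values = dict(params.base_values())
    values.update(
        growth_rate_small=growth,
        rupture_rate_nongrowing=rupture,
        rupture_rate_growing=rupture_growing,
        rr_rupture_mia=rr_rupture,
        rr_growth_mia=rr_growth,
        de_novo_rate=de_novo,
        mortality_after_two=mort_two,
    )
    for sid in STRATEGY_ORDER:
        _, occ, _ = _run_batch(get_strategy(sid), values, table, params.settings, keep_trace=True)
        np.testing.assert_allclose(occ[0].sum(axis=1), 1.0, atol=1e-9)
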