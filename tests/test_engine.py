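"""Cohort propagation, discounting and accrual arithmetic."""

import numpy as np
import pytest

import menomark as mm
from menomark.engine import (
    accumulate_costs,
    accumulate_qalys,
    discount_factor,
    propagate,
)
from menomark.params import CostLedger, UtilityTable
from menomark.states import (
    ABSORBING,
    HealthStateGraph,
    INITIAL,
    ON_ALLOCATED,
    STATES,
    STATE_INDEX,
)
from menomark.transitions import TransitionModel, TransitionRow


def _frozen_cohort_model(arm=mm.ARM_LNG):
    """A model whose cohort never leaves the initial state."""
    graph = HealthStateGraph(
        arm=arm,
        allowed_edges={**{s: frozenset({s}) for s in STATES},
                       INITIAL: frozenset({INITIAL})},
    )
    rows = {s: TransitionRow(s, {s: 1.0}, fixed=True)
            for s in STATES if s != INITIAL}
    first = TransitionRow(INITIAL, {INITIAL: 1.0}, fixed=True)
    return TransitionModel(graph=graph, first_cycle_row=first, rows=rows)


def _flat_utilities(value, arm=mm.ARM_LNG):
    return UtilityTable(instrument="eq5d", arm=arm,
                        values={s: value for s in STATES})


def _empty_ledger(**kw):
    defaults = dict(entry_cost=0.0, discontinuation_cost=0.0,
                    surgery_cost=0.0, switch_cost=0.0)
    defaults.update(kw)
    return CostLedger(**defaults)


class TestPropagate:
    def test_identity_model_keeps_occupancy_constant(self):
        trace = propagate(_frozen_cohort_model(), 24)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_first_cycle_applies_initial_row(self, lng_model):
        trace = propagate(lng_model, 24)
        occ1 = {s: trace.occupancy[1, STATE_INDEX[s]] for s in STATES}
        assert occ1[INITIAL] == 0.0
        assert occ1["well_allocated"] == pytest.approx(182 / 285)
        assert occ1["symptomatic"] == pytest.approx(72 / 285)
        assert occ1["change_to_other"] == pytest.approx(19 / 285)
        assert occ1["no_treatment"] == pytest.approx(12 / 285)
        assert occ1["surgery"] == 0.0

    def test_second_cycle_symptomatic_mass(self, lng_model):
        # hand product of the first-cycle and stay probabilities
        trace = propagate(lng_model, 24)
        symp2 = trace.occupancy[2, STATE_INDEX["symptomatic"]]
        assert symp2 == pytest.approx((72 / 285) * (700 / 772))
        assert symp2 == pytest.approx(0.253 * 0.907, abs=5e-4)

    def test_conservation_and_monotone_absorption(self, eq5d_spec):
        for arm in mm.ARMS:
            trace = propagate(eq5d_spec.arm(arm).transitions, 24)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            for s in ABSORBING:
                occ = trace.state_occupancy(s)
                assert np.all(np.diff(occ) >= -1e-12)

    def test_no_return_to_allocated_treatment(self, eq5d_spec):
        """Mass on the allocated treatment never increases once lost."""
        idx = [STATE_INDEX[s] for s in ON_ALLOCATED]
        for arm in mm.ARMS:
            trace = propagate(eq5d_spec.arm(arm).transitions, 24)
            on_alloc = trace.occupancy[:, idx].sum(axis=1)
            assert np.all(np.diff(on_alloc) <= 1e-12)

    def test_invalid_horizon(self, lng_model):
        with pytest.raises(ValueError):
            propagate(lng_model, 0)


class TestDiscounting:
    @pytest.mark.parametrize(
        "cycle, rate, expected",
        [(0, 0.035, 1.0),
         (12, 0.035, 1 / 1.035),
         (24, 0.0, 1.0)],
    )
    def test_smooth_factor(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected)

    def test_smooth_factor_is_nonincreasing(self):
        f = [discount_factor(t, 0.035) for t in range(25)]
        assert all(a >= b for a, b in zip(f, f[1:]))
        assert all(0 < x <= 1 for x in f)

    def test_annual_step_convention(self):
        # year 1 undiscounted, year 2 discounted one year
        assert discount_factor(1, 0.035, "annual-step") == 1.0
        assert discount_factor(12, 0.035, "annual-step") == 1.0
        assert discount_factor(13, 0.035, "annual-step") == pytest.approx(1 / 1.035)
        assert discount_factor(24, 0.035, "annual-step") == pytest.approx(1 / 1.035)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-1, 0.035)


class TestQalyAccrual:
    def test_perfect_health_two_years_no_discounting(self):
        trace = propagate(_frozen_cohort_model(), 24)
        q = accumulate_qalys(trace, _flat_utilities(1.0), annual_rate=0.0)
        assert q == 2.0

    def test_half_utility_one_year(self):
        trace = propagate(_frozen_cohort_model(), 12)
        q = accumulate_qalys(trace, _flat_utilities(0.5), annual_rate=0.0)
        assert q == pytest.approx(0.5)

    def test_entry_month_accrual_adds_one_baseline_month(self):
        trace = propagate(_frozen_cohort_model(), 24)
        base = accumulate_qalys(trace, _flat_utilities(0.6), 0.0)
        with_entry = accumulate_qalys(trace, _flat_utilities(0.6), 0.0,
                                      entry_month_accrual=True)
        assert with_entry - base == pytest.approx(0.6 / 12)

    def test_missing_state_utility_raises(self):
        trace = propagate(_frozen_cohort_model(), 12)
        table = UtilityTable(instrument="eq5d", arm=mm.ARM_LNG,
                             values={INITIAL: 0.75})
        with pytest.raises(KeyError, match="well_allocated"):
            accumulate_qalys(trace, table, 0.0)

    def test_discounting_reduces_qalys(self, eq5d_spec):
        arm_spec = eq5d_spec.arm(mm.ARM_LNG)
        trace = propagate(arm_spec.transitions, 24)
        q0 = accumulate_qalys(trace, arm_spec.utilities, 0.0)
        q35 = accumulate_qalys(trace, arm_spec.utilities, 0.035)
        assert q35 < q0


class TestCostAccrual:
    def test_empty_ledger_costs_nothing(self, lng_model):
        trace = propagate(lng_model, 24)
        assert accumulate_costs(trace, _empty_ledger(), 0.035) == 0.0

    def test_entry_bundle_only(self):
        # cohort never leaves the initial state; only the insertion bundle
        # (26.67 + 53.33 + 17.00 + 88.00 + 21.63) is charged
        trace = propagate(_frozen_cohort_model(), 24)
        ledger = _empty_ledger(entry_cost=206.63)
        assert accumulate_costs(trace, ledger, 0.035) == pytest.approx(206.63)

    def test_surgery_cost_charged_to_inflow(self, lng_model):
        trace = propagate(lng_model, 24)
        ledger = _empty_ledger(surgery_cost=1000.0)
        total = accumulate_costs(trace, ledger, 0.0)
        cum_inflow = sum(trace.inflow("surgery", t) for t in range(1, 25))
        assert total == pytest.approx(1000.0 * cum_inflow)

    def test_scheduled_cost_beyond_horizon_raises(self, lng_model):
        from menomark.params import ScheduledCost
        trace = propagate(lng_model, 24)
        ledger = _empty_ledger(
            scheduled=(ScheduledCost(cycle=30, states=ON_ALLOCATED,
                                     amount=10.0, label="late"),))
        with pytest.raises(ValueError, match="beyond horizon"):
            accumulate_costs(trace, ledger, 0.035)
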