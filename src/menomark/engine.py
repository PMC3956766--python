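"""Cohort Markov engine: propagation, discounting, QALY and cost accrual.

The engine tracks the expected fraction of a cohort in each health state at
each monthly boundary (the *occupancy*), plus the full flow matrix of each
cycle so that event costs attached to transitions (surgery, discontinuation,
switching treatment) can be accrued without re-deriving flows from occupancy
differences.

QALY accounting: each of the 24 cycles contributes ``utility / 12`` weighted
by end-of-cycle occupancy and discounted at the cycle's end.  Under the
reference convention one additional entry month is accrued at baseline in
the initial state (see :class:`menomark.params.ModelSettings`); with that
switch off, a zero discount rate and unit utilities the total is exactly
``horizon / 12`` years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ArmSpec, CostLedger, ModelSettings, ModelSpec, UtilityTable
from .states import (
    CHANGE_TO_OTHER,
    INITIAL,
    N_STATES,
    ON_ALLOCATED,
    STATE_INDEX,
    STATES,
    SURGERY,
)
from .transitions import TransitionModel
from .econ import EconResult, econ_result

_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy and flows of one arm's cohort over the model horizon.

    ``occupancy[t]`` is the state distribution at month ``t`` (0..horizon);
    ``flows[t-1]`` is the matrix of probability mass moving source->dest
    during cycle ``t`` (1..horizon).
    """

    arm: str
    occupancy: np.ndarray  # (horizon+1, n_states)
    flows: np.ndarray      # (horizon, n_states, n_states)

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.all(np.abs(sums - 1.0) <= 1e-6):
            raise ValueError("occupancy vectors must sum to 1")

    @property
    def horizon_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_occupancy(self, state: str) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[state]]

    def inflow(self, state: str, cycle: int) -> float:
        """Probability mass entering ``state`` from elsewhere during ``cycle``."""
        j = STATE_INDEX[state]
        F = self.flows[cycle - 1]
        return float(F[:, j].sum() - F[j, j])

    def outflow(self, sources, dests, cycle: int) -> float:
        si = [STATE_INDEX[s] for s in sources]
        di = [STATE_INDEX[d] for d in dests]
        return float(self.flows[cycle - 1][np.ix_(si, di)].sum())


def propagate(model: TransitionModel, horizon_cycles: int,
              initial_row_cycles: int = 1) -> CohortTrace:
    """Run the cohort through ``horizon_cycles`` monthly transitions.

    The dedicated first-cycle row (the transition out of the initial state)
    is applied for ``initial_row_cycles`` cycles; the stationary matrix
    governs thereafter.  With the default of 1 the initial state empties
    after the first cycle.
    """
    if horizon_cycles < 1:
        raise ValueError("horizon_cycles must be >= 1")
    occ = np.zeros((horizon_cycles + 1, N_STATES))
    flows = np.zeros((horizon_cycles, N_STATES, N_STATES))
    occ[0, STATE_INDEX[INITIAL]] = 1.0
    M_first = model.matrix(first_cycle=True)
    M_rest = model.matrix(first_cycle=False)
    for t in range(1, horizon_cycles + 1):
        M = M_first if t <= initial_row_cycles else M_rest
        F = occ[t - 1][:, None] * M
        flows[t - 1] = F
        occ[t] = F.sum(axis=0)
        if abs(occ[t].sum() - 1.0) > _CONSERVATION_TOL:
            raise ArithmeticError(f"cohort mass not conserved at cycle {t}")
    return CohortTrace(arm=model.arm, occupancy=occ, flows=flows)


def discount_factor(cycle: int, annual_rate: float,
                    convention: str = "smooth") -> float:
    """Discount factor for an accrual at the end of month ``cycle``.

    'smooth' compounds continuously per cycle: ``(1+r)^(-cycle/12)``.
    'annual-step' discounts in whole-year blocks (months 1..12 undiscounted,
    months 13..24 at ``(1+r)^-1``, ...).
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    if convention == "smooth":
        return float((1.0 + annual_rate) ** (-cycle / 12.0))
    if convention == "annual-step":
        year = max(0, (cycle - 1)) // 12
        return float((1.0 + annual_rate) ** (-year))
    raise ValueError(f"unknown discount convention {convention!r}")


def accumulate_qalys(trace: CohortTrace, utilities: UtilityTable,
                     annual_rate: float, convention: str = "smooth",
                     entry_month_accrual: bool = False) -> float:
    """Discounted QALYs per woman over the trace's horizon.

    Each cycle contributes one twelfth of the occupancy-weighted utility,
    discounted at the cycle's end.  ``entry_month_accrual`` adds one
    undiscounted month in the baseline state distribution.
    """
    missing = [s for s in STATES if s not in utilities.values]
    if missing:
        raise KeyError(f"utility table is missing states: {missing}")
    u = np.array([utilities.values[s] for s in STATES])
    horizon = trace.horizon_cycles
    per_cycle = [
        discount_factor(t, annual_rate, convention)
        * float(trace.occupancy[t] @ u)
        for t in range(1, horizon + 1)
    ]
    if entry_month_accrual:
        per_cycle.append(float(trace.occupancy[0] @ u))
    # single division keeps the undiscounted unit-utility case exact
    return math.fsum(per_cycle) / 12.0


def accumulate_costs(trace: CohortTrace, ledger: CostLedger,
                     annual_rate: float, convention: str = "smooth") -> float:
    """Discounted total cost per woman.

    Event costs are charged to the probability mass triggering them
    (inflows and outflows from the trace's flow matrices), scheduled costs
    to occupancy at their cycle, recurring costs to per-cycle occupancy of
    their states.
    """
    horizon = trace.horizon_cycles
    total = ledger.entry_cost  # cycle 0, whole cohort, undiscounted
    leave_states = (CHANGE_TO_OTHER, "no_treatment", SURGERY)
    for t in range(1, horizon + 1):
        df = discount_factor(t, annual_rate, convention)
        total += df * ledger.surgery_cost * trace.inflow(SURGERY, t)
        total += df * ledger.discontinuation_cost * trace.outflow(
            ON_ALLOCATED, leave_states, t)
        total += df * ledger.switch_cost * trace.inflow(CHANGE_TO_OTHER, t)
    for sched in ledger.scheduled:
        if sched.cycle > horizon:
            raise ValueError(f"scheduled cost {sched.label!r} at cycle "
                             f"{sched.cycle} beyond horizon {horizon}")
        df = discount_factor(sched.cycle, annual_rate, convention)
        occ = sum(trace.occupancy[sched.cycle, STATE_INDEX[s]]
                  for s in sched.states)
        total += df * sched.amount * occ
    if ledger.recurring:
        idx = [STATE_INDEX[s] for s in ledger.recurring]
        amounts = np.array([ledger.recurring[s] for s in ledger.recurring])
        if ledger.recurring_timing == "start":
            cycles = range(0, horizon)        # occupancy at cycle start
        else:
            cycles = range(1, horizon + 1)    # occupancy at cycle end
        for t in cycles:
            df = discount_factor(t, annual_rate, convention)
            total += df * float(trace.occupancy[t, idx] @ amounts)
    return total


@dataclass(frozen=True)
class ArmOutcome:
    arm: str
    cost: float
    qalys: float
    trace: CohortTrace


def evaluate_arm(arm_spec: ArmSpec, settings: ModelSettings) -> ArmOutcome:
    """Deterministic cost and QALY totals for one arm."""
    trace = propagate(arm_spec.transitions, settings.horizon_cycles,
                      settings.initial_row_cycles)
    qalys = accumulate_qalys(trace, arm_spec.utilities,
                             settings.discount_rate_annual,
                             settings.discount_convention,
                             settings.entry_month_accrual)
    cost = accumulate_costs(trace, arm_spec.costs,
                            settings.discount_rate_annual,
                            settings.discount_convention)
    return ArmOutcome(arm=arm_spec.arm, cost=cost, qalys=qalys, trace=trace)


def evaluate_spec(spec: ModelSpec) -> EconResult:
    """Evaluate both arms of a model spec and compare them."""
    outcomes = {arm: evaluate_arm(arm_spec, spec.settings)
                for arm, arm_spec in spec.arms.items()}
    return econ_result(
        cost_per_arm={a: o.cost for a, o in outcomes.items()},
        qaly_per_arm={a: o.qalys for a, o in outcomes.items()},
    )
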