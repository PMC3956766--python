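"""Independent individual-level microsimulation oracle.

Samples N women one at a time through the same monthly transition rows and
accumulates the same cost and QALY components as the cohort engine, but at
the individual level with Monte Carlo sampling.  By the law of large
numbers its per-woman means converge to the cohort model's expectations, so
it serves as an independent check on the cohort propagation and accrual
arithmetic.  Deliberately written against raw transition matrices and the
ledger fields, not the engine's trace/flow machinery.
"""

from __future__ import annotations

import numpy as np

from menomark.params import ArmSpec, ModelSettings
from menomark.states import (
    CHANGE_TO_OTHER,
    INITIAL,
    NO_TREATMENT,
    ON_ALLOCATED,
    STATE_INDEX,
    STATES,
    SURGERY,
)


def microsimulate(arm_spec: ArmSpec, settings: ModelSettings, n_women: int,
                  seed: int) -> dict:
    """Mean cost/QALYs per woman with Monte Carlo standard errors."""
    rng = np.random.default_rng(seed)
    horizon = settings.horizon_cycles
    rate = settings.discount_rate_annual
    assert settings.discount_convention == "smooth"
    df = (1.0 + rate) ** (-np.arange(horizon + 1) / 12.0)

    cum_first = arm_spec.transitions.matrix(first_cycle=True).cumsum(axis=1)
    cum_rest = arm_spec.transitions.matrix(first_cycle=False).cumsum(axis=1)

    # individual paths, shape (n, horizon+1)
    paths = np.zeros((n_women, horizon + 1), dtype=np.int64)
    paths[:, 0] = STATE_INDEX[INITIAL]
    for t in range(1, horizon + 1):
        cum = cum_first if t <= settings.initial_row_cycles else cum_rest
        u = rng.random(n_women)
        paths[:, t] = (u[:, None] >= cum[paths[:, t - 1]]).sum(axis=1)

    utab = arm_spec.utilities
    u_vec = np.array([utab.values[s] for s in STATES])
    qalys = (u_vec[paths[:, 1:]] * df[1:]).sum(axis=1) / 12.0
    if settings.entry_month_accrual:
        qalys = qalys + u_vec[paths[:, 0]] / 12.0

    ledger = arm_spec.costs
    costs = np.full(n_women, ledger.entry_cost)
    i_surg = STATE_INDEX[SURGERY]
    i_change = STATE_INDEX[CHANGE_TO_OTHER]
    alloc = np.array([STATE_INDEX[s] for s in ON_ALLOCATED])
    leave = np.array([STATE_INDEX[s] for s in
                      (CHANGE_TO_OTHER, NO_TREATMENT, SURGERY)])
    for t in range(1, horizon + 1):
        prev, cur = paths[:, t - 1], paths[:, t]
        costs += df[t] * ledger.surgery_cost * (cur == i_surg)
        discont = np.isin(prev, alloc) & np.isin(cur, leave)
        costs += df[t] * ledger.discontinuation_cost * discont
        switched = (cur == i_change) & (prev != i_change)
        costs += df[t] * ledger.switch_cost * switched
    for sched in ledger.scheduled:
        idx = np.array([STATE_INDEX[s] for s in sched.states])
        present = np.isin(paths[:, sched.cycle], idx)
        costs += df[sched.cycle] * sched.amount * present
    if ledger.recurring:
        idx = np.array([STATE_INDEX[s] for s in ledger.recurring])
        amounts = np.array([ledger.recurring[s] for s in ledger.recurring])
        amount_by_state = np.zeros(len(STATES))
        amount_by_state[idx] = amounts
        cycles = (range(0, horizon) if ledger.recurring_timing == "start"
                  else range(1, horizon + 1))
        for t in cycles:
            costs += df[t] * amount_by_state[paths[:, t]]

    return {
        "qalys": float(qalys.mean()),
        "qalys_se": float(qalys.std(ddof=1) / np.sqrt(n_women)),
        "cost": float(costs.mean()),
        "cost_se": float(costs.std(ddof=1) / np.sqrt(n_women)),
        "n": n_women,
    }
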