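"""Probabilistic sensitivity analysis.

Each Monte Carlo draw jointly resamples every uncertain parameter: all
non-fixed transition rows from Dirichlet distributions with the observed
counts as concentrations, and every state utility from its Beta
distribution (surgery utilities are not sampled independently; they follow
the post-surgery draw at the fixed point-value ratio).  Costs carry no
published distributions and are held at their deterministic values.  Both
arms are evaluated on each draw; Table 2 lists separate utility rows per
arm, so utilities are drawn independently per arm even for states that
describe the same treatment.

Outputs: the per-draw cost/QALY records (the cost-effectiveness plane) and
cost-effectiveness acceptability curves (CEACs) based on net monetary
benefit, NMB(lambda) = lambda x QALYs - cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .engine import accumulate_costs, accumulate_qalys, propagate
from .params import ArmSpec, ModelSpec, UtilityTable
from .states import ARM_LNG, ARM_USUAL, ARMS
from .transitions import TransitionModel, TransitionRow

#: Default willingness-to-pay grid, GBP per QALY.
DEFAULT_LAMBDA_GRID = tuple(range(0, 50_001, 500))


@dataclass(frozen=True)
class PSADraws:
    """Per-draw economic outcomes of a probabilistic sensitivity analysis."""

    n_draws: int
    seed: int
    instrument: str
    records: pd.DataFrame  # cost_lng, cost_usual, qaly_lng, qaly_usual, ...

    def __post_init__(self) -> None:
        if len(self.records) != self.n_draws:
            raise ValueError("records length must equal n_draws")

    @property
    def plane(self) -> pd.DataFrame:
        """Cost-effectiveness plane: (draw, delta_cost, delta_qaly)."""
        return self.records[["draw", "delta_cost", "delta_qaly"]].copy()


def sample_transition_row(counts: dict[str, int],
                          rng: np.random.Generator) -> dict[str, float]:
    """One Dirichlet draw with the observed counts as concentrations."""
    dests = list(counts)
    alpha = np.array([counts[d] for d in dests], dtype=float)
    total = alpha.sum()
    if total <= 0:
        raise ValueError("cannot sample a row with zero total count")
    # zero counts are structural zeros, not Dirichlet components
    positive = alpha > 0
    draw = np.zeros(len(dests))
    draw[positive] = rng.dirichlet(alpha[positive])
    return {d: float(p) for d, p in zip(dests, draw)}


def sample_utility(alpha: float, beta: float, rng: np.random.Generator) -> float:
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    return float(rng.beta(alpha, beta))


def _sample_transitions(model: TransitionModel,
                        rng: np.random.Generator) -> TransitionModel:
    def perturb(row: TransitionRow) -> TransitionRow:
        if row.fixed or row.counts is None:
            return row
        return dc_replace(row, probs=sample_transition_row(row.counts, rng))

    first = perturb(model.first_cycle_row)
    rows = {s: perturb(r) for s, r in model.rows.items()}
    return TransitionModel(graph=model.graph, first_cycle_row=first, rows=rows)


def _sample_utilities(table: UtilityTable,
                      rng: np.random.Generator) -> UtilityTable:
    values = dict(table.values)
    for state, (a, b) in table.beta_params.items():
        values[state] = sample_utility(a, b, rng)
    for state, target in table.linked.items():
        values[state] = min(1.0, table.linked_ratio(state) * values[target])
    return dc_replace(table, values=values, beta_params={}, linked={})


def run_psa(spec: ModelSpec, n_draws: int = 1000, seed: int = 0) -> PSADraws:
    """Run ``n_draws`` joint parameter draws through both arms.

    Identical ``seed`` and spec give bit-identical draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    settings = spec.settings
    rows = []
    for i in range(n_draws):
        rec = {"draw": i}
        for arm in ARMS:
            arm_spec = spec.arm(arm)
            model = _sample_transitions(arm_spec.transitions, rng)
            utilities = _sample_utilities(arm_spec.utilities, rng)
            trace = propagate(model, settings.horizon_cycles,
                              settings.initial_row_cycles)
            qalys = accumulate_qalys(trace, utilities,
                                     settings.discount_rate_annual,
                                     settings.discount_convention,
                                     settings.entry_month_accrual)
            cost = accumulate_costs(trace, arm_spec.costs,
                                    settings.discount_rate_annual,
                                    settings.discount_convention)
            suffix = "lng" if arm == ARM_LNG else "usual"
            rec[f"cost_{suffix}"] = cost
            rec[f"qaly_{suffix}"] = qalys
        rec["delta_cost"] = rec["cost_lng"] - rec["cost_usual"]
        rec["delta_qaly"] = rec["qaly_lng"] - rec["qaly_usual"]
        rows.append(rec)
    records = pd.DataFrame(rows)
    return PSADraws(n_draws=n_draws, seed=seed, instrument=spec.instrument,
                    records=records)


def ceac(draws: PSADraws,
         lambdas=DEFAULT_LAMBDA_GRID) -> pd.DataFrame:
    """Probability each arm is cost-effective across willingness-to-pay.

    At each lambda the probability for LNG-IUS is the fraction of draws
    with positive incremental net monetary benefit; exact ties count 0.5 to
    each arm so the two curves always sum to one.
    """
    lambdas = np.asarray(list(lambdas), dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(lambdas < 0):
        raise ValueError("willingness-to-pay values must be >= 0")
    d_cost = draws.records["delta_cost"].to_numpy()
    d_qaly = draws.records["delta_qaly"].to_numpy()
    probs = []
    for lam in lambdas:
        inmb = lam * d_qaly - d_cost  # incremental NMB, LNG-IUS vs usual
        p = (np.count_nonzero(inmb > 0) + 0.5 * np.count_nonzero(inmb == 0))
        probs.append(p / len(inmb))
    probs = np.array(probs)
    return pd.DataFrame({
        "lambda": lambdas,
        "p_lng_ius": probs,
        "p_usual_medical": 1.0 - probs,
    })


def ceac_from_plane(plane: pd.DataFrame,
                    lambdas=DEFAULT_LAMBDA_GRID) -> pd.DataFrame:
    """Recompute the CEAC from exported plane points (consistency check)."""
    fake = PSADraws(
        n_draws=len(plane), seed=-1, instrument="",
        records=plane.rename(columns=str).assign(
            delta_cost=plane["delta_cost"], delta_qaly=plane["delta_qaly"]),
    )
    return ceac(fake, lambdas)
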