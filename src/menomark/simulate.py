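"""Synthetic trial generator.

Draws per-woman monthly treatment pathways from a known ("truth")
transition model and sparse questionnaire observations around known state
utilities, reproducing the structure of the real data the model was
estimated from: 24 monthly cycles, quality-of-life instruments at baseline,
6, 12 and 24 months.  With the generator's truth set to the packaged
reference tables, the estimation layer can be exercised end to end and its
parameter recovery verified.

Observation noise model: values are drawn from a Beta distribution with
mean equal to the occupied state's utility and a dispersion parameter
``d`` scaling the variance as ``d * m * (1 - m)`` (so ``d -> 0`` recovers
the state means exactly).  A questionnaire dated on a treatment-change day
reflects the month the woman has just lived through, i.e. the *prior*
state's utility; the base-case 'subsequent' assignment rule therefore
mixes a little inflow into each state's pool, which is exactly what the
coincident-date sensitivity analysis probes.
"""

from __future__ import annotations

import numpy as np

from .estimation import OBSERVATION_MONTHS, Observation, WomanPathway
from .params import UtilityTable
from .states import N_STATES, STATES, STATE_INDEX, INITIAL
from .transitions import TransitionModel

#: Default per-arm sample size, matching the scale of the randomised trial
#: the model derives from (571 women across both arms).
DEFAULT_N_WOMEN = 285

#: Default observation-noise dispersion: variance = d * m * (1-m).  With
#: utilities around 0.75 this gives an individual-level SD of roughly 0.09,
#: a realistic between-woman spread for preference-based instruments.
DEFAULT_DISPERSION = 0.04


def simulate_state_paths(truth: TransitionModel, n_women: int, seed: int,
                         horizon_cycles: int = 24,
                         initial_row_cycles: int = 1) -> np.ndarray:
    """Vectorised state sequences: integer array of shape (n_women, h+1)."""
    if n_women < 1:
        raise ValueError("n_women must be >= 1")
    rng = np.random.default_rng(seed)
    cum_first = truth.matrix(first_cycle=True).cumsum(axis=1)
    cum_rest = truth.matrix(first_cycle=False).cumsum(axis=1)
    paths = np.zeros((n_women, horizon_cycles + 1), dtype=np.int8)
    paths[:, 0] = STATE_INDEX[INITIAL]
    for t in range(1, horizon_cycles + 1):
        cum = cum_first if t <= initial_row_cycles else cum_rest
        u = rng.random(n_women)
        rows = cum[paths[:, t - 1]]
        paths[:, t] = (u[:, None] >= rows).sum(axis=1)
    return paths


def simulate_pathways(truth: TransitionModel, n_women: int, seed: int,
                      horizon_cycles: int = 24, start_id: int = 0,
                      initial_row_cycles: int = 1) -> list[WomanPathway]:
    """Draw ``n_women`` monthly pathways from the truth model."""
    paths = simulate_state_paths(truth, n_women, seed, horizon_cycles,
                                 initial_row_cycles)
    return [
        WomanPathway(
            woman_id=start_id + i,
            arm=truth.arm,
            monthly_state=tuple(STATES[j] for j in paths[i]),
        )
        for i in range(n_women)
    ]


def simulate_observations(
    pathways: list[WomanPathway],
    truth_utilities: UtilityTable,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    schedule: tuple[int, ...] = OBSERVATION_MONTHS,
    missing_rate: float = 0.0,
) -> list[WomanPathway]:
    """Attach questionnaire observations drawn around the truth utilities.

    Returns new pathway objects; the inputs are not modified.  With
    ``missing_rate`` > 0 each scheduled observation is independently
    dropped with that probability (missing completely at random).
    """
    if not 0.0 <= dispersion < 1.0:
        raise ValueError("dispersion must be in [0, 1)")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    instrument = truth_utilities.instrument
    out = []
    for p in pathways:
        changes = set(p.change_dates)
        obs = []
        for month in schedule:
            if month >= len(p.monthly_state):
                raise ValueError(f"observation month {month} beyond horizon")
            if missing_rate and rng.random() < missing_rate:
                continue
            # the value reflects the month just lived: the prior state on
            # change days, the current state otherwise
            state = p.monthly_state[month]
            if month in changes:
                state = p.monthly_state[month - 1]
            mean = truth_utilities.value(state)
            if dispersion == 0.0:
                value = mean
            else:
                kappa = 1.0 / dispersion - 1.0
                value = float(rng.beta(mean * kappa, (1.0 - mean) * kappa))
            obs.append(Observation(month=month, instrument=instrument,
                                   value=value))
        out.append(WomanPathway(woman_id=p.woman_id, arm=p.arm,
                                monthly_state=p.monthly_state,
                                observations=p.observations + tuple(obs)))
    return out
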