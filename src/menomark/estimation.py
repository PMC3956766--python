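"""Estimate model parameters from per-woman pathway data.

The model's transition counts and state utilities are both derivable from
trial-like data: a monthly state sequence per woman, and sparse
quality-of-life questionnaires at baseline, 6, 12 and 24 months.

Utility assignment rule: each post-baseline questionnaire is assigned to
the state occupied at its timepoint.  When the questionnaire date coincides
with a treatment-change date the base case assigns it to the *subsequent*
(new) state; the 'prior' rule (sensitivity analysis) assigns it to the old
state.  Baseline questionnaires precede randomised treatment and are never
assigned to a model state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median as _median

import numpy as np
import pandas as pd

from .params import INSTRUMENT_RANGE, UtilityTable
from .states import (
    ABSORBING,
    ALLOWED_EDGES,
    ARMS,
    HealthStateGraph,
    INITIAL,
    STATES,
)

OBSERVATION_MONTHS = (0, 6, 12, 24)


@dataclass(frozen=True)
class Observation:
    month: int
    instrument: str
    value: float


@dataclass(frozen=True)
class WomanPathway:
    """One woman's monthly state sequence and questionnaire observations.

    ``monthly_state[m]`` is the state occupied at month ``m`` (0..horizon),
    with ``monthly_state[0]`` the initial allocated-treatment state.
    """

    woman_id: int
    arm: str
    monthly_state: tuple[str, ...]
    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.monthly_state[0] != INITIAL:
            raise ValueError(
                f"woman {self.woman_id}: pathway must start in {INITIAL!r}")
        for m in range(1, len(self.monthly_state)):
            src, dst = self.monthly_state[m - 1], self.monthly_state[m]
            allowed = ALLOWED_EDGES[src]
            if dst not in allowed:
                raise ValueError(
                    f"woman {self.woman_id}, cycle {m}: move "
                    f"{src!r} -> {dst!r} violates the pathway constraints")
        horizon = len(self.monthly_state) - 1
        seen: set[tuple[str, int]] = set()
        for obs in self.observations:
            if obs.month > horizon:
                raise ValueError(
                    f"woman {self.woman_id}: observation at month {obs.month} "
                    f"beyond pathway horizon {horizon}")
            key = (obs.instrument, obs.month)
            if key in seen:
                raise ValueError(
                    f"woman {self.woman_id}: duplicate {obs.instrument} "
                    f"observation at month {obs.month}")
            seen.add(key)
            lo, hi = INSTRUMENT_RANGE.get(obs.instrument, (-1.0, 1.0))
            if not lo <= obs.value <= hi:
                raise ValueError(
                    f"woman {self.woman_id}: {obs.instrument} value "
                    f"{obs.value} outside [{lo}, {hi}]")

    @property
    def change_dates(self) -> tuple[int, ...]:
        """Months at which the occupied state changed."""
        return tuple(
            m for m in range(1, len(self.monthly_state))
            if self.monthly_state[m] != self.monthly_state[m - 1]
        )


@dataclass(frozen=True)
class Assignment:
    woman_id: int
    arm: str
    state: str
    instrument: str
    month: int
    value: float


def assign_observations_to_states(
    pathway: WomanPathway, coincident_rule: str = "subsequent"
) -> list[Assignment]:
    """Map each post-baseline observation to a model state.

    'subsequent' (base case) assigns an observation dated on a change day
    to the newly entered state; 'prior' assigns it to the state just left.
    Baseline (month 0) observations are excluded.
    """
    if coincident_rule not in ("subsequent", "prior"):
        raise ValueError(f"unknown coincident_rule {coincident_rule!r}")
    out = []
    changes = set(pathway.change_dates)
    for obs in pathway.observations:
        if obs.month == 0:
            continue
        state = pathway.monthly_state[obs.month]
        if coincident_rule == "prior" and obs.month in changes:
            state = pathway.monthly_state[obs.month - 1]
        out.append(Assignment(pathway.woman_id, pathway.arm, state,
                              obs.instrument, obs.month, obs.value))
    return out


def _fit_beta_moments(values: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit; wide Beta(1,1) fallback when degenerate."""
    m = float(values.mean())
    v = float(values.var(ddof=1)) if len(values) > 1 else 0.0
    if not 0.0 < m < 1.0 or v <= 0.0 or v >= m * (1.0 - m):
        warnings.warn("degenerate sample for Beta fit; using Beta(1, 1)",
                      stacklevel=2)
        return (1.0, 1.0)
    kappa = m * (1.0 - m) / v - 1.0
    return (m * kappa, (1.0 - m) * kappa)


def estimate_utilities(
    assignments: list[Assignment],
    instrument: str,
    arm: str,
    per_woman: bool = False,
) -> UtilityTable:
    """Per-state mean (and median) utilities from assigned observations.

    ``per_woman=True`` first averages within each woman, then across women
    (the default weights every observation equally).  States with no
    observations are flagged with a warning and left out of the table.
    """
    rows = [a for a in assignments
            if a.instrument == instrument and a.arm == arm]
    values: dict[str, float] = {}
    medians: dict[str, float] = {}
    betas: dict[str, tuple[float, float]] = {}
    for state in STATES:
        sample = [a for a in rows if a.state == state]
        if not sample:
            continue
        if per_woman:
            by_woman: dict[int, list[float]] = {}
            for a in sample:
                by_woman.setdefault(a.woman_id, []).append(a.value)
            vals = np.array([float(np.mean(v)) for v in by_woman.values()])
        else:
            vals = np.array([a.value for a in sample])
        values[state] = float(vals.mean())
        medians[state] = float(_median(vals.tolist()))
        betas[state] = _fit_beta_moments(vals)
    missing = [s for s in STATES if s not in values]
    if missing:
        warnings.warn(f"no {instrument} observations for states {missing} "
                      f"in arm {arm!r}", stacklevel=2)
    return UtilityTable(instrument=instrument, arm=arm, values=values,
                        beta_params=betas, medians=medians or None)


def estimate_transition_counts(
    pathways: list[WomanPathway],
) -> dict[str, dict]:
    """Count observed month-to-month moves, pooled per model row.

    Returns, per arm, the first-cycle destination counts (from each woman's
    first transition only) and per-source count vectors for all later
    cycles.  Pathways that violate the graph constraints raise at
    :class:`WomanPathway` construction; an empty input yields all-zero
    counts with a warning.
    """
    out = {arm: {"first_cycle": {}, "rows": {}} for arm in ARMS}
    if not pathways:
        warnings.warn("no pathways supplied; returning all-zero counts",
                      stacklevel=2)
        return out
    for p in pathways:
        counts = out[p.arm]
        first_dest = p.monthly_state[1]
        counts["first_cycle"][first_dest] = (
            counts["first_cycle"].get(first_dest, 0) + 1)
        for m in range(2, len(p.monthly_state)):
            src, dst = p.monthly_state[m - 1], p.monthly_state[m]
            row = counts["rows"].setdefault(src, {})
            row[dst] = row.get(dst, 0) + 1
    return out


def counts_to_row_specs(arm_counts: dict, drop_absorbing: bool = True) -> dict:
    """Convert estimated counts into transition-model row specifications.

    Structurally fixed rows (absorbing states and the one-cycle surgery
    dwell) are emitted as fixed probability vectors, matching how the
    reference tables encode them.
    """
    specs: dict[str, dict] = {}
    for state in STATES:
        if state == INITIAL:
            continue
        if drop_absorbing and state in ABSORBING:
            specs[state] = {"fixed": {state: 1.0}}
        elif state == "surgery":
            specs[state] = {"fixed": {"post_surgery": 1.0}}
        else:
            row = arm_counts["rows"].get(state)
            if row:
                specs[state] = {"counts": dict(row)}
            else:
                # unvisited transient state: formally self-loops
                specs[state] = {"fixed": {state: 1.0}}
    return specs


# ---------------------------------------------------------------------------
# Delimited-table interchange (one row per woman-cycle / per observation)


def pathways_to_frames(
    pathways: list[WomanPathway],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export pathways as (states, observations) tidy tables."""
    srows = [(p.woman_id, p.arm, m, s)
             for p in pathways for m, s in enumerate(p.monthly_state)]
    orows = [(p.woman_id, o.month, o.instrument, o.value)
             for p in pathways for o in p.observations]
    states = pd.DataFrame(srows, columns=["woman_id", "arm", "cycle", "state"])
    obs = pd.DataFrame(orows, columns=["woman_id", "timepoint", "instrument",
                                       "value"])
    return states, obs


def frames_to_pathways(
    states: pd.DataFrame, observations: pd.DataFrame | None = None
) -> list[WomanPathway]:
    obs_by_woman: dict[int, list[Observation]] = {}
    if observations is not None and len(observations):
        for row in observations.itertuples(index=False):
            obs_by_woman.setdefault(int(row.woman_id), []).append(
                Observation(int(row.timepoint), str(row.instrument),
                            float(row.value)))
    pathways = []
    for (woman_id, arm), grp in states.groupby(["woman_id", "arm"], sort=True):
        grp = grp.sort_values("cycle")
        pathways.append(WomanPathway(
            woman_id=int(woman_id), arm=str(arm),
            monthly_state=tuple(grp["state"]),
            observations=tuple(obs_by_woman.get(int(woman_id), ())),
        ))
    return pathways
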