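"""Deterministic sensitivity analyses as pure transforms of a model spec.

* **SA1** — replace mean state utilities by medians.
* **SA2** — national costing-template staffing: nurse-led 10-minute initial
  consultation and insertion, 6-week nurse review only in the LNG-IUS arm,
  annual follow-up in both arms.
* **SA3** — questionnaires dated on a treatment-change day are assigned to
  the state *prior* to the change instead of the new state.
* **SA4** — swap the EQ-5D utility tables for SF-6D; costs untouched.

Each transform takes a :class:`~menomark.params.ModelSpec` and returns a
new one built from an edited copy of its configuration, so transforms are
idempotent and commute whenever they touch disjoint parts of the spec.
"""

from __future__ import annotations

import copy

import numpy as np

from .engine import propagate
from .estimation import (
    OBSERVATION_MONTHS,
    WomanPathway,
    assign_observations_to_states,
    estimate_utilities,
)
from .params import ModelSpec, from_config
from .states import (
    ARMS,
    CHANGE_TO_OTHER,
    INITIAL,
    N_STATES,
    POST_SURGERY,
    STATE_INDEX,
    STATES,
    SURGERY,
    SYMPTOMATIC,
    WELL_ALLOCATED,
    WELL_WITH_OTHER,
)

#: States counted as "on a treatment" for the SA2 annual follow-up.
_ON_TREATMENT = (WELL_ALLOCATED, SYMPTOMATIC, CHANGE_TO_OTHER, WELL_WITH_OTHER)


def _utility_cfg(spec: ModelSpec, cfg: dict, arm: str) -> dict:
    return cfg["utilities"][spec.instrument][arm]


def apply_sa1_median_utilities(spec: ModelSpec) -> ModelSpec:
    """SA1: medians replace mean state utilities; all else unchanged."""
    cfg = copy.deepcopy(spec.config)
    for arm in ARMS:
        table = spec.arm(arm).utilities
        entries = _utility_cfg(spec, cfg, arm)
        for state in STATES:
            if state in table.linked:
                # keep the linked ratio: scale by the linked target's change
                continue
            if table.medians is None or state not in table.medians:
                raise ValueError(
                    f"SA1 requires a median utility for every state; "
                    f"missing {state!r} in arm {arm!r}")
            entries[state]["value"] = float(table.medians[state])
            entries[state].pop("use_beta_mean", None)
        # re-link surgery to the new post-surgery value, preserving ratio
        for state, target in table.linked.items():
            ratio = table.linked_ratio(state)
            entries[state]["value"] = min(1.0, ratio * entries[target]["value"])
    return from_config(cfg, instrument=spec.instrument)


def apply_sa2_nice_costing(spec: ModelSpec, reading: str = "replace") -> ModelSpec:
    """SA2: costing-template staffing and follow-up schedule.

    ``reading='replace'`` (default) takes the template text literally: a
    practice nurse, 10 minutes, carries out both the initial consultation
    and the device insertion.  ``reading='additive'`` keeps a GP present
    alongside the nurse at 10 minutes each.  Both add a 6-week nurse review
    (LNG-IUS arm) and annual follow-up GP appointments at months 12 and 24
    for women still on any treatment.
    """
    if reading not in ("replace", "additive"):
        raise ValueError(f"unknown SA2 reading {reading!r}")
    cfg = copy.deepcopy(spec.config)
    costs = cfg["costs"]
    staff = costs["staff"]
    nurse, gp = float(staff["nurse_10min"]), float(staff["gp_10min"])
    consult = nurse if reading == "replace" else gp + nurse
    lng, usual = costs["lng_ius"], costs["usual_medical"]

    lng["consultation"] = consult
    usual["consultation"] = consult
    insertion = lng["insertion"]
    for key in ("gp_20min", "nurse_20min", "gp_10min", "nurse_10min"):
        insertion.pop(key, None)
    insertion["staff"] = nurse if reading == "replace" else gp + nurse

    def _with_annual_followup(reviews: list, six_week_nurse: bool) -> list:
        out = []
        for r in reviews:
            r = dict(r)
            if six_week_nurse and r.get("label") == "six_week_review":
                r["cost"] = nurse
            if r.get("label") == "annual_follow_up":
                continue  # idempotence: re-added below
            out.append(r)
        for cycle in (12, 24):
            out.append({"cycle": cycle, "cost": gp, "states": list(_ON_TREATMENT),
                        "label": "annual_follow_up"})
        return out

    lng["reviews"] = _with_annual_followup(lng.get("reviews", []),
                                           six_week_nurse=True)
    usual["reviews"] = _with_annual_followup(usual.get("reviews", []),
                                             six_week_nurse=False)
    return from_config(cfg, instrument=spec.instrument)


def apply_sa4_sf6d(spec: ModelSpec) -> ModelSpec:
    """SA4: SF-6D utilities instead of EQ-5D; costs bit-identical."""
    return spec.with_instrument("sf6d")


# ---------------------------------------------------------------------------
# SA3: coincident-date assignment rule


def sa3_utility_values(spec: ModelSpec, arm: str) -> dict[str, float]:
    """Closed-form large-sample utilities under the 'prior' assignment rule.

    The packaged point utilities are subsequent-rule estimates: on a change
    day the questionnaire reflects the month just lived (the prior state),
    so each state's subsequent-rule mean at the observation months mixes in
    its inflows' utilities.  Writing ``v[s]`` for the subsequent-rule mean
    and ``u[s]`` for the clean (prior-rule) mean,

        v[s] = ( sum_m stay(m, s) u[s] + sum_m sum_{s'} flow(m, s'->s) u[s'] )
               / sum_m occ(m, s)

    over observation months m, which is a linear system solved here for
    ``u``.  Surgery has a one-cycle dwell (no stayers at any observation
    month), so its equation is replaced by the table's own linkage: the
    surgery utility keeps its fixed ratio to post-surgery.
    """
    arm_spec = spec.arm(arm)
    model = arm_spec.transitions
    table = arm_spec.utilities
    settings = spec.settings
    months = [m for m in OBSERVATION_MONTHS
              if 0 < m <= settings.horizon_cycles]
    trace = propagate(model, settings.horizon_cycles,
                      settings.initial_row_cycles)
    occ = trace.occupancy
    v = np.array([table.values[s] for s in STATES])
    A = np.zeros((N_STATES, N_STATES))
    b = v.copy()
    i_surg = STATE_INDEX[SURGERY]
    for s in range(N_STATES):
        total = sum(occ[m][s] for m in months)
        if total <= 1e-12 or s == i_surg:
            A[s, s] = 1.0
            continue
        for m in months:
            F = trace.flows[m - 1]
            inflow = F[:, s].copy()
            inflow[s] = 0.0
            stay = occ[m][s] - inflow.sum()
            A[s, s] += stay / total
            A[s, :] += inflow / total
    # linkage equation: u[surgery] = ratio * u[post_surgery]
    A[i_surg, :] = 0.0
    A[i_surg, i_surg] = 1.0
    A[i_surg, STATE_INDEX[POST_SURGERY]] = -table.linked_ratio(SURGERY)
    b[i_surg] = 0.0
    u = np.linalg.solve(A, b)
    return {state: float(np.clip(u[i], 1e-9, 1.0))
            for i, state in enumerate(STATES)}


def apply_sa3_assignment_rule(
    spec: ModelSpec,
    pathways: list[WomanPathway] | None = None,
) -> ModelSpec:
    """SA3: utilities re-derived under the 'prior' coincident-date rule.

    With ``pathways`` given, both rules are estimated from the data and the
    paired difference (same observations, only coincident ones reassigned)
    is applied to the spec's utilities.  Without data, the closed-form
    large-sample adjustment of :func:`sa3_utility_values` is used; the two
    agree as the number of women grows.
    """
    if spec.settings.coincident_rule == "prior":
        return spec  # already under the prior rule; idempotent
    cfg = copy.deepcopy(spec.config)
    cfg.setdefault("settings", {})["coincident_rule"] = "prior"
    for arm in ARMS:
        entries = _utility_cfg(spec, cfg, arm)
        if pathways is None:
            new_values = sa3_utility_values(spec, arm)
            for state in STATES:
                entries[state]["value"] = new_values[state]
                entries[state].pop("use_beta_mean", None)
        else:
            arm_paths = [p for p in pathways if p.arm == arm]
            subs, prior = [], []
            for p in arm_paths:
                subs.extend(assign_observations_to_states(p, "subsequent"))
                prior.extend(assign_observations_to_states(p, "prior"))
            t_subs = estimate_utilities(subs, spec.instrument, arm)
            t_prior = estimate_utilities(prior, spec.instrument, arm)
            table = spec.arm(arm).utilities
            for state in STATES:
                if state in table.linked:
                    continue
                shift = (t_prior.values.get(state, table.values[state])
                         - t_subs.values.get(state, table.values[state]))
                entries[state]["value"] = float(
                    np.clip(table.values[state] + shift, 1e-9, 1.0))
                entries[state].pop("use_beta_mean", None)
            for state, target in table.linked.items():
                ratio = table.linked_ratio(state)
                entries[state]["value"] = min(
                    1.0, ratio * entries[target]["value"])
    return from_config(cfg, instrument=spec.instrument)
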