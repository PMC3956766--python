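"""Model parameterisation: utilities, costs, settings and the packaged tables.

The packaged reference configuration carries the published parameter tables
for the two-arm menorrhagia treatment model: the cost ledger (2011 GBP, UK
NHS perspective), per-state annual utilities for both the EQ-5D and SF-6D
instruments with their Beta PSA parameters, and the monthly transition
probabilities with their Dirichlet count parameters.

A :class:`ModelSpec` bundles everything one deterministic run needs.  It is
built from a plain configuration dictionary (YAML on disk), so sensitivity
analyses can be expressed as pure transforms of that dictionary.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any

import yaml

from .states import (
    ARMS,
    ARM_LNG,
    ARM_USUAL,
    CHANGE_TO_OTHER,
    HealthStateGraph,
    INITIAL,
    ON_ALLOCATED,
    ON_OTHER,
    POST_SURGERY,
    STATES,
    SURGERY,
    SYMPTOMATIC,
    WELL_ALLOCATED,
    WELL_WITH_OTHER,
)
from .transitions import TransitionModel, build_transition_model

INSTRUMENTS = ("eq5d", "sf6d")

#: Utility instrument value ranges (used for validation of observations).
INSTRUMENT_RANGE = {"eq5d": (-0.594, 1.0), "sf6d": (0.29, 1.0)}


@dataclass(frozen=True)
class UtilityTable:
    """Per-state annual health-state utilities for one arm and instrument.

    ``values`` are the deterministic (point) utilities.  ``beta_params``
    holds (alpha, beta) for states perturbed in PSA.  States listed in
    ``linked`` have no independent distribution: their PSA draw is the
    linked state's draw scaled by the ratio of the point values.
    """

    instrument: str
    arm: str
    values: dict[str, float]
    beta_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    medians: dict[str, float] | None = None
    linked: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for state, u in self.values.items():
            if not 0.0 < u <= 1.0:
                raise ValueError(f"utility for {state!r} is {u}, outside (0, 1]")
        for state, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {state!r} must be positive")
        for state, target in self.linked.items():
            if state in self.beta_params:
                raise ValueError(f"{state!r} is linked to {target!r} but has own Beta")

    def value(self, state: str) -> float:
        if state not in self.values:
            raise KeyError(f"no utility value for state {state!r}")
        return self.values[state]

    def linked_ratio(self, state: str) -> float:
        """Point-value ratio used to derive a linked state's PSA draw."""
        target = self.linked[state]
        return self.values[state] / self.values[target]


@dataclass(frozen=True)
class ScheduledCost:
    cycle: int
    states: tuple[str, ...]
    amount: float
    label: str = ""


@dataclass(frozen=True)
class CostLedger:
    """One arm's cost structure (money in GBP, 2011 prices).

    * ``entry_cost`` — charged once at model entry to the whole cohort
      (initial consultation, plus the device insertion bundle in the
      LNG-IUS arm).
    * ``discontinuation_cost`` — per unit of flow out of the allocated
      treatment into change / no-treatment / surgery.
    * ``surgery_cost`` — per unit of inflow into the surgery state.
    * ``switch_cost`` — per unit of inflow into the change-to-other state
      (initiation costs of the *other* treatment).
    * ``scheduled`` — review appointments at fixed cycles, charged to
      occupancy of the listed states.
    * ``recurring`` — per-cycle costs by state (repeat prescriptions while
      on a medical treatment), charged to start-of-cycle occupancy by
      default (drugs are dispensed for the month ahead).
    """

    entry_cost: float
    discontinuation_cost: float
    surgery_cost: float
    switch_cost: float
    scheduled: tuple[ScheduledCost, ...] = ()
    recurring: dict[str, float] = field(default_factory=dict)
    recurring_timing: str = "start"

    def __post_init__(self) -> None:
        amounts = [self.entry_cost, self.discontinuation_cost, self.surgery_cost,
                   self.switch_cost, *(s.amount for s in self.scheduled),
                   *self.recurring.values()]
        if any(a < 0 for a in amounts):
            raise ValueError("monetary amounts must be non-negative")
        if self.recurring_timing not in ("start", "end"):
            raise ValueError("recurring_timing must be 'start' or 'end'")


@dataclass(frozen=True)
class ModelSettings:
    """Structural and numerical conventions of a run.

    The published description leaves several conventions open; each is a
    named switch here so alternative readings stay reproducible.
    """

    horizon_cycles: int = 24
    discount_rate_annual: float = 0.035
    #: 'smooth' = (1+r)^(-t/12) per monthly cycle; 'annual-step' = year
    #: blocks (year 1 undiscounted).
    discount_convention: str = "smooth"
    #: Accrue one month of the initial state's utility at model entry in
    #: addition to the 24 end-of-cycle accruals.
    entry_month_accrual: bool = True
    #: Number of cycles the dedicated first-cycle row is applied.
    initial_row_cycles: int = 1
    #: Questionnaire dated on a treatment-change day belongs to the
    #: 'subsequent' (new) or 'prior' (old) state.
    coincident_rule: str = "subsequent"

    def __post_init__(self) -> None:
        if self.discount_convention not in ("smooth", "annual-step"):
            raise ValueError("discount_convention must be 'smooth' or 'annual-step'")
        if self.coincident_rule not in ("subsequent", "prior"):
            raise ValueError("coincident_rule must be 'subsequent' or 'prior'")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.initial_row_cycles < 1:
            raise ValueError("initial_row_cycles must be >= 1")


@dataclass(frozen=True)
class ArmSpec:
    transitions: TransitionModel
    utilities: UtilityTable
    costs: CostLedger

    @property
    def arm(self) -> str:
        return self.transitions.arm


@dataclass(frozen=True)
class ModelSpec:
    """Everything a deterministic two-arm evaluation needs."""

    instrument: str
    arms: dict[str, ArmSpec]
    settings: ModelSettings
    config: dict[str, Any] = field(default_factory=dict, repr=False)

    def arm(self, arm: str) -> ArmSpec:
        return self.arms[arm]

    def with_settings(self, **changes) -> "ModelSpec":
        cfg = copy.deepcopy(self.config)
        cfg.setdefault("settings", {}).update(changes)
        return from_config(cfg, instrument=self.instrument)

    def with_instrument(self, instrument: str) -> "ModelSpec":
        return from_config(copy.deepcopy(self.config), instrument=instrument)


# ---------------------------------------------------------------------------
# Construction from configuration dictionaries


def _require(cfg: dict, key: str, where: str) -> Any:
    if key not in cfg:
        raise KeyError(f"missing configuration key {key!r} in {where}")
    return cfg[key]


def _build_utilities(cfg: dict, instrument: str, arm: str) -> UtilityTable:
    table = _require(_require(cfg, "utilities", "config"), instrument, "utilities")
    entries = _require(table, arm, f"utilities.{instrument}")
    values, betas, medians, linked = {}, {}, {}, {}
    for state in STATES:
        entry = _require(entries, state, f"utilities.{instrument}.{arm}")
        if "linked_to" in entry:
            linked[state] = entry["linked_to"]
            values[state] = float(entry["value"])
            continue
        beta = entry.get("beta")
        if beta is not None:
            a, b = float(beta[0]), float(beta[1])
            betas[state] = (a, b)
            # Where flagged, the printed point value is superseded by the
            # Beta mean (used when print and distribution disagree).
            values[state] = a / (a + b) if entry.get("use_beta_mean") else float(entry["value"])
        else:
            values[state] = float(entry["value"])
        if "median" in entry:
            medians[state] = float(entry["median"])
    return UtilityTable(
        instrument=instrument,
        arm=arm,
        values=values,
        beta_params=betas,
        medians=medians or None,
        linked=linked,
    )


def _drug_price_per_cycle(costs: dict) -> float:
    usual = _require(costs, "usual_medical", "costs")
    drugs = _require(usual, "drugs", "costs.usual_medical")
    weights = usual.get("drug_weights", "equal")
    if weights == "equal":
        weights = {name: 1.0 for name in drugs}
    total_w = sum(weights.values())
    pack = sum(weights[name] * float(price) for name, price in drugs.items()) / total_w
    months = float(usual.get("months_per_pack", 1))
    return pack / months


def _build_ledger(cfg: dict, arm: str, horizon: int) -> CostLedger:
    costs = _require(cfg, "costs", "config")
    lng, usual = costs["lng_ius"], costs["usual_medical"]
    surgery_cost = float(_require(costs, "surgery", "costs"))
    presc = _drug_price_per_cycle(costs)
    presc_timing = costs.get("prescription_timing", "start")

    def bundle(d: dict) -> float:
        return float(sum(d.values()))

    lng_entry = float(lng["consultation"]) + bundle(lng["insertion"])
    usual_entry = float(usual["consultation"])

    if arm == ARM_LNG:
        entry = lng_entry
        discontinuation = bundle(lng["discontinuation"])
        switch = usual_entry  # switching to usual medical treatment
        recurring = {CHANGE_TO_OTHER: presc, WELL_WITH_OTHER: presc}
        reviews = lng.get("reviews", [])
    else:
        entry = usual_entry
        discontinuation = bundle(usual["discontinuation"])
        switch = lng_entry  # switching to LNG-IUS: full insertion bundle
        recurring = {s: presc for s in ON_ALLOCATED}
        reviews = usual.get("reviews", [])

    scheduled = []
    for r in reviews:
        cycle = int(r["cycle"])
        if cycle > horizon:
            raise ValueError(f"scheduled cost {r.get('label', '')!r} at cycle "
                             f"{cycle} beyond horizon {horizon}")
        states = tuple(r.get("states", ON_ALLOCATED))
        scheduled.append(ScheduledCost(cycle=cycle, states=states,
                                       amount=float(r["cost"]),
                                       label=str(r.get("label", ""))))
    return CostLedger(
        entry_cost=entry,
        discontinuation_cost=discontinuation,
        surgery_cost=surgery_cost,
        switch_cost=switch,
        scheduled=tuple(scheduled),
        recurring=recurring,
        recurring_timing=presc_timing,
    )


def _build_transitions(cfg: dict, arm: str) -> TransitionModel:
    trans = _require(_require(cfg, "transitions", "config"), arm, "transitions")
    graph = HealthStateGraph(arm=arm)
    first = _require(trans, "first_cycle", f"transitions.{arm}")
    rows = _require(trans, "rows", f"transitions.{arm}")
    return build_transition_model(graph, dict(first["counts"]), rows)


def from_config(config: dict, instrument: str = "eq5d") -> ModelSpec:
    """Build a :class:`ModelSpec` from a configuration dictionary."""
    if instrument not in INSTRUMENTS:
        raise ValueError(f"unknown instrument {instrument!r}")
    settings = ModelSettings(**config.get("settings", {}))
    arms = {}
    for arm in ARMS:
        arms[arm] = ArmSpec(
            transitions=_build_transitions(config, arm),
            utilities=_build_utilities(config, instrument, arm),
            costs=_build_ledger(config, arm, settings.horizon_cycles),
        )
    return ModelSpec(instrument=instrument, arms=arms, settings=settings,
                     config=config)


def load_config(path=None) -> dict:
    """Load a YAML configuration; packaged reference tables by default."""
    if path is None:
        ref = resources.files("menomark.data").joinpath("reference_parameters.yaml")
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_reference_spec(instrument: str = "eq5d") -> ModelSpec:
    """The packaged reference model (published tables, default conventions)."""
    return from_config(load_config(), instrument=instrument)
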