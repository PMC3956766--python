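"""Health-state space for the treatment-pathway Markov model.

Both randomised arms (LNG-IUS and usual medical treatment) share one state
template.  "Allocated" refers to the treatment the woman was randomised to;
"other" resolves to the opposite treatment for each arm: in the LNG-IUS arm
``CHANGE_TO_OTHER`` means a change to usual medical treatment, and in the
usual-medical arm it means a change to LNG-IUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Canonical state order; occupancy vectors and transition matrices follow it.
INITIAL = "initial"
WELL_ALLOCATED = "well_allocated"
SYMPTOMATIC = "symptomatic"
CHANGE_TO_OTHER = "change_to_other"
WELL_WITH_OTHER = "well_with_other"
NO_TREATMENT = "no_treatment"
SURGERY = "surgery"
POST_SURGERY = "post_surgery"

STATES: tuple[str, ...] = (
    INITIAL,
    WELL_ALLOCATED,
    SYMPTOMATIC,
    CHANGE_TO_OTHER,
    WELL_WITH_OTHER,
    NO_TREATMENT,
    SURGERY,
    POST_SURGERY,
)
STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

ABSORBING: frozenset[str] = frozenset({WELL_ALLOCATED, WELL_WITH_OTHER, POST_SURGERY})

#: States in which the woman is still on her randomised treatment.
ON_ALLOCATED: tuple[str, ...] = (INITIAL, WELL_ALLOCATED, SYMPTOMATIC)

#: States in which the woman is on the alternative ("other") treatment.
ON_OTHER: tuple[str, ...] = (CHANGE_TO_OTHER, WELL_WITH_OTHER)

#: States reached by leaving the allocated treatment.
OFF_ALLOCATED: tuple[str, ...] = (
    CHANGE_TO_OTHER,
    WELL_WITH_OTHER,
    NO_TREATMENT,
    SURGERY,
    POST_SURGERY,
)

# Structural edge constraints.  Once off the allocated treatment a woman can
# never return to it; a woman who is well cannot spontaneously become
# symptomatic; a change to the other treatment requires at least one full
# cycle in the change state before "well with other"; surgery lasts exactly
# one cycle and leads to the absorbing post-surgery state.
ALLOWED_EDGES: dict[str, frozenset[str]] = {
    INITIAL: frozenset({WELL_ALLOCATED, SYMPTOMATIC, CHANGE_TO_OTHER, NO_TREATMENT}),
    WELL_ALLOCATED: frozenset({WELL_ALLOCATED}),
    SYMPTOMATIC: frozenset({SYMPTOMATIC, CHANGE_TO_OTHER, NO_TREATMENT, SURGERY}),
    CHANGE_TO_OTHER: frozenset(
        {CHANGE_TO_OTHER, WELL_WITH_OTHER, NO_TREATMENT, SURGERY}
    ),
    WELL_WITH_OTHER: frozenset({WELL_WITH_OTHER}),
    NO_TREATMENT: frozenset({CHANGE_TO_OTHER, NO_TREATMENT, SURGERY}),
    SURGERY: frozenset({POST_SURGERY}),
    POST_SURGERY: frozenset({POST_SURGERY}),
}

ARM_LNG = "lng_ius"
ARM_USUAL = "usual_medical"
ARMS: tuple[str, str] = (ARM_LNG, ARM_USUAL)

ARM_LABELS = {ARM_LNG: "LNG-IUS", ARM_USUAL: "Usual medical treatment"}


@dataclass(frozen=True)
class HealthStateGraph:
    """Per-arm pathway state space with its structural constraints.

    Parameters
    ----------
    arm:
        ``"lng_ius"`` or ``"usual_medical"``.  The state template is shared;
        the arm label resolves what "allocated" and "other" mean.
    """

    arm: str
    states: tuple[str, ...] = STATES
    absorbing: frozenset[str] = ABSORBING
    initial: str = INITIAL
    allowed_edges: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(ALLOWED_EDGES)
    )

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")

    def index(self, state: str) -> int:
        return STATE_INDEX[state]

    def is_allowed(self, source: str, dest: str) -> bool:
        return dest in self.allowed_edges[source]

    @property
    def other_arm(self) -> str:
        return ARM_USUAL if self.arm == ARM_LNG else ARM_LNG
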