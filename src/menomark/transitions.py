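"""Monthly transition probabilities and their Dirichlet count parameters.

Each arm's model has one probability row per source state.  Rows come in two
flavours:

* **fixed** rows — structural certainties (absorbing states, the one-cycle
  surgery dwell, the impossibility of returning from symptomatic to well).
  They carry no counts and are never perturbed in probabilistic sensitivity
  analysis.
* **count** rows — estimated from observed month-to-month moves.  The
  deterministic probability is ``count / row total`` and the counts double as
  the Dirichlet concentration parameters for PSA.

A row may additionally carry a ``printed`` override: a probability vector to
use deterministically in place of the count-derived one (used where a source
table's printed probabilities and counts disagree; PSA still uses counts).

The model distinguishes the first cycle from all later cycles: the initial
state has no "remain" probability, so its row is applied once (by default) as
the transition out of the initial state, after which the stationary matrix
governs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import HealthStateGraph, INITIAL, N_STATES, STATE_INDEX, STATES

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class TransitionRow:
    """One source state's destination distribution."""

    source: str
    probs: dict[str, float]
    counts: dict[str, int] | None = None  # None for fixed rows
    fixed: bool = False

    def vector(self) -> np.ndarray:
        v = np.zeros(N_STATES)
        for dest, p in self.probs.items():
            v[STATE_INDEX[dest]] = p
        return v


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic monthly transition model for one arm."""

    graph: HealthStateGraph
    first_cycle_row: TransitionRow
    rows: dict[str, TransitionRow]

    def __post_init__(self) -> None:
        _validate_row(self.first_cycle_row, self.graph)
        for source, row in self.rows.items():
            if row.source != source:
                raise ValueError(f"row stored under {source!r} has source {row.source!r}")
            _validate_row(row, self.graph)
        missing = [s for s in STATES if s != INITIAL and s not in self.rows]
        if missing:
            raise ValueError(f"no transition row for states: {missing}")

    @property
    def arm(self) -> str:
        return self.graph.arm

    def matrix(self, first_cycle: bool = False) -> np.ndarray:
        """Dense row-stochastic matrix for one cycle.

        In the first-cycle matrix the initial state follows its dedicated
        row; in all later cycles the initial state is empty and formally
        self-loops so the matrix stays stochastic.
        """
        M = np.zeros((N_STATES, N_STATES))
        for source, row in self.rows.items():
            M[STATE_INDEX[source]] = row.vector()
        i0 = STATE_INDEX[INITIAL]
        if first_cycle:
            M[i0] = self.first_cycle_row.vector()
        else:
            M[i0, i0] = 1.0
        return M

    def sampled_rows(self) -> list[TransitionRow]:
        """Rows that are perturbed in PSA (non-fixed, counts present)."""
        out = [r for r in [self.first_cycle_row, *self.rows.values()]
               if not r.fixed and r.counts is not None]
        return out


def _validate_row(row: TransitionRow, graph: HealthStateGraph) -> None:
    total = sum(row.probs.values())
    if abs(total - 1.0) > _ROW_TOL:
        raise ValueError(
            f"row {row.source!r} probabilities sum to {total!r}, not 1"
        )
    for dest, p in row.probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"row {row.source!r}: probability {p} outside [0, 1]")
        if p > 0.0 and not graph.is_allowed(row.source, dest):
            raise ValueError(
                f"arm {graph.arm!r}: edge {row.source!r} -> {dest!r} is not allowed"
            )
    if row.counts is not None:
        for dest, c in row.counts.items():
            if c < 0:
                raise ValueError(f"row {row.source!r}: negative count for {dest!r}")
    if row.fixed and row.counts is not None:
        raise ValueError(f"fixed row {row.source!r} must not carry counts")


def build_row(
    source: str,
    counts: dict[str, int] | None = None,
    fixed_probs: dict[str, float] | None = None,
    printed_probs: dict[str, float] | None = None,
) -> TransitionRow:
    """Build one transition row from counts and/or fixed probabilities.

    Exactly one of ``counts`` / ``fixed_probs`` drives the row type.  When
    ``printed_probs`` accompanies ``counts`` the printed vector is used
    deterministically while the counts remain attached for PSA.
    """
    if (counts is None) == (fixed_probs is None):
        raise ValueError(f"row {source!r}: provide exactly one of counts or fixed_probs")
    if fixed_probs is not None:
        total = sum(fixed_probs.values())
        if abs(total - 1.0) > _ROW_TOL:
            raise ValueError(f"fixed row {source!r} sums to {total}, not 1")
        return TransitionRow(source=source, probs=dict(fixed_probs), fixed=True)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError(f"row {source!r}: all-zero count row")
    if printed_probs is not None:
        probs = dict(printed_probs)
    else:
        probs = {dest: c / total for dest, c in counts.items()}
    return TransitionRow(source=source, probs=probs, counts=dict(counts))


def build_transition_model(
    graph: HealthStateGraph,
    first_cycle_counts: dict[str, int],
    row_specs: dict[str, dict],
) -> TransitionModel:
    """Assemble a :class:`TransitionModel` from per-row specifications.

    ``row_specs`` maps each non-initial source state to a dict with one of
    the keys ``counts`` (Dirichlet counts), ``fixed`` (a fixed probability
    vector) and optionally ``printed`` (deterministic override alongside
    counts).
    """
    first = build_row(INITIAL, counts=first_cycle_counts)
    rows = {}
    for source, spec in row_specs.items():
        rows[source] = build_row(
            source,
            counts=spec.get("counts"),
            fixed_probs=spec.get("fixed"),
            printed_probs=spec.get("printed"),
        )
    return TransitionModel(graph=graph, first_cycle_row=first, rows=rows)
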