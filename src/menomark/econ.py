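"""Incremental cost-effectiveness comparison of the two arms.

Sign convention throughout: incremental values are LNG-IUS minus usual
medical treatment.  Dominance means one arm is strictly cheaper and at
least as effective, with at least one strict inequality; equal
effectiveness with unequal costs is reported explicitly rather than as
dominance, carrying the cost difference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .states import ARM_LNG, ARM_USUAL

_QALY_TIE_TOL = 0.0  # exact ties only; comparisons use unrounded values


@dataclass(frozen=True)
class Verdict:
    kind: str            # 'icer' | 'dominance' | 'equal_effect' | 'equal'
    icer: float | None = None
    winner: str | None = None
    cost_difference: float | None = None

    def __str__(self) -> str:
        if self.kind == "icer":
            return f"ICER {self.icer:.0f} per QALY"
        if self.kind == "dominance":
            return f"{self.winner} dominates"
        if self.kind == "equal_effect":
            return (f"equal effect; cheaper arm ({self.winner}) preferred "
                    f"(cost difference {self.cost_difference:.2f})")
        return "arms equal"


@dataclass(frozen=True)
class EconResult:
    cost_per_arm: dict[str, float]
    qaly_per_arm: dict[str, float]
    incremental_cost: float
    incremental_qaly: float
    verdict: Verdict


def econ_result(cost_per_arm: dict[str, float],
                qaly_per_arm: dict[str, float]) -> EconResult:
    """Compare the two arms on unrounded totals.

    The ICER is incremental cost over incremental QALYs (LNG-IUS minus
    usual).  When the cheaper arm is also at least as effective the verdict
    is dominance; exactly equal QALYs with unequal costs yield an explicit
    equal-effect verdict instead of an ICER or dominance claim.
    """
    for qs in qaly_per_arm.values():
        if qs < 0:
            raise ValueError("QALYs must be non-negative")
    d_cost = cost_per_arm[ARM_LNG] - cost_per_arm[ARM_USUAL]
    d_qaly = qaly_per_arm[ARM_LNG] - qaly_per_arm[ARM_USUAL]

    if d_cost == 0.0 and d_qaly == 0.0:
        verdict = Verdict(kind="equal")
    elif d_qaly == 0.0:
        winner = ARM_USUAL if d_cost > 0 else ARM_LNG
        verdict = Verdict(kind="equal_effect", winner=winner,
                          cost_difference=abs(d_cost))
    elif d_cost < 0 and d_qaly > 0:
        verdict = Verdict(kind="dominance", winner=ARM_LNG)
    elif d_cost > 0 and d_qaly < 0:
        verdict = Verdict(kind="dominance", winner=ARM_USUAL)
    else:
        verdict = Verdict(kind="icer", icer=d_cost / d_qaly)
    return EconResult(
        cost_per_arm=dict(cost_per_arm),
        qaly_per_arm=dict(qaly_per_arm),
        incremental_cost=d_cost,
        incremental_qaly=d_qaly,
        verdict=verdict,
    )


def net_monetary_benefit(wtp: float, cost: float, qalys: float) -> float:
    """NMB = willingness-to-pay x QALYs - cost."""
    return wtp * qalys - cost
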