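"""Report generation: results tables, plane/CEAC exports and plots.

Published reporting conventions are applied at this layer only: costs are
rounded to the nearest GBP 10 and QALYs to three decimal places, while all
comparisons and ICERs are computed upstream on unrounded values.  Every
artefact carries a provenance header (config hash, seed, package version,
resolved settings) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict

import pandas as pd

from . import __version__
from .econ import EconResult
from .params import ModelSpec
from .states import ARM_LABELS, ARM_LNG, ARM_USUAL


def round_cost(x: float) -> int:
    """Nearest GBP 10, for reporting only."""
    return int(round(x / 10.0) * 10)


def round_qalys(x: float) -> float:
    return round(x, 3)


def config_hash(spec: ModelSpec) -> str:
    payload = json.dumps(spec.config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(spec: ModelSpec, seed: int | None = None) -> str:
    lines = [
        f"# menomark {__version__}",
        f"# config_hash: {config_hash(spec)}",
        f"# instrument: {spec.instrument}",
        f"# settings: {json.dumps(asdict(spec.settings))}",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("# costs in GBP, 2011 prices; QALYs discounted at the "
                 "configured annual rate")
    return "\n".join(lines) + "\n"


def verdict_label(result: EconResult) -> str:
    """Label for the results table's ICER column.

    Equal-effect results are printed as the cheaper arm dominating, with a
    flag, mirroring how such rows appear in published summary tables.
    """
    v = result.verdict
    if v.kind == "icer":
        return f"{v.icer:.0f}"
    if v.kind == "dominance":
        return "Dominates"
    if v.kind == "equal_effect":
        return "Dominates (equal effect; cheaper arm preferred)"
    return "Equal"


def results_table(results: dict[str, EconResult]) -> pd.DataFrame:
    """Summary table in the published layout, one block per analysis.

    ``results`` maps an analysis label (e.g. ``"base case"``) to its
    :class:`EconResult`.
    """
    rows = []
    for label, res in results.items():
        icer = verdict_label(res)
        rows.append({
            "analysis": label,
            "intervention": ARM_LABELS[ARM_USUAL],
            "total_cost": round_cost(res.cost_per_arm[ARM_USUAL]),
            "total_qalys": round_qalys(res.qaly_per_arm[ARM_USUAL]),
            "icer_vs_usual": icer,
        })
        rows.append({
            "analysis": label,
            "intervention": ARM_LABELS[ARM_LNG],
            "total_cost": round_cost(res.cost_per_arm[ARM_LNG]),
            "total_qalys": round_qalys(res.qaly_per_arm[ARM_LNG]),
            "icer_vs_usual": "",
        })
        rows.append({
            "analysis": label,
            "intervention": "Mean difference",
            "total_cost": round_cost(res.incremental_cost),
            "total_qalys": round_qalys(res.incremental_qaly),
            "icer_vs_usual": "",
        })
    return pd.DataFrame(rows)


def write_csv(df: pd.DataFrame, path, spec: ModelSpec,
              seed: int | None = None) -> None:
    buf = io.StringIO()
    buf.write(provenance_header(spec, seed))
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def plot_plane(plane: pd.DataFrame, path, instrument: str) -> None:
    """Cost-effectiveness plane scatter (incremental, LNG-IUS vs usual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["delta_qaly"], plane["delta_cost"], s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs (LNG-IUS - usual medical treatment)")
    ax.set_ylabel("Incremental cost, GBP")
    ax.set_title(f"Cost-effectiveness plane ({instrument.upper()})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: pd.DataFrame, path, instrument: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["lambda"], curve["p_lng_ius"], label="LNG-IUS")
    ax.plot(curve["lambda"], curve["p_usual_medical"],
            label="Usual medical treatment")
    ax.set_xlabel("Willingness to pay, GBP per QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"Cost-effectiveness acceptability curves "
                 f"({instrument.upper()})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
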