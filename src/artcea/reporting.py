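"""Result tables and figures.

Tables are written as CSV with a comment header carrying the config
hash and seed, in two flavours: a reported table rounded to the field's
printed precision (money and QALYs to 2 decimals, probabilities to 4)
and a parallel full-precision table.  Figures: the cost-effectiveness
plane with the willingness-to-pay line, the tornado diagram, and the
acceptability curves; written as SVG and PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cea import UNDOMINATED
from .pipeline import INTERVENTION, ORIGINAL, PairResult

__all__ = [
    "base_case_table",
    "write_table",
    "plot_ce_plane",
    "plot_tornado",
    "plot_ceac",
]

_MONEY_COLS = (
    "cost",
    "incremental_cost",
    "icer",
    "ce_ratio",
    "icer_low",
    "icer_high",
    "swing",
    "wtp",
)
_QALY_COLS = ("effectiveness", "incremental_effectiveness")
_PROB_COLS = ("prob_original_optimal", "prob_intervention_optimal")


def base_case_table(result: PairResult) -> pd.DataFrame:
    """Two-strategy comparison in the shape of a standard CEA table."""
    rows = []
    for r in result.results:
        rows.append(
            {
                "strategy": r.strategy.name,
                "cost": r.strategy.cost,
                "incremental_cost": r.incremental_cost,
                "effectiveness": r.strategy.effectiveness,
                "incremental_effectiveness": r.incremental_effectiveness,
                "icer": r.icer,
                "ce_ratio": r.ce_ratio,
                "dominance": r.dominance,
                "decision": r.decision,
            }
        )
    return pd.DataFrame(rows)


def _rounded(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        if col in _MONEY_COLS or col in _QALY_COLS:
            out[col] = out[col].round(2)
        elif col in _PROB_COLS:
            out[col] = out[col].round(4)
    return out


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    config_hash: str,
    seed: int,
    full_precision_path: str | Path | None = None,
) -> None:
    """Write a rounded CSV (plus optionally a full-precision twin)."""
    header = f"# artcea config_hash={config_hash} seed={seed}\n"
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(header)
        _rounded(table).to_csv(fh, index=False)
    if full_precision_path is not None:
        with open(full_precision_path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, index=False)


def _save(fig, path_stem: str | Path) -> list[Path]:
    stem = Path(path_stem)
    paths = []
    for suffix in (".svg", ".png"):
        p = stem.with_suffix(suffix)
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def plot_ce_plane(result: PairResult, wtp: float, path_stem) -> list[Path]:
    """Strategies on the cost-effectiveness plane with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    markers = {ORIGINAL: ("s", "tab:red"), INTERVENTION: ("^", "tab:blue")}
    for name, strategy in result.strategies.items():
        marker, color = markers.get(name, ("o", "tab:grey"))
        ax.scatter(
            strategy.effectiveness, strategy.cost,
            marker=marker, color=color, s=70, label=name, zorder=3,
        )
    eff_max = max(s.effectiveness for s in result.strategies.values())
    xs = np.linspace(0, eff_max * 1.15, 50)
    ax.plot(xs, wtp * xs, "k:", label=f"WTP = {wtp:,.0f} USD/QALY")
    ax.set_xlabel("Effectiveness (discounted QALYs/patient)")
    ax.set_ylabel("Cost (discounted USD/patient)")
    ax.legend(frameon=False)
    return _save(fig, path_stem)


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path_stem) -> list[Path]:
    """Horizontal bars from the base-case ICER to each bound's ICER."""
    rows = tornado.dropna(subset=["swing"]).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6.5, 0.5 * max(len(rows), 4) + 1))
    for i, row in enumerate(rows.itertuples()):
        lo, hi = sorted((row.icer_low, row.icer_high))
        ax.barh(i, hi - lo, left=lo, color="tab:blue", alpha=0.7)
    ax.axvline(base_icer, color="k", ls=":", label=f"base ICER = {base_icer:,.0f}")
    ax.set_yticks(range(len(rows)), rows["param"])
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(frameon=False)
    return _save(fig, path_stem)


def plot_ceac(ceac_table: pd.DataFrame, path_stem) -> list[Path]:
    """Acceptability curves: P(optimal) against willingness to pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(
        ceac_table["wtp"], ceac_table["prob_original_optimal"],
        color="tab:red", label="original (hospital only)",
    )
    ax.plot(
        ceac_table["wtp"], ceac_table["prob_intervention_optimal"],
        color="tab:blue", label="intervention (hospital + mobile)",
    )
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    return _save(fig, path_stem)
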