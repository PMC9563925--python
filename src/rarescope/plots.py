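"""Figure exports: Kaplan–Meier curves and per-sample enumeration bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .clinical_stats import StratifiedKM


def plot_km_stratification(strat: StratifiedKM, path: str | Path) -> None:
    """Overall KM curve plus the median-split high/low curves for one
    analyte."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for km, style in ((strat.km_overall, dict(color="0.5", ls="--")),
                      (strat.km_high, dict(color="tab:red")),
                      (strat.km_low, dict(color="tab:blue"))):
        if km.event_observed is not None and len(km.event_observed):
            km.plot_survival_function(ax=ax, ci_show=False, **style)
    op = ">" if strat.rule == "gt" else "≥"
    ax.set_title(f"{strat.analyte}: split at {op} {strat.threshold:.2f}/mL")
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free fraction")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enumeration_bars(enumeration: pd.DataFrame, path: str | Path) -> None:
    """Stacked events/mL per sample, one bar per (patient, draw), colored by
    classification."""
    wide = enumeration.pivot_table(
        index=["patient_id", "draw"], columns="classification",
        values="events_per_ml", fill_value=0.0,
    )
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(wide)), 4))
    wide.plot(kind="bar", stacked=True, ax=ax, colormap="tab20", width=0.8)
    ax.set_ylabel("events/mL")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
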