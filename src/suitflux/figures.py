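"""Report figures: grouped bar charts (mean ± SD) with significance marks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["make_figures"]

_MARK = {"sig05": "*", "sig01": "**", "trend": "(*)"}


def _grouped_bars(ax, comp: pd.DataFrame, title: str, ylabel: str) -> None:
    states = comp["state"].tolist()
    x = range(len(states))
    w = 0.38
    ax.bar(
        [i - w / 2 for i in x], comp["mean_A"], w,
        yerr=comp["sd_A"], capsize=3, label="control", color="0.45",
    )
    ax.bar(
        [i + w / 2 for i in x], comp["mean_B"], w,
        yerr=comp["sd_B"], capsize=3, label="affected", color="0.75",
    )
    for i, row in enumerate(comp.itertuples(index=False)):
        mark = _MARK.get(row.cls)
        if mark:
            top = max(row.mean_A + row.sd_A, row.mean_B + row.sd_B)
            ax.text(i, top * 1.04, mark, ha="center", fontsize=11)
    ax.set_xticks(list(x))
    ax.set_xticklabels(states, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)


def make_figures(
    samples_df: pd.DataFrame, comparison_df: pd.DataFrame, out_dir: str | Path
) -> list[Path]:
    """Write the three standard report figures; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    panels = [
        ("fcr", "Flux control ratios (ref. CI+CII ETS)", "FCR", "fig_fcr.png"),
        ("flux_per_cs", "O2 flux per CS unit", "pmol/(s*ml) per (umol/ml/min)",
         "fig_flux_per_cs.png"),
        ("rcr", "Respiratory control ratio", "RCR", "fig_rcr.png"),
    ]
    for mode, title, ylabel, fname in panels:
        comp = comparison_df[comparison_df["mode"] == mode]
        if comp.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 3.2), dpi=120)
        _grouped_bars(ax, comp, title, ylabel)
        fig.tight_layout()
        path = out / fname
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths
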