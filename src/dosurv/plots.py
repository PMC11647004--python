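"""Matplotlib views of cross-validation summaries and error curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_MODEL_COLORS = {
    "cox": "tab:green",
    "cox_lasso": "tab:blue",
    "cox_bootstrap_lasso": "tab:purple",
    "rsf": "tab:orange",
}


def plot_cv_summary(summary: pd.DataFrame, out_path: str | Path) -> None:
    """Dot plot of mean +/- SD per metric, grouped by feature group and model."""
    metrics = [("harrell_c", "Harrell's C"), ("ipcw_c", "IPCW C"), ("ibs", "IBS")]
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5), sharey=False)
    groups = list(dict.fromkeys(summary["feature_group"]))
    xs = {g: i for i, g in enumerate(groups)}
    for ax, (metric, label) in zip(axes, metrics):
        for model, color in _MODEL_COLORS.items():
            rows = summary[summary["model"] == model]
            if not len(rows):
                continue
            x = [xs[g] for g in rows["feature_group"]]
            ax.errorbar(
                x,
                rows[f"{metric}_mean"],
                yerr=rows[f"{metric}_sd"],
                fmt="o",
                color=color,
                label=model,
                capsize=3,
                alpha=0.8,
            )
        ref = summary[f"{metric}_mean"].min() if metric == "ibs" else summary[f"{metric}_mean"].max()
        ax.axhline(ref, ls=":", color="grey")
        ax.set_xticks(range(len(groups)), groups, rotation=30, ha="right")
        ax.set_title(label)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_error_curves(mean_frame: pd.DataFrame, out_path: str | Path) -> None:
    """Time-dependent bounded C-index and Brier-score mean curves."""
    fig, (ax_c, ax_b) = plt.subplots(1, 2, figsize=(12, 4.5))
    for name, sub in mean_frame.groupby("model"):
        ax_c.plot(sub["tau"], sub["ctau"], label=name, lw=1.5)
        ax_b.plot(sub["tau"], sub["brier"], label=name, lw=1.5)
    ax_c.set_xlabel("time (years)")
    ax_c.set_ylabel(r"bounded IPCW C-index $C_\tau$")
    ax_b.set_xlabel("time (years)")
    ax_b.set_ylabel(r"Brier score BS($\tau$)")
    ax_c.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
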