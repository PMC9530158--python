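"""Study-summary plots: metric vs series and metric vs NSA."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_series_comparison", "plot_nsa_dependence"]

_SERIES_ORDER = ["echo1", "echo2", "echo3", "echo4", "echo5",
                 "echo1-2", "echo1-3", "echo1-4", "echo1-5"]
_PANELS = ["cnr_wm_csf", "cnr_gm_wm", "contrast_wm_csf",
           "contrast_gm_wm", "snr_wm", "snr_gm"]
_COLORS = {"lse": "tab:blue", "cm": "tab:red"}


def _panel(ax, sel: pd.DataFrame, x_col: str, order=None):
    for region, grp in sel.groupby("region"):
        if order is not None:
            grp = grp.set_index(x_col).reindex(order).reset_index()
            x = range(len(grp))
            ax.set_xticks(list(x), grp[x_col], rotation=45, fontsize=7)
        else:
            grp = grp.sort_values(x_col)
            x = grp[x_col]
        ax.errorbar(x, grp["mean"], yerr=grp["sd"], marker="o", ms=3,
                    capsize=2, label=region.upper(), color=_COLORS.get(region))


def plot_series_comparison(summary: pd.DataFrame, path: str | Path, nsa: int | None = None):
    """Metric vs echo/echo-combination at fixed (default max) NSA."""
    if nsa is None:
        nsa = int(summary["nsa"].max())
    fig, axes = plt.subplots(3, 2, figsize=(8, 9), sharex=True)
    for ax, metric in zip(axes.ravel(), _PANELS):
        sel = summary[(summary["metric"] == metric) & (summary["nsa"] == nsa)]
        order = [s for s in _SERIES_ORDER if s in set(sel["series_id"])]
        _panel(ax, sel, "series_id", order=order)
        ax.set_title(metric, fontsize=9)
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(f"Echoes and echo combinations (NSA = {nsa})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_nsa_dependence(summary: pd.DataFrame, path: str | Path, series_id: str = "echo1-3"):
    """Metric vs NSA for one series (default: 3 combined echoes)."""
    fig, axes = plt.subplots(3, 2, figsize=(8, 9), sharex=True)
    for ax, metric in zip(axes.ravel(), _PANELS):
        sel = summary[(summary["metric"] == metric) & (summary["series_id"] == series_id)]
        _panel(ax, sel, "nsa")
        ax.set_title(metric, fontsize=9)
        ax.set_xlabel("NSA")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(f"Signal averaging ({series_id})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
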