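"""Optional basic plots: KM step curves and the AUC-vs-model-size trace.

Rendering is deliberately plain — the tabular outputs are the primary
interface; these helpers exist for quick desk inspection.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_km_curves", "plot_auc_trace"]


def plot_km_curves(curves: pd.DataFrame, path: str | Path) -> Path:
    """Step plot of the per-group survival curves (columns group/time/survival)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in curves.groupby("group"):
        ax.step(sub["time"], sub["survival"], where="post", label=str(group))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(title="risk group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_auc_trace(trace: pd.DataFrame, path: str | Path) -> Path:
    """AUC against candidate-model size, with the zenith marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(trace["size"], trace["auc"], marker="o")
    best = trace.loc[trace["auc"].idxmax()]
    ax.axvline(best["size"], ls="--", color="grey")
    ax.set_xlabel("model size (pairs)")
    ax.set_ylabel("horizon AUC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
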