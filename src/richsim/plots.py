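"""Optional figures: detection-frequency histograms and median accumulation curves.

Requires matplotlib (the ``plot`` extra); import is deferred so the core
package stays plot-free.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .community import IncidenceMatrix
from .experiment import frequency_histogram

__all__ = ["plot_frequency_histogram", "plot_median_curves"]


def plot_frequency_histogram(matrix: IncidenceMatrix, path: str | Path) -> None:
    """Bar chart of detections-per-species (the Q_k profile) for one sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = frequency_histogram(matrix)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(hist), list(hist.values()), color="steelblue", width=0.9)
    ax.set_xlabel("detections per species (k)")
    ax.set_ylabel("number of species (Q_k)")
    ax.set_title(f"T = {matrix.T} effort units")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_median_curves(raw: pd.DataFrame, path: str | Path) -> None:
    """Scatter of replicate estimates with the median curve, per estimator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    estimators = sorted(raw["estimator"].unique())
    fig, axes = plt.subplots(
        len(estimators), 1, figsize=(7, 3 * len(estimators)), sharex=True, squeeze=False
    )
    for ax, name in zip(axes.ravel(), estimators):
        sub = raw[raw["estimator"] == name]
        ax.plot(sub["effort_level"], sub["estimate"], "o", color="black",
                alpha=0.15, markersize=3)
        med = sub.groupby("effort_level")["estimate"].median()
        ax.plot(med.index, med.values, color="red", lw=2, label="median")
        ax.set_ylabel(f"{name}\nestimated richness")
        ax.legend(loc="lower right")
    axes.ravel()[-1].set_xlabel("effort units (days)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
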