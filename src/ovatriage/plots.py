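"""Figure helpers for the report stage: ROC band and calibration curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_roc_band", "plot_calibration"]


def plot_roc_band(band: pd.DataFrame, path: str | Path) -> Path:
    """ROC curve with its pointwise bootstrap percentile band, drawn in the
    (specificity, sensitivity) plane with specificity decreasing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    x = 1.0 - band["specificity"]
    ax.fill_between(x, band["sens_lower"], band["sens_upper"],
                    alpha=0.25, label="95% band")
    ax.plot(x, band["sens_point"], lw=1.5, label="AI models")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_calibration(cal: pd.DataFrame, path: str | Path) -> Path:
    """Predicted risk versus observed malignancy proportion per bin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.plot(cal["mean_score"], cal["observed"], marker="o")
    ax.set_xlabel("Mean predicted risk of malignancy")
    ax.set_ylabel("Observed proportion malignant")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
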