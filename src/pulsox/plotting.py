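"""Agreement plots: Bland-Altman and correlation scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["bland_altman_plot", "correlation_plot"]


def bland_altman_plot(
    pairs: pd.DataFrame, ax=None, path: str | Path | None = None
):
    """Difference vs mean with bias and 1.96-sd limits of agreement."""
    est = pairs["spo2_est"].to_numpy(float)
    ref = pairs["spo2_ref"].to_numpy(float)
    diff = est - ref
    mean = 0.5 * (est + ref)
    bias = diff.mean()
    sd = diff.std(ddof=1) if diff.size > 1 else 0.0
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=12, alpha=0.6)
    ax.axhline(bias, color="k", lw=1)
    for lim in (bias - 1.96 * sd, bias + 1.96 * sd):
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of estimate and reference SpO2 [%]")
    ax.set_ylabel("estimate - reference [%]")
    ax.set_title("Bland-Altman")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def correlation_plot(
    pairs: pd.DataFrame, ax=None, path: str | Path | None = None
):
    """Estimate vs reference scatter with the identity line."""
    est = pairs["spo2_est"].to_numpy(float)
    ref = pairs["spo2_ref"].to_numpy(float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, est, s=12, alpha=0.6)
    lo = min(ref.min(), est.min()) - 1
    hi = max(ref.max(), est.max()) + 1
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("reference SpO2 [%]")
    ax.set_ylabel("estimated SpO2 [%]")
    ax.set_title("Correlation")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
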