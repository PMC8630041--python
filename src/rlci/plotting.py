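"""Figures: classification images, impact curves, RT summaries."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends
import matplotlib.pyplot as plt
import numpy as np

from .kernels import ClassificationImage, ImpactCurves, RTSummary


def plot_classification_image(ci: ClassificationImage, ax: Optional[plt.Axes] = None):
    """Space x lag kernel as an image: bright = positive weight."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    vmax = np.nanmax(np.abs(ci.kernel)) or 1.0
    ax.imshow(
        ci.kernel,
        aspect="auto",
        origin="lower",
        cmap="gray",
        vmin=-vmax,
        vmax=vmax,
        extent=[ci.lag_ms[0], ci.lag_ms[-1], -0.5, ci.kernel.shape[0] - 0.5],
    )
    ax.invert_xaxis()
    ax.set_xlabel("time before response (ms)")
    ax.set_ylabel("bar")
    return ax


def plot_impact_curves(curves: ImpactCurves, ax: Optional[plt.Axes] = None, label_prefix: str = ""):
    """Central (red) and adjacent (blue) weight-vs-lag profiles."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(curves.lag_ms, curves.central, color="crimson", label=f"{label_prefix}central")
    ax.plot(curves.lag_ms, curves.adjacent, color="steelblue", label=f"{label_prefix}adjacent")
    if curves.se_central is not None:
        ax.fill_between(
            curves.lag_ms,
            curves.central - curves.se_central,
            curves.central + curves.se_central,
            color="crimson",
            alpha=0.25,
            lw=0,
        )
    ax.invert_xaxis()
    ax.set_xlabel("time before response (ms)")
    ax.set_ylabel("weight")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_rt_summary(summary: RTSummary, ax: Optional[plt.Axes] = None):
    """Cumulative RT histograms per ramp rate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    colors = {0.05: "crimson", 0.1: "steelblue", 0.2: "seagreen"}
    for alpha, (grid, cdf) in summary.ecdf.items():
        ax.plot(grid, cdf, color=colors.get(alpha, "k"), label=f"alpha={alpha}")
    ax.set_xlabel("reaction time (ms)")
    ax.set_ylabel("cumulative proportion")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_fit(result, ax: Optional[plt.Axes] = None):
    """Fitted-model impact curves over the target curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    target = result.model.target_curves
    model = result.model_curves
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.plot(target.lag_ms, target.central, color="crimson", alpha=0.4, label="target central")
    ax.plot(target.lag_ms, target.adjacent, color="steelblue", alpha=0.4, label="target adjacent")
    ax.plot(model.lag_ms, model.central, color="crimson", ls="--", label="model central")
    ax.plot(model.lag_ms, model.adjacent, color="steelblue", ls="--", label="model adjacent")
    ax.invert_xaxis()
    ax.set_xlabel("time before response (ms)")
    ax.set_ylabel("weight")
    ax.legend(frameon=False, fontsize=7)
    return ax
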