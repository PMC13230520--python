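"""Optional matplotlib views of counterfactual runs (import separately)."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np


def plot_counterfactual_ensemble(cf, reference, coord=0, ax=None):
    """Sampled counterfactuals (black) against the deterministic reference (red)."""
    ax = ax or plt.gca()
    for k in range(cf.K):
        ax.plot(cf.trajectories[k, :, coord], color="k", alpha=0.25, lw=0.6)
    ax.plot(reference[:, coord], color="r", lw=1.2, label="deterministic cf")
    ax.set_xlabel("step")
    ax.set_ylabel(f"x{coord + 1}")
    ax.legend(loc="best", fontsize="small")
    return ax


def plot_phase_portrait(cf, reference, coords=(0, 1), ax=None):
    """2-D projection of the ensemble and the reference trajectory."""
    i, j = coords
    ax = ax or plt.gca()
    for k in range(cf.K):
        ax.plot(
            cf.trajectories[k, :, i], cf.trajectories[k, :, j],
            color="k", alpha=0.2, lw=0.5,
        )
    ax.plot(reference[:, i], reference[:, j], color="r", lw=1.0)
    ax.set_xlabel(f"x{i + 1}")
    ax.set_ylabel(f"x{j + 1}")
    return ax


def plot_rmse_curves(curves: dict, threshold=None, ax=None):
    """Smoothed RMSE_t per parameter regime, with an optional threshold line."""
    ax = ax or plt.gca()
    for label, curve in curves.items():
        if curve is None:
            continue
        ax.plot(curve.smoothed, label=label)
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("step")
    ax.set_ylabel(r"RMSE$_t$ (smoothed)")
    ax.legend(loc="best", fontsize="small")
    return ax


def save_figure(path, fig=None, dpi=150):
    (fig or plt.gcf()).savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
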