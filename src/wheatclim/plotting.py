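"""Generic matplotlib figures for the pipeline outputs.

All functions take an optional ``ax`` and return the Axes they drew on, so
they compose with user-managed figures; nothing here is written to disk
unless the caller does so.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _get_ax(ax):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_trend(x, y, fit=None, ax=None, xlabel="harvest year", ylabel=""):
    """Scatter of an annual series with an optional fitted polynomial trend."""
    ax = _get_ax(ax)
    ax.scatter(x, y, s=18, color="tab:blue", alpha=0.8)
    if fit is not None:
        xs = np.linspace(np.min(x), np.max(x), 200)
        ax.plot(xs, fit.predict(xs), color="tab:red",
                label=f"degree {fit.degree}, R²={fit.r_squared:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax


def plot_obs_vs_sim(pairs, metrics=None, ax=None):
    """Observed-vs-simulated scatter with the 1:1 line and fitted regression."""
    ax = _get_ax(ax)
    obs, sim = pairs.observed, pairs.simulated
    lo = min(obs.min(), sim.min())
    hi = max(obs.max(), sim.max())
    pad = 0.05 * (hi - lo or 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad],
            ls="--", color="grey", label="1:1")
    ax.scatter(obs, sim, s=20, color="tab:blue")
    if metrics is not None:
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, metrics.intercept + metrics.slope * xs, color="tab:red",
                label=f"S = {metrics.intercept:.2f} + {metrics.slope:.2f}·O")
        ax.set_title(
            f"R²={metrics.r_squared:.2f} RMSE={metrics.rmse:.2f} "
            f"MAE={metrics.mae:.2f} bias={metrics.bias:+.2f}", fontsize=9
        )
    ax.set_xlabel(f"observed {pairs.label}".strip())
    ax.set_ylabel(f"simulated {pairs.label}".strip())
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_sensitivity_boxes(grid, axis: str = "delta_t", ax=None):
    """Boxplots of replicate yields along the ΔT (default) or CO₂ axis,
    pooled over the other axis."""
    ax = _get_ax(ax)
    if axis not in ("delta_t", "co2"):
        raise ValueError("axis must be 'delta_t' or 'co2'")
    levels = np.sort(grid.data[axis].unique())
    groups = [grid.data.loc[grid.data[axis] == v, "yield_t_ha"].to_numpy()
              for v in levels]
    ax.boxplot(groups, tick_labels=[f"{v:g}" for v in levels])
    ax.set_xlabel("ΔT (°C)" if axis == "delta_t" else "CO₂ (ppm)")
    ax.set_ylabel("simulated yield (t ha⁻¹)")
    return ax


def plot_correlation_matrix(corr: pd.DataFrame, ax=None):
    """Heatmap of a Pearson correlation matrix with annotated r values."""
    ax = _get_ax(ax)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(len(corr.index)):
        for j in range(len(corr.columns)):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
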