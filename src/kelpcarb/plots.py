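"""Plotting helpers (matplotlib is imported lazily; install the ``plot`` extra)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_light_curve(results, ax=None, n_grid: int = 200):
    """Observed points and the fitted P-I curve of a :class:`LightCurveResults`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = results.model
    ax.plot(m.irradiance, m.response, "o", label="observed")
    E = np.linspace(0, float(np.max(m.irradiance)) * 1.05, n_grid)
    ax.plot(E, results.predict(E), "-",
            label=f"fit: Pmax={results.p_max:.2f}, Ek={results.e_k:.0f}")
    ax.axvline(results.e_k, ls=":", color="grey")
    ax.set_xlabel("irradiance (µmol photons m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel("Δ response")
    ax.legend()
    return ax


def plot_amelioration_surface(grid: pd.DataFrame, ax=None, threshold: float | None = None):
    """Filled-contour per-density-rate surface over irradiance x flow.

    ``grid`` is the output of :func:`kelpcarb.surface_grid`; ``threshold``
    optionally draws the zero-net-rate contour (amelioration threshold).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pivot = grid.pivot_table(index="flow_l_min", columns="irradiance", values="rate")
    E = pivot.columns.to_numpy()
    F = pivot.index.to_numpy()
    cs = ax.contourf(E, F, pivot.to_numpy(), levels=20, cmap="viridis")
    plt.colorbar(cs, ax=ax, label="rate (µmol L$^{-1}$ per g FW L$^{-1}$)")
    if threshold is not None:
        ax.axvline(threshold, color="black", lw=2)
    ax.set_xlabel("irradiance (µmol photons m$^{-2}$ s$^{-1}$)")
    ax.set_ylabel("flow (L min$^{-1}$)")
    scen = grid["scenario"].iloc[0]
    var = grid["variable"].iloc[0]
    ax.set_title(f"{var} per-density rate, {scen}")
    return ax
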