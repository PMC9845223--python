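"""Diagnostic figures: heat maps with fitted circles, speed and MSD plots."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .heatmap import CircleEstimate, HeatMapGrid
from .kinematics import MSDCurve

__all__ = ["plot_heatmap", "plot_msd", "plot_speed_distribution"]


def plot_heatmap(grid: HeatMapGrid, circle: Optional[CircleEstimate] = None, ax=None):
    """Render a heat map (log-scaled counts) with an optional fitted circle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [
        grid.i0 * grid.cell_size,
        (grid.i0 + grid.counts.shape[0]) * grid.cell_size,
        grid.j0 * grid.cell_size,
        (grid.j0 + grid.counts.shape[1]) * grid.cell_size,
    ]
    img = np.where(grid.counts > 0, np.log1p(grid.counts), np.nan)
    ax.imshow(img.T, origin="lower", extent=extent, aspect="equal", cmap="viridis")
    if circle is not None:
        theta = np.linspace(0, 2 * np.pi, 256)
        ax.plot(
            circle.x_c + circle.r_c * np.cos(theta),
            circle.y_c + circle.r_c * np.sin(theta),
            "k--", linewidth=1,
        )
    lo, hi = grid.v0_bin
    ax.set_xlabel("x [m]")
    ax.set_ylabel("y [m]")
    ax.set_title(f"arrival points, v0 in [{lo:g}, {hi:g}) m/s, dt = {grid.delta_t:g} s")
    return ax


def plot_msd(curve: MSDCurve, fit_windows: Sequence[Tuple[float, float]] = (), ax=None):
    """Log-log MSD curve with optional fitted power laws per window."""
    import matplotlib.pyplot as plt

    from .kinematics import fit_msd_exponent

    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(curve.tau, curve.msd, "o", markersize=3, label="MSD")
    for lo, hi in fit_windows:
        beta = fit_msd_exponent(curve, (lo, hi))
        mask = (curve.tau >= lo) & (curve.tau <= hi)
        anchor = curve.msd[mask][0] / curve.tau[mask][0] ** beta
        ax.loglog(
            curve.tau[mask], anchor * curve.tau[mask] ** beta, "-",
            label=f"beta = {beta:.2f} on [{lo:g}, {hi:g}] s",
        )
    ax.set_xlabel("tau [s]")
    ax.set_ylabel("MSD [m$^2$]")
    ax.legend()
    return ax


def plot_speed_distribution(edges: np.ndarray, density: np.ndarray, ax=None, **kwargs):
    """Speed histogram as a step plot (walking and jogging modes visible)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.stairs(density, edges, **kwargs)
    ax.set_xlabel("speed [m/s]")
    ax.set_ylabel("density [s/m]")
    return ax
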