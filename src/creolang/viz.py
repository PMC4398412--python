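"""Plots: transition stripe (with the expanded x axis) and phase surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .demography import (
    CREOLE_PREDICTED,
    NO_CREOLE_PREDICTED,
    Classification,
)
from .phase import TransitionStripe

#: Exponent of the horizontal-axis expansion used for stripe plots: small
#: Mulatto fractions carry most of the structure, so x is shown as x**0.2.
X_EXPAND_POWER = 0.2

_VERDICT_COLORS = {
    CREOLE_PREDICTED: "tab:orange",
    NO_CREOLE_PREDICTED: "tab:blue",
    "uncertain": "tab:green",
}


def _tx(x: np.ndarray | float) -> np.ndarray | float:
    return np.asarray(x, dtype=float) ** X_EXPAND_POWER


def plot_stripe(
    stripe: TransitionStripe,
    classifications: list[Classification] | None = None,
    ax: plt.Axes | None = None,
    path=None,
):
    """Stripe (and optionally classified census points) in the (x, y) plane.

    The horizontal axis is expanded by the power 0.2; tick labels show the
    untransformed Mulatto fraction.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    ok = ~np.isnan(stripe.y_lower) & ~np.isnan(stripe.y_upper)
    xs = stripe.xs[ok]
    ax.fill_between(
        _tx(xs),
        stripe.y_lower[ok],
        stripe.y_upper[ok],
        color="0.8",
        label="transition stripe (ε 0.05–0.07)",
    )
    ax.plot(_tx(xs), stripe.y_lower[ok], "k-", lw=1)
    ax.plot(_tx(xs), stripe.y_upper[ok], "k-", lw=1)
    okm = ~np.isnan(stripe.y_mid)
    ax.plot(_tx(stripe.xs[okm]), stripe.y_mid[okm], "k--", lw=1, label="ε = 0.06")

    if classifications:
        for verdict, color in _VERDICT_COLORS.items():
            pts = [c.point for c in classifications if c.verdict == verdict]
            if pts:
                ax.scatter(
                    _tx(np.array([p.x for p in pts])),
                    [p.y for p in pts],
                    s=30,
                    color=color,
                    label=verdict.replace("_", " "),
                    zorder=3,
                )

    ticks = np.array([0.001, 0.01, 0.05, 0.2, 0.5, 1.0])
    ax.set_xticks(_tx(ticks))
    ax.set_xticklabels([f"{t:g}" for t in ticks])
    ax.set_xlabel(r"$N_M/(N_M+N_B)$  (axis expanded by power 0.2)")
    ax.set_ylabel(r"$(N_M+N_B)/N$")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8, loc="lower left")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_phase_surface(grid_frame, value: str = "f_C", ax=None, path=None):
    """Heatmap of a sweep column (e.g. f_C or p_creole) over the (x, y) grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 4.5))
    pivot = grid_frame.pivot_table(index="y", columns="x", values=value)
    mesh = ax.pcolormesh(
        pivot.columns.to_numpy(),
        pivot.index.to_numpy(),
        pivot.to_numpy(),
        shading="nearest",
        vmin=0,
        vmax=1,
        cmap="viridis",
    )
    ax.figure.colorbar(mesh, ax=ax, label=value)
    ax.set_xlabel(r"$N_M/(N_M+N_B)$")
    ax.set_ylabel(r"$(N_M+N_B)/N$")
    if path:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
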