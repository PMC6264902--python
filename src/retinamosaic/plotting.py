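"""Rendering of retina patterns and phase diagrams.

The lattice is stored rectangularly; hexagonal geometry is purely a display
concern, handled here by offsetting alternate columns by half a row, as in
the packed ommatidial grid of the compound eye.  Rendering flips the
horizontal axis so that anterior (the last column generated) appears on the
left, matching the usual presentation of fly eyes.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import RegularPolygon

from .pattern import RetinaPattern
from .pattern_stats import PhaseDiagram

__all__ = ["render_pattern", "plot_phase_diagram", "plot_recovery_curves"]

GREEN = "#2ca02c"
RED = "#d62728"


def render_pattern(
    pattern: RetinaPattern,
    path: Union[str, Path, None] = None,
    ax: Optional[plt.Axes] = None,
    hex_packed: bool = True,
):
    """Draw a pattern (green = 1, red = 0) with anterior on the left.

    With ``hex_packed`` the cells are drawn as half-row-offset hexagons;
    otherwise as a plain raster.  Returns the axes; saves a PNG when ``path``
    is given.
    """
    created = ax is None
    if created:
        fig, ax = plt.subplots(
            figsize=(max(2.0, pattern.n_cols / 8), max(1.5, pattern.n_rows / 8))
        )
    n, m = pattern.n_rows, pattern.n_cols
    if hex_packed:
        radius = 1.0 / math.sqrt(3)
        for i in range(n):
            for j in range(m):
                x = m - 1 - j  # flip: anterior (last generated) on the left
                y = n - 1 - i + (0.5 if j % 2 else 0.0)
                ax.add_patch(
                    RegularPolygon(
                        (x, y),
                        numVertices=6,
                        radius=radius,
                        orientation=math.pi / 6,
                        facecolor=GREEN if pattern.cells[i, j] else RED,
                        edgecolor="none",
                    )
                )
        ax.set_xlim(-1, m)
        ax.set_ylim(-1, n + 1)
        ax.set_aspect("equal")
    else:
        ax.imshow(
            pattern.cells[:, ::-1],
            cmap=matplotlib.colors.ListedColormap([RED, GREEN]),
            vmin=0,
            vmax=1,
            interpolation="nearest",
        )
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlabel("anterior $\\leftarrow$ furrow $\\leftarrow$ posterior")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_phase_diagram(diagram: PhaseDiagram, path: Union[str, Path, None] = None):
    """Heatmap of mean <R^h> on the signed-alpha x P0_droso plane.

    Negative x is the uniform-fly (beta < 0) branch, positive x the
    alternating Doli (beta > 0) branch; undefined (constant-pattern) cells
    are left blank.
    """
    uniform = diagram.values[diagram.branches.index("uniform")]
    doli = diagram.values[diagram.branches.index("doli")]
    # left half: alpha increasing leftwards on the uniform branch
    combined = np.concatenate([uniform[::-1], doli], axis=0).T  # (P0, signed alpha)
    signed_alpha = np.concatenate([-diagram.alpha_grid[::-1], diagram.alpha_grid])
    fig, ax = plt.subplots(figsize=(7, 4))
    im = ax.pcolormesh(
        signed_alpha,
        diagram.p0_droso_grid,
        combined,
        cmap="RdGy_r",
        vmin=-1,
        vmax=1,
        shading="nearest",
    )
    fig.colorbar(im, ax=ax, label=r"mean $\langle R^h \rangle$")
    ax.set_xlabel(r"$\alpha$  (left: $\beta<0$ uniform branch, right: $\beta>0$ Doli branch)")
    ax.set_ylabel(r"$P_0^{Droso}$")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def plot_recovery_curves(report, path: Union[str, Path, None] = None):
    """Recovery-study summary: alpha and epsilon identity curves and errors."""
    curve = report.alpha_curve()
    eps_curve = report.epsilon_curve()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    ax = axes[0]
    for col in ("mae_alpha", "mae_epsilon", "mae_P0", "mode_error_rate"):
        ax.plot(curve.index, curve[col], marker="o", label=col)
    ax.set_xlabel(r"true $\alpha$")
    ax.set_ylabel("mean error")
    ax.legend(fontsize=7)
    ax = axes[1]
    ax.errorbar(
        curve["mean_true_alpha"],
        curve["mean_inferred_alpha"],
        yerr=curve["std_inferred_alpha"],
        marker="o",
        ls="none",
    )
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel(r"true $\alpha$")
    ax.set_ylabel(r"mean inferred $\alpha$")
    ax = axes[2]
    ax.errorbar(
        eps_curve.index,
        eps_curve["mean_inferred_epsilon"],
        yerr=eps_curve["std"],
        marker="o",
        ls="none",
    )
    lim = max(eps_curve.index.max(), 0.5)
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel(r"true $\epsilon$")
    ax.set_ylabel(r"mean inferred $\epsilon$")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return axes
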