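"""Half-disc wedge rendering of SpheriCell maps.

A 6x3 ROI map is drawn as a half disc: shells become concentric rings and
the three latitude sectors become mirrored wedge pairs (polar at the top
and bottom of the vertical mitotic axis, equatorial around the horizontal
division plane), matching the longitudinal-cut projection used to display
the spherical coordinate system.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Wedge

from .geometry import DEFAULT_GRID, RoiGrid

STYLES = {"intensity": "viridis", "effect": "coolwarm"}

#: angular spans (degrees, from the horizontal division plane) of each
#: sector and its mirror images on the half disc drawn over [-90, 90]
_SECTOR_SPANS = {
    0: [(60.0, 90.0), (-90.0, -60.0)],  # polar
    1: [(30.0, 60.0), (-60.0, -30.0)],  # diagonal
    2: [(-30.0, 30.0)],  # equatorial
}


def render_map(
    values: np.ndarray,
    path=None,
    style: str = "intensity",
    grid: RoiGrid = DEFAULT_GRID,
    title: str | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
    ax=None,
):
    """Render 6x3 ROI values (NaN = masked/not significant) as a half disc.

    ``style`` selects the colormap: 'intensity' (sequential) or 'effect'
    (diverging, centered at zero).  Returns the matplotlib figure; with
    ``path`` set, also saves it (deterministic for fixed inputs).
    """
    if style not in STYLES:
        raise ValueError(f"style must be one of {sorted(STYLES)}")
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_shells, grid.n_sectors):
        raise ValueError(f"values must have shape {(grid.n_shells, grid.n_sectors)}")

    cmap = plt.get_cmap(STYLES[style])
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("all ROIs masked; nothing to render")
    if style == "effect":
        bound = np.max(np.abs(finite)) or 1.0
        vmin = -bound if vmin is None else vmin
        vmax = bound if vmax is None else vmax
    else:
        vmin = float(finite.min()) if vmin is None else vmin
        vmax = float(finite.max()) if vmax is None else vmax
    span = vmax - vmin or 1.0

    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(4, 5))
    else:
        fig = ax.figure
    for mu in range(grid.n_shells):
        r_out = (mu + 1) / grid.n_shells
        width = 1.0 / grid.n_shells
        for nu in range(grid.n_sectors):
            val = values[mu, nu]
            if np.isfinite(val):
                color = cmap((val - vmin) / span)
            else:
                color = (0.85, 0.85, 0.85, 1.0)
            for a0, a1 in _SECTOR_SPANS[nu]:
                ax.add_patch(
                    Wedge((0, 0), r_out, a0, a1, width=width,
                          facecolor=color, edgecolor="white", linewidth=0.5)
                )
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    sm = plt.cm.ScalarMappable(
        cmap=cmap, norm=plt.Normalize(vmin=vmin, vmax=vmax)
    )
    fig.colorbar(sm, ax=ax, fraction=0.04, pad=0.02)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        if own_fig:
            plt.close(fig)
    return fig
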