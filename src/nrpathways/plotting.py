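"""Optional rendering of the diagnostic diagram (isopleths + gradient arrows)."""

from __future__ import annotations

import numpy as np

from .pathway import GradientField, Pathway, ResponseSurface, gradient_field


def plot_diagnostic_diagram(
    surface: ResponseSurface,
    path: Pathway | None = None,
    cost_path: Pathway | None = None,
    gradients: GradientField | None = None,
    ax=None,
):
    """Contour the surface on the control plane with gradient arrows and pathways.

    Returns the matplotlib Axes.  Importing matplotlib is deferred so headless
    library use never touches a plotting backend.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    X, Y = np.meshgrid(surface.x_grid, surface.y_grid, indexing="ij")
    cs = ax.contour(X, Y, surface.value, levels=12, cmap="viridis")
    ax.clabel(cs, inline=True, fontsize=7, fmt="%.1f")

    if gradients is None:
        gradients = gradient_field(surface)
    ax.quiver(X, Y, -gradients.gx, -gradients.gy, color="steelblue", alpha=0.6, width=0.003)

    for p, color, label in ((path, "purple", "optimal"), (cost_path, "red", "cost-optimal")):
        if p is not None:
            xs = [n[0] for n in p.nodes]
            ys = [n[1] for n in p.nodes]
            ax.plot(xs, ys, color=color, lw=2.5, marker="o", ms=4, label=label)
    if path is not None or cost_path is not None:
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("NH$_3$ emission reduction")
    ax.set_ylabel("NO$_x$ emission reduction")
    return ax
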