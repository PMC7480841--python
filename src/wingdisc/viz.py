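"""Quick-look rendering of tissue states and curvature traces."""

from __future__ import annotations

import numpy as np

from .quantify import pouch_basal_polyline
from .state import NodeClass, TissueState

__all__ = ["plot_tissue", "plot_curvature_trace"]

_KIND_COLORS = {"columnar": "#4878cf", "boundary": "#6acc65", "squamous": "#d65f5f"}


def plot_tissue(state: TissueState, ax=None, show_ecm: bool = True):
    """Draw cell outlines, nuclei and the ECM chain of one state."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for i, cell in enumerate(state.cells):
        poly = state.pos[cell.membrane_ring]
        ax.fill(
            poly[:, 0], poly[:, 1],
            facecolor=_KIND_COLORS[cell.kind], edgecolor="k",
            linewidth=0.4, alpha=0.35, zorder=1,
        )
        if cell.nucleus_nodes.size:
            nuc = state.pos[cell.nucleus_nodes]
            ax.plot(nuc[:, 0], nuc[:, 1], ".", color="#30304a", ms=2, zorder=3)
    if show_ecm and state.has_ecm:
        chain = state.pos[state.ecm_chain]
        ax.plot(chain[:, 0], chain[:, 1], "-", color="#9467bd", lw=1.2, zorder=2)
    basal = pouch_basal_polyline(state)
    ax.plot(basal[:, 0], basal[:, 1], "-", color="#c44e52", lw=1.0, zorder=4)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    return ax


def plot_curvature_trace(trajectory, ax=None):
    """Global curvature vs time with the fitted plateau, if it converged."""
    import matplotlib.pyplot as plt

    from .quantify import asymptotic_fit

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    t, c = trajectory.times, trajectory.global_curvature
    ax.plot(t, c, "k-", lw=1)
    if len(t) >= 5:
        c_inf, tau, resid = asymptotic_fit(t, c)
        if np.isfinite(resid):
            ax.axhline(c_inf, color="#c44e52", ls="--", lw=1,
                       label=f"plateau {c_inf:.4f} (res {resid:.1%})")
            ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("time (AU)")
    ax.set_ylabel("global curvature (μm$^{-1}$)")
    return ax
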