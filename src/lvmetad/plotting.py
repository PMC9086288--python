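"""Minimal FES heat-map helper."""

from __future__ import annotations

__all__ = ["plot_fes"]


def plot_fes(fes, path=None, ax=None, cmap="viridis", vmax=None):
    """Pcolormesh of a 2D free-energy surface; returns the axes.

    Unsampled cells are masked.  Saves to ``path`` if given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    F = np.ma.masked_invalid(fes.F)
    mesh = ax.pcolormesh(fes.x_edges, fes.y_edges, F.T, cmap=cmap, vmax=vmax)
    ax.figure.colorbar(mesh, ax=ax, label="free energy (kcal/mol)")
    ax.set_xlabel(f"{fes.x_name}")
    ax.set_ylabel(f"{fes.y_name}")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
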