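"""Figure-style outputs: 1D profiles, 2D contour maps with MEP overlay."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mep import MinimumEnergyPath
from .wham import PMFGrid

__all__ = ["contour_levels", "plot_pmf_1d", "plot_pmf_2d", "plot_path_profile"]

CONTOUR_SPACING = 1.0  # kcal/mol between isolines


def contour_levels(pmf: PMFGrid, spacing: float = CONTOUR_SPACING) -> np.ndarray:
    """Isoline levels {0, spacing, 2·spacing, …} covering the masked range."""
    top = np.nanmax(pmf.values[pmf.mask])
    lo = min(0.0, np.nanmin(pmf.values[pmf.mask]))
    start = np.floor(lo / spacing) * spacing
    return np.arange(start, top + spacing, spacing)


def plot_pmf_1d(pmf: PMFGrid, ax=None, **kwargs):
    if pmf.dim != 1:
        raise ValueError("plot_pmf_1d needs a 1D PMF")
    if ax is None:
        _, ax = plt.subplots()
    x = pmf.centers[0]
    y = np.where(pmf.mask, pmf.values, np.nan)
    ax.plot(x, y, **kwargs)
    ax.set_xlabel("d1 (Å)")
    ax.set_ylabel("free energy (kcal/mol)")
    return ax


def plot_pmf_2d(pmf: PMFGrid, path: MinimumEnergyPath = None, ax=None,
                spacing: float = CONTOUR_SPACING):
    """Filled contour map with isolines every ``spacing`` kcal/mol.

    The optional minimum energy path is overlaid as a black line, one vertex
    per path node.
    """
    if pmf.dim != 2:
        raise ValueError("plot_pmf_2d needs a 2D PMF")
    if path is not None and path.nodes.shape[1] != 2:
        raise ValueError("path dimensionality does not match the PMF")
    if ax is None:
        _, ax = plt.subplots()
    x, y = pmf.centers
    Z = np.where(pmf.mask, pmf.values, np.nan).T  # contourf wants (ny, nx)
    levels = contour_levels(pmf, spacing)
    cf = ax.contourf(x, y, Z, levels=levels, cmap="viridis")
    ax.contour(x, y, Z, levels=levels, colors="k", linewidths=0.4)
    plt.colorbar(cf, ax=ax, label="free energy (kcal/mol)")
    if path is not None:
        ax.plot(path.nodes[:, 0], path.nodes[:, 1], "k-", lw=1.5)
    ax.set_xlabel("d1 (Å)")
    ax.set_ylabel("d2 (Å)")
    return ax


def plot_path_profile(path: MinimumEnergyPath, ax=None, annotate_minima=True):
    """Free energy along the path vs node index, with d1/d2 annotations."""
    if ax is None:
        _, ax = plt.subplots()
    idx = np.arange(path.n_points)
    ax.plot(idx, path.free_energy, "b-")
    ax.set_xlabel("path node")
    ax.set_ylabel("free energy (kcal/mol)")
    if annotate_minima:
        from .mep import find_minima_and_barriers

        report = find_minima_and_barriers(path.free_energy, nodes=path.nodes)
        for i, pos, f in report.minima:
            if pos is not None:
                ax.annotate(
                    f"({pos[0]:.1f}, {pos[1]:.1f})",
                    (i, f),
                    textcoords="offset points",
                    xytext=(0, -12),
                    ha="center",
                    fontsize=7,
                )
    return ax
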