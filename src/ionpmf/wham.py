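"""Weighted histogram analysis method (WHAM) for 1D and 2D umbrella sampling.

Reconstructs the unbiased potential of mean force F(ξ) = −kT ln p(ξ) from
histograms of biased window samples via the standard self-consistent
equations

    p_j = ( Σ_i n_ij ) / ( Σ_i N_i exp[(f_i − c_ij)/kT] )
    exp(−f_i/kT) = Σ_j p_j exp(−c_ij/kT)

where n_ij are window i's counts in bin j, N_i its retained total, and c_ij
the bias energy evaluated at the bin centre.  The per-window free-energy
constants f_i are iterated to self-consistency; an equivalent convex
log-likelihood minimization (in the reduced variables g_i = f_i/kT) is
available as a fallback for poorly conditioned window sets.

No autocorrelation correction is applied inside WHAM — statistical error is
quantified downstream by the block-analysis module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .constants import thermal_energy
from .umbrella import UmbrellaWindow, bias_energy

__all__ = [
    "HistogramSet",
    "PMFGrid",
    "WhamConnectivityError",
    "histogram_windows",
    "solve_wham",
    "align_pmf",
    "pmf_difference",
    "wham_residual",
    "wham_objective",
]

DEFAULT_BIN_WIDTH_1D = 0.1  # Å
DEFAULT_BIN_WIDTH_2D = 0.25  # Å per axis


class WhamConnectivityError(RuntimeError):
    """Raised when the occupied histogram splits into disconnected components."""

    def __init__(self, components):
        self.components = components
        sizes = [len(c) for c in components]
        super().__init__(
            f"histogram coverage splits into {len(components)} disconnected "
            f"components of sizes {sizes}; windows do not overlap"
        )


@dataclass
class HistogramSet:
    """Per-window histograms on a common grid, plus the aligned bias list."""

    edges: tuple  # one strictly increasing edge array per dimension (Å)
    counts: np.ndarray  # (n_windows, *grid_shape)
    totals: np.ndarray  # (n_windows,) retained samples per window
    biases: list  # aligned with the window axis
    temperature: float = 300.0  # K

    @property
    def dim(self) -> int:
        return len(self.edges)

    @property
    def shape(self) -> tuple:
        return tuple(len(e) - 1 for e in self.edges)

    @property
    def centers(self) -> tuple:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def total_counts(self) -> np.ndarray:
        """Counts per bin summed over windows."""
        return self.counts.sum(axis=0)


@dataclass
class PMFGrid:
    """Binned free-energy surface with a sampled-bin mask.

    ``values`` holds kcal/mol on the grid, NaN on unmasked bins.  With the
    "min-zero" convention the minimum over masked bins is exactly 0.
    """

    centers: tuple  # bin-centre array per dimension (Å)
    values: np.ndarray  # grid of kcal/mol, NaN where unmasked
    mask: np.ndarray  # bool grid: bins with enough samples
    counts: np.ndarray  # total counts per bin
    temperature: float = 300.0
    zero_convention: str = "min-zero"
    meta: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return len(self.centers)

    @property
    def bin_widths(self) -> tuple:
        return tuple(float(c[1] - c[0]) if len(c) > 1 else 0.0 for c in self.centers)


def _bin_edges(samples, bin_width, bounds=None):
    if bounds is not None:
        lo, hi = bounds
    else:
        lo = samples.min() - bin_width  # pad by one bin
        hi = samples.max() + bin_width
    first = np.floor(lo / bin_width) * bin_width
    n = int(np.ceil((hi - first) / bin_width - 1e-9))
    return first + bin_width * np.arange(n + 1)


def histogram_windows(
    windows: list[UmbrellaWindow],
    bin_width=None,
    bounds=None,
    temperature: float = 300.0,
) -> HistogramSet:
    """Bin all window samples onto a common half-open grid.

    Bins are [edge_i, edge_i+1): a sample exactly on an interior edge goes to
    the bin on its right.  The grid spans the union of all samples padded by
    one bin unless explicit per-dimension ``bounds`` are given.
    """
    if not windows:
        raise ValueError("no windows to histogram")
    dim = windows[0].dim
    if any(w.dim != dim for w in windows):
        raise ValueError("all windows must share dimensionality")
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTH_1D if dim == 1 else DEFAULT_BIN_WIDTH_2D
    widths = np.broadcast_to(np.asarray(bin_width, dtype=float), (dim,))

    all_samples = np.concatenate([w.samples for w in windows], axis=0)
    edges = []
    for d in range(dim):
        b = None if bounds is None else bounds[d]
        edges.append(_bin_edges(all_samples[:, d], widths[d], b))
    shape = tuple(len(e) - 1 for e in edges)

    counts = np.zeros((len(windows),) + shape, dtype=float)
    for i, w in enumerate(windows):
        idx = []
        ok = np.ones(w.n_samples, dtype=bool)
        for d in range(dim):
            j = np.floor((w.samples[:, d] - edges[d][0]) / widths[d]).astype(int)
            ok &= (j >= 0) & (j < shape[d])
            idx.append(j)
        if not ok.all():
            raise ValueError(
                f"window {i} has {int((~ok).sum())} samples outside the grid bounds"
            )
        np.add.at(counts[i], tuple(j[ok] for j in idx), 1.0)
    totals = np.array([w.n_samples for w in windows], dtype=float)
    return HistogramSet(
        edges=tuple(edges),
        counts=counts,
        totals=totals,
        biases=[w.bias for w in windows],
        temperature=temperature,
    )


def _bin_center_grid(h: HistogramSet) -> np.ndarray:
    """Flattened (n_bins, dim) array of bin-centre positions."""
    centers = h.centers
    mesh = np.meshgrid(*centers, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _bias_matrix(h: HistogramSet) -> np.ndarray:
    """Bias energies c_ij at bin centres: (n_windows, n_bins)."""
    pts = _bin_center_grid(h)
    rows = []
    for b in h.biases:
        if h.dim == 1:
            rows.append(bias_energy(b, pts[:, 0]))
        else:
            rows.append(bias_energy(b, pts))
    return np.asarray(rows)


def _check_connectivity(h: HistogramSet, gap_bins: int = 2):
    """Verify the occupied bins form one statistically coupled component.

    Occupied bins are considered connected when within ``gap_bins`` of each
    other along every axis (window tails couple near-adjacent bins through
    the bias weights) or when co-occupied by the same window.
    """
    from scipy import ndimage

    occ_grid = h.total_counts > 0
    structure = np.ones((2 * gap_bins + 1,) * occ_grid.ndim, dtype=bool)
    dilated = ndimage.binary_dilation(occ_grid, structure=structure)
    labels, n_comp = ndimage.label(dilated, structure=np.ones((3,) * occ_grid.ndim, int))
    comp = labels.ravel()
    occ_w = h.counts.reshape(len(h.biases), -1) > 0

    # merge components bridged by a single window's own samples
    parent = {c: c for c in range(1, n_comp + 1)}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(occ_w.shape[0]):
        comps = {find(int(c)) for c in np.unique(comp[occ_w[i]]) if c != 0}
        comps = sorted(comps)
        for c in comps[1:]:
            parent[c] = comps[0]

    occupied = np.flatnonzero(occ_grid.ravel())
    roots = {}
    for b in occupied:
        roots.setdefault(find(int(comp[b])), []).append(int(b))
    if len(roots) > 1:
        raise WhamConnectivityError(list(roots.values()))


def wham_objective(g, log_n, log_N, neg_beta_c):
    """Convex WHAM log-likelihood objective and gradient in g_i = f_i/kT.

    Minimizing  Φ(g) = Σ_j n_j ln D_j − Σ_i N_i g_i  with
    D_j = Σ_i N_i exp(g_i − βc_ij)  is equivalent to the self-consistent
    equations; the gauge g_0 = 0 is fixed by the caller.
    """
    a = log_N[:, None] + g[:, None] + neg_beta_c  # (n_w, n_bins)
    logD = logsumexp(a, axis=0)
    phi = float(np.sum(np.exp(log_n) * logD) - np.sum(np.exp(log_N) * g))
    # dΦ/dg_k = Σ_j n_j softmax_k(a_j) − N_k
    w = np.exp(a - logD)  # (n_w, n_bins)
    grad = w @ np.exp(log_n) - np.exp(log_N)
    return phi, grad


def wham_residual(h: HistogramSet, f: np.ndarray) -> float:
    """Max |f − WHAM_update(f)| in kcal/mol: the self-consistency residual."""
    kT = thermal_energy(h.temperature)
    c = _bias_matrix(h)
    n_j = h.total_counts.ravel()
    occ = n_j > 0
    g = np.asarray(f, dtype=float) / kT
    logD = logsumexp(
        np.log(h.totals)[:, None] + g[:, None] - c[:, occ] / kT, axis=0
    )
    logp = np.log(n_j[occ]) - logD
    g_new = -logsumexp(logp[None, :] - c[:, occ] / kT, axis=1)
    g_new -= g_new[0] - g[0]
    return float(np.max(np.abs(g_new - g)) * kT)


def solve_wham(
    h: HistogramSet,
    tol: float = 1e-7,
    max_iter: int = 100000,
    min_count: int = 1,
    method: str = "auto",
) -> PMFGrid:
    """Solve the WHAM equations and return the PMF on the histogram grid.

    Parameters
    ----------
    tol : float
        Convergence threshold on max |Δf_i| per iteration, kcal/mol.
    max_iter : int
        Iteration cap; non-convergence raises with the last residual.
    min_count : int
        Bins with fewer total counts are masked out of the PMF.
    method : {"auto", "scf", "mle"}
        "scf" iterates the self-consistent equations; "mle" minimizes the
        equivalent convex likelihood then polishes with SCF; "auto" starts
        with SCF and falls back to "mle" if progress is slow.

    Returns a min-zero aligned :class:`PMFGrid`; ``meta`` records iterations
    and the final self-consistency residual.
    """
    n_j_grid = h.total_counts
    n_j = n_j_grid.ravel()
    if not np.any(n_j > 0):
        raise ValueError("histogram set holds no counts")
    _check_connectivity(h)

    kT = thermal_energy(h.temperature)
    c = _bias_matrix(h)  # (n_w, n_bins)
    occ = n_j > 0
    neg_beta_c = -c[:, occ] / kT
    log_n = np.log(n_j[occ])
    log_N = np.log(h.totals)
    n_w = len(h.biases)

    # linear-space SCF with per-iteration gauge fixing; underflowed bias
    # weights are true zeros (window never reaches that bin)
    with np.errstate(under="ignore"):
        W = np.exp(neg_beta_c)  # (n_w, n_bins_occ)
    N = h.totals

    def scf_sweep(g, n_iter):
        resid = np.inf
        it = 0
        for it in range(1, n_iter + 1):
            D = (N * np.exp(g)) @ W  # (n_bins,)
            p = np.exp(log_n) / D
            z = W @ p
            g_new = -np.log(z)
            g_new -= g_new[0]
            resid = float(np.max(np.abs(g_new - g)) * kT)
            g = g_new
            if resid < tol:
                break
        return g, resid, it

    def mle_step(g):
        res = optimize.minimize(
            wham_objective,
            g,
            args=(log_n, log_N, neg_beta_c),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        return res.x - res.x[0]

    g = np.zeros(n_w)
    iterations = 0
    if method == "scf":
        g, resid, iterations = scf_sweep(g, max_iter)
    elif method == "mle":
        g = mle_step(g)
        g, resid, iterations = scf_sweep(g, max_iter)
    elif method == "auto":
        g, resid, iterations = scf_sweep(g, min(max_iter, 2000))
        if resid >= tol:
            g = mle_step(g)
            g, resid, it2 = scf_sweep(g, max(max_iter - iterations, 1000))
            iterations += it2
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = wham_residual_from(g, kT, log_n, log_N, neg_beta_c)
    if resid >= tol:
        raise RuntimeError(
            f"WHAM did not converge in {iterations} iterations "
            f"(last residual {resid:.3e} kcal/mol)"
        )

    # unbiased probabilities and PMF on occupied bins
    D = (N * np.exp(g)) @ W
    p = np.exp(log_n) / D
    F_occ = -kT * np.log(p)

    values = np.full(n_j.shape, np.nan)
    values[occ] = F_occ
    mask = n_j >= min_count
    values[~mask] = np.nan
    shape = h.shape
    pmf = PMFGrid(
        centers=h.centers,
        values=values.reshape(shape),
        mask=mask.reshape(shape),
        counts=n_j_grid.astype(float),
        temperature=h.temperature,
        zero_convention="min-zero",
        meta={
            "iterations": iterations,
            "residual_kcal_mol": float(resid),
            "window_free_energies": (g * kT).tolist(),
            "tol": tol,
        },
    )
    return align_pmf(pmf, "min-zero")


def wham_residual_from(g, kT, log_n, log_N, neg_beta_c) -> float:
    logD = logsumexp(log_N[:, None] + g[:, None] + neg_beta_c, axis=0)
    logp = log_n - logD
    g_new = -logsumexp(logp[None, :] + neg_beta_c, axis=1)
    g_new -= g_new[0] - g[0]
    return float(np.max(np.abs(g_new - g)) * kT)


def align_pmf(p: PMFGrid, convention="min-zero", anchor=None) -> PMFGrid:
    """Shift a PMF to a zero convention.

    "min-zero" subtracts the minimum over masked bins; "anchor" subtracts the
    value at the given bin index (tuple), which must be masked.
    """
    if not np.any(p.mask):
        raise ValueError("PMF has no masked (sampled) bins")
    if convention == "min-zero":
        shift = np.nanmin(p.values[p.mask])
        tag = "min-zero"
    elif convention == "anchor":
        if anchor is None:
            raise ValueError("anchor convention needs an anchor bin index")
        idx = tuple(np.atleast_1d(anchor).astype(int))
        if not p.mask[idx]:
            raise ValueError(f"anchor bin {idx} is not masked (unsampled)")
        shift = p.values[idx]
        tag = f"anchor:{idx}"
    else:
        raise ValueError(f"unknown zero convention {convention!r}")
    return replace(p, values=p.values - shift, zero_convention=tag)


def pmf_difference(p: PMFGrid, bin_a, bin_b) -> float:
    """F(bin_a) − F(bin_b) in kcal/mol; independent of the zero convention."""
    ia = tuple(np.atleast_1d(bin_a).astype(int))
    ib = tuple(np.atleast_1d(bin_b).astype(int))
    for idx in (ia, ib):
        if not p.mask[idx]:
            raise ValueError(f"bin {idx} is unsampled; no PMF value there")
    return float(p.values[ia] - p.values[ib])
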