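"""Analytic free-energy landscapes used as synthetic ground truth.

The permeation free-energy surfaces of a sodium-channel selectivity filter
have a characteristic topology: two basins (ion bound at distinct sites, or
one ion in the aqueous cavity vs. both ions in the filter) separated by a
single saddle, with barriers of a few kcal/mol.  The constructors below build
smooth closed-form surfaces with exactly that topology — sums of inverted
Gaussian wells on a weak confining quadratic background — with the well and
barrier values calibrated numerically so that the requested barrier and
basin asymmetry hold exactly at the stationary points.

All energies are in kcal/mol, positions in Å.  The global minimum of every
constructed surface is normalized to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

__all__ = [
    "AnalyticSurface",
    "make_double_well_1d",
    "make_two_ion_surface_2d",
]

# Curvature of the weak confining background (kcal/mol/Å²). Keeps the
# landscape bounded far from the wells without distorting the calibrated
# stationary values (which are solved for with the background included).
_BACKGROUND_CURVATURE = 0.02


@dataclass
class AnalyticSurface:
    """A closed-form free-energy landscape with analytic gradient.

    ``value`` accepts positions with a trailing axis of length ``dim``
    (for ``dim == 1`` any shape is interpreted elementwise) and returns the
    free energy in kcal/mol; ``gradient`` returns kcal/mol/Å with the same
    trailing-axis convention.
    """

    dim: int
    params: dict = field(default_factory=dict)
    bounds: np.ndarray = None  # shape (dim, 2), Å
    _value: Callable = None
    _gradient: Callable = None
    _offset: float = 0.0

    def _coerce(self, x):
        x = np.asarray(x, dtype=float)
        if self.dim == 1:
            return x.reshape(-1, 1), x.shape
        if x.shape[-1] != self.dim:
            raise ValueError(
                f"expected trailing axis of length {self.dim}, got shape {x.shape}"
            )
        return x.reshape(-1, self.dim), x.shape[:-1]

    def value(self, x):
        pts, out_shape = self._coerce(x)
        return (self._value(pts) - self._offset).reshape(out_shape)

    def gradient(self, x):
        pts, out_shape = self._coerce(x)
        g = self._gradient(pts)
        if self.dim == 1:
            return g.reshape(out_shape)
        return g.reshape(out_shape + (self.dim,))

    def gradient_nd(self, pts):
        """Gradient on points of shape (n, dim), returned as (n, dim)."""
        pts = np.asarray(pts, dtype=float).reshape(-1, self.dim)
        return self._gradient(pts)

    def value_nd(self, pts):
        pts = np.asarray(pts, dtype=float).reshape(-1, self.dim)
        return self._value(pts) - self._offset


def _gauss_well_1d(x, center, amp, width):
    z = (x - center) / width
    e = np.exp(-0.5 * z * z)
    return -amp * e, amp * z / width * e  # value, d/dx


def _build_1d(centers, amps, width, mid, bounds):
    c1, c2 = centers
    a1, a2 = amps
    half_sep = 0.5 * (c2 - c1)

    # flat-bottom confining background: zero between the wells (so no
    # spurious dip appears between narrow wells), quadratic beyond them
    def _bg(x):
        excess = np.maximum(np.abs(x - mid) - half_sep, 0.0)
        return _BACKGROUND_CURVATURE * excess**2, \
            2.0 * _BACKGROUND_CURVATURE * excess * np.sign(x - mid)

    def value(pts):
        x = pts[:, 0]
        v1, _ = _gauss_well_1d(x, c1, a1, width)
        v2, _ = _gauss_well_1d(x, c2, a2, width)
        return _bg(x)[0] + v1 + v2

    def gradient(pts):
        x = pts[:, 0]
        _, g1 = _gauss_well_1d(x, c1, a1, width)
        _, g2 = _gauss_well_1d(x, c2, a2, width)
        return (_bg(x)[1] + g1 + g2)[:, None]

    return value, gradient


def _stationary_values_1d(value_fn, c1, c2, width):
    """Locate the two well minima and the intervening maximum of a 1D profile."""

    def f(x):
        return float(value_fn(np.array([[x]]))[0])

    r1 = optimize.minimize_scalar(f, bounds=(c1 - 2 * width, c1 + 2 * width), method="bounded")
    r2 = optimize.minimize_scalar(f, bounds=(c2 - 2 * width, c2 + 2 * width), method="bounded")
    rt = optimize.minimize_scalar(
        lambda x: -f(x), bounds=(min(r1.x, r2.x), max(r1.x, r2.x)), method="bounded"
    )
    return (r1.x, r1.fun), (r2.x, r2.fun), (rt.x, -rt.fun)


def make_double_well_1d(
    centers=(-3.0, 3.0),
    barrier: float = 3.0,
    asymmetry: float = 0.0,
    width: float = 0.4,
    bounds=None,
) -> AnalyticSurface:
    """Double-well 1D landscape: two minima separated by one internal barrier.

    Parameters
    ----------
    centers : pair of floats (Å)
        Approximate positions of the two minima.
    barrier : float (kcal/mol)
        Height of the internal maximum above the *lower* minimum (exact).
    asymmetry : float (kcal/mol)
        Free energy of the minimum near ``centers[1]`` relative to the one
        near ``centers[0]`` (exact; may be negative).
    width : float (Å)
        Gaussian width of each well.
    bounds : optional pair (Å)
        Domain bounds; default pads the well centers by 4 widths + 2 Å.
    """
    c1, c2 = float(centers[0]), float(centers[1])
    if c1 == c2:
        raise ValueError("well centers must be distinct")
    if c1 > c2:
        c1, c2 = c2, c1
        asymmetry = -asymmetry
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if width <= 0:
        raise ValueError("width must be positive")
    if barrier <= abs(asymmetry):
        raise ValueError(
            "barrier must exceed |asymmetry|; otherwise the higher well vanishes"
        )
    mid = 0.5 * (c1 + c2)

    def residual(amps):
        value_fn, _ = _build_1d((c1, c2), amps, width, mid, None)
        (x1, f1), (x2, f2), (xt, ft) = _stationary_values_1d(value_fn, c1, c2, width)
        lower = min(f1, f2)
        return [ft - lower - barrier, (f2 - f1) - asymmetry]

    guess = np.array([barrier + max(asymmetry, 0), barrier - min(asymmetry, 0)])
    amps = optimize.fsolve(residual, guess, xtol=1e-12)
    value_fn, grad_fn = _build_1d((c1, c2), amps, width, mid, None)

    (x1, f1), (x2, f2), (xt, ft) = _stationary_values_1d(value_fn, c1, c2, width)
    offset = min(f1, f2)
    if bounds is None:
        pad = 4.0 * width + 2.0
        bounds = (c1 - pad, c2 + pad)
    surf = AnalyticSurface(
        dim=1,
        params={
            "kind": "double_well_1d",
            "centers": (c1, c2),
            "barrier": barrier,
            "asymmetry": asymmetry,
            "width": width,
            "amplitudes": tuple(float(a) for a in amps),
            "minima": (float(x1), float(x2)),
            "maximum": float(xt),
            "bounds": (float(bounds[0]), float(bounds[1])),
        },
        bounds=np.array([[bounds[0], bounds[1]]], dtype=float),
        _value=value_fn,
        _gradient=grad_fn,
        _offset=float(offset),
    )
    return surf


def _build_2d(minima, amps, w_par, w_perp, mid, u, v):
    (ax, ay), (bx, by) = minima
    a1, a2 = amps

    def _well(pts, cx, cy, amp):
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        s = dx * u[0] + dy * u[1]
        t = dx * v[0] + dy * v[1]
        q = 0.5 * (s / w_par) ** 2 + 0.5 * (t / w_perp) ** 2
        e = np.exp(-q)
        val = -amp * e
        # d(val)/ds = amp * s / w_par^2 * e  etc.; chain back to x,y
        gs = amp * s / w_par**2 * e
        gt = amp * t / w_perp**2 * e
        gx = gs * u[0] + gt * v[0]
        gy = gs * u[1] + gt * v[1]
        return val, gx, gy

    def value(pts):
        v1, _, _ = _well(pts, ax, ay, a1)
        v2, _, _ = _well(pts, bx, by, a2)
        dx = pts[:, 0] - mid[0]
        dy = pts[:, 1] - mid[1]
        return _BACKGROUND_CURVATURE * (dx * dx + dy * dy) + v1 + v2

    def gradient(pts):
        _, g1x, g1y = _well(pts, ax, ay, a1)
        _, g2x, g2y = _well(pts, bx, by, a2)
        gx = 2.0 * _BACKGROUND_CURVATURE * (pts[:, 0] - mid[0]) + g1x + g2x
        gy = 2.0 * _BACKGROUND_CURVATURE * (pts[:, 1] - mid[1]) + g1y + g2y
        return np.stack([gx, gy], axis=-1)

    return value, gradient


def make_two_ion_surface_2d(
    minima_a=(0.0, 0.0),
    minima_b=(6.0, 6.0),
    barrier: float = 3.5,
    valley_width: float = 1.5,
    asymmetry: float = 0.0,
    bounds=None,
) -> AnalyticSurface:
    """Two-basin 2D landscape joined through a single saddle.

    The two wells are anisotropic Gaussians aligned with the inter-minimum
    axis (longitudinal width set by the separation, transverse width by
    ``valley_width``) on a weak confining quadratic background centred at the
    midpoint.  The construction is mirror-symmetric about the line through
    the minima, so all stationary points lie on that line and the saddle is
    the calibrated maximum between the wells.

    ``asymmetry`` is the free energy of the basin at ``minima_b`` relative to
    the one at ``minima_a`` (exact); ``barrier`` is the saddle height above
    the lower basin (exact).
    """
    a = np.asarray(minima_a, dtype=float)
    b = np.asarray(minima_b, dtype=float)
    sep = float(np.linalg.norm(b - a))
    if sep == 0.0:
        raise ValueError("basin minima must be distinct")
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if valley_width <= 0:
        raise ValueError("valley_width must be positive")
    if barrier <= abs(asymmetry):
        raise ValueError("barrier must exceed |asymmetry|")
    u = (b - a) / sep          # along the inter-minimum axis
    v = np.array([-u[1], u[0]])  # transverse
    mid = 0.5 * (a + b)
    w_par = sep / 4.0

    def line_profile(value_fn):
        # stationary analysis restricted to the symmetry line through a, b
        def f(s):
            p = mid + (s - sep / 2.0) * u
            return float(value_fn(p.reshape(1, 2))[0])

        r1 = optimize.minimize_scalar(f, bounds=(-2 * w_par, 2 * w_par), method="bounded")
        r2 = optimize.minimize_scalar(
            f, bounds=(sep - 2 * w_par, sep + 2 * w_par), method="bounded"
        )
        rt = optimize.minimize_scalar(
            lambda s: -f(s), bounds=(min(r1.x, r2.x), max(r1.x, r2.x)), method="bounded"
        )
        return (r1.x, r1.fun), (r2.x, r2.fun), (rt.x, -rt.fun)

    def residual(amps):
        value_fn, _ = _build_2d((a, b), amps, w_par, valley_width, mid, u, v)
        (s1, f1), (s2, f2), (st, ft) = line_profile(value_fn)
        lower = min(f1, f2)
        return [ft - lower - barrier, (f2 - f1) - asymmetry]

    bg = _BACKGROUND_CURVATURE * (sep / 2.0) ** 2
    guess = np.array([barrier + max(asymmetry, 0) + bg, barrier - min(asymmetry, 0) + bg])
    amps = optimize.fsolve(residual, guess, xtol=1e-12)
    value_fn, grad_fn = _build_2d((a, b), amps, w_par, valley_width, mid, u, v)

    (s1, f1), (s2, f2), (st, ft) = line_profile(value_fn)
    offset = min(f1, f2)
    min_a = mid + (s1 - sep / 2.0) * u
    min_b = mid + (s2 - sep / 2.0) * u
    saddle = mid + (st - sep / 2.0) * u
    if bounds is None:
        pad = 2.0 * max(w_par, valley_width) + 2.0
        lo = np.minimum(a, b) - pad
        hi = np.maximum(a, b) + pad
        bounds = np.stack([lo, hi], axis=-1)
    else:
        bounds = np.asarray(bounds, dtype=float)
    return AnalyticSurface(
        dim=2,
        params={
            "kind": "two_ion_surface_2d",
            "minima_a": tuple(a),
            "minima_b": tuple(b),
            "barrier": barrier,
            "asymmetry": asymmetry,
            "valley_width": valley_width,
            "amplitudes": tuple(float(x) for x in amps),
            "stationary_minima": (tuple(min_a), tuple(min_b)),
            "saddle": tuple(saddle),
            "bounds": bounds.tolist(),
        },
        bounds=bounds,
        _value=value_fn,
        _gradient=grad_fn,
        _offset=float(offset),
    )


def surface_from_params(params: dict) -> AnalyticSurface:
    """Rebuild a surface from the ``params`` record written by a generator run."""
    kind = params.get("kind")
    if kind == "double_well_1d":
        return make_double_well_1d(
            centers=params["centers"],
            barrier=params["barrier"],
            asymmetry=params["asymmetry"],
            width=params["width"],
            bounds=params["bounds"],
        )
    if kind == "two_ion_surface_2d":
        return make_two_ion_surface_2d(
            minima_a=params["minima_a"],
            minima_b=params["minima_b"],
            barrier=params["barrier"],
            asymmetry=params["asymmetry"],
            valley_width=params["valley_width"],
            bounds=params["bounds"],
        )
    raise ValueError(f"unknown surface kind: {kind!r}")


def tabulate_surface(surface: AnalyticSurface, bin_width: float = 0.25, bounds=None):
    """Evaluate a 2D analytic surface on a bin-centre grid as a PMFGrid.

    Useful for exercising the path machinery against exact landscapes; the
    result is fully masked-in with a uniform nominal count per bin.
    """
    from .wham import PMFGrid  # deferred: wham does not depend on surfaces

    if surface.dim != 2:
        raise ValueError("tabulate_surface expects a 2D surface")
    if bounds is None:
        bounds = surface.bounds
    bounds = np.asarray(bounds, dtype=float)
    centers = tuple(
        np.arange(bounds[d, 0] + bin_width / 2, bounds[d, 1], bin_width)
        for d in range(2)
    )
    mesh = np.stack(np.meshgrid(*centers, indexing="ij"), axis=-1)
    values = surface.value(mesh)
    values = values - values.min()
    return PMFGrid(
        centers=centers,
        values=values,
        mask=np.ones(values.shape, dtype=bool),
        counts=np.full(values.shape, 1e6),
        zero_convention="min-zero",
    )
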