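"""Overdamped Langevin sampler for synthetic umbrella-sampling windows.

Generates per-window reaction-coordinate time series with the statistical
structure the downstream analysis assumes: samples distributed as the
Boltzmann weight of (analytic surface + harmonic bias) at the simulation
temperature, correlated on the picosecond scale, recorded at a fixed stride.

Integration is Euler–Maruyama on the overdamped equation

    dx = -(D/kT) ∇(F + U_bias) dt + sqrt(2 D dt) ξ

with reflecting walls at the surface's domain bounds.  Every window is a
pure function of (surface, bias, config, seed): identical inputs give
bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import thermal_energy
from .surfaces import AnalyticSurface
from .umbrella import BiasPotential, UmbrellaWindow

__all__ = ["SamplerConfig", "sample_window", "sample_windows", "window_seed"]

#: Default provenance seed recorded in generated output headers.
DEFAULT_SEED = 2012

# How far beyond the domain bounds a step may land before the integrator is
# declared unstable (reflection can no longer be trusted).
_DOMAIN_MARGIN = 1.0  # Å


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the synthetic sampler.

    Defaults emulate a 0.5 ns umbrella window sampled once per picosecond:
    500 recorded samples of which the first 50 are later discarded as
    equilibration, leaving 450 per window.
    """

    temperature: float = 300.0  # K
    diffusion: float = 0.1  # Å²/ps
    dt: float = 0.01  # ps
    n_samples: int = 500  # recorded positions per window
    stride: float = 1.0  # ps between recorded positions
    seed: int = DEFAULT_SEED
    t0: float = 0.0  # ps, time stamp of the first recorded sample

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one sample per window")
        if self.stride < self.dt:
            raise ValueError("stride must be at least one time step")

    @property
    def kT(self) -> float:
        return thermal_energy(self.temperature)


def window_seed(base_seed: int, index: int) -> int:
    """Stable per-window seed derived from a protocol base seed (< 2³¹)."""
    return (int(base_seed) * 1_000_003 + 7919 * int(index) + 1) % (2**31)


def _equilibrium_start(surface, bias, cfg, rng):
    """Draw the window's initial position from the biased Boltzmann density.

    Emulates seeding each umbrella window from an equilibrated configuration:
    the density ∝ exp(−(F + U_bias)/kT) is tabulated on a fine grid within
    the window's reach (several bias standard deviations, clipped to the
    domain) and sampled by inverse CDF using the window's own generator.
    """
    kT = cfg.kT
    c = np.asarray(bias.center, dtype=float)
    reach = 6.0 * np.sqrt(kT / bias.k)
    lo = np.maximum(c - reach, surface.bounds[:, 0])
    hi = np.minimum(c + reach, surface.bounds[:, 1])
    n = 121
    axes = [np.linspace(lo[d], hi[d], n) for d in range(surface.dim)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, surface.dim)
    u = surface.value_nd(mesh) + bias_energy_nd(bias, mesh)
    w = np.exp(-(u - u.min()) / kT)
    cdf = np.cumsum(w)
    idx = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
    return mesh[min(idx, len(mesh) - 1)]


def bias_energy_nd(bias: BiasPotential, pts: np.ndarray) -> np.ndarray:
    c = np.asarray(bias.center)
    return 0.5 * bias.k * np.sum((pts - c) ** 2, axis=-1)


def _check_bias(surface: AnalyticSurface, bias: BiasPotential):
    if bias.dim != surface.dim:
        raise ValueError(
            f"bias dimensionality {bias.dim} does not match surface ({surface.dim})"
        )
    lo, hi = surface.bounds[:, 0], surface.bounds[:, 1]
    c = np.asarray(bias.center)
    if np.any(c < lo) or np.any(c > hi):
        raise ValueError(f"bias centre {bias.center} outside domain bounds")


def sample_windows(
    surface: AnalyticSurface,
    biases: list[BiasPotential],
    cfg: SamplerConfig,
    seeds=None,
    init: str = "equilibrium",
) -> list[UmbrellaWindow]:
    """Sample all windows of a protocol simultaneously (one stream per window).

    Window i uses the seed ``seeds[i]`` (default: ``window_seed(cfg.seed, i)``)
    and its series is bit-identical to ``sample_window`` run alone with that
    seed — the per-window noise streams are independent generators.

    ``init`` selects the starting position: "equilibrium" (default) draws it
    from the window's biased Boltzmann density, emulating seeding from an
    equilibrated configuration; "center" starts at the bias centre.
    """
    if not biases:
        raise ValueError("no bias windows given")
    for b in biases:
        _check_bias(surface, b)
    if seeds is None:
        seeds = [window_seed(cfg.seed, i) for i in range(len(biases))]
    if len(seeds) != len(biases):
        raise ValueError("need one seed per window")

    dim = surface.dim
    n_w = len(biases)
    centers = np.array([b.center for b in biases], dtype=float)  # (n_w, dim)
    ks = np.array([b.k for b in biases], dtype=float)
    lo = surface.bounds[:, 0]
    hi = surface.bounds[:, 1]

    steps_per_rec = int(round(cfg.stride / cfg.dt))
    mobility = cfg.diffusion * cfg.dt / cfg.kT
    noise_amp = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    rngs = [np.random.default_rng(int(s)) for s in seeds]

    if init == "equilibrium":
        x = np.array(
            [_equilibrium_start(surface, b, cfg, r) for b, r in zip(biases, rngs)]
        )
    elif init == "center":
        x = centers.copy()
    else:
        raise ValueError(f"unknown init {init!r}")
    np.clip(x, lo, hi, out=x)
    out = np.empty((cfg.n_samples, n_w, dim))
    out[0] = x
    for rec in range(1, cfg.n_samples):
        noise = np.stack(
            [rng.standard_normal((steps_per_rec, dim)) for rng in rngs], axis=1
        )  # (steps, n_w, dim)
        for t in range(steps_per_rec):
            grad = surface.gradient_nd(x) + ks[:, None] * (x - centers)
            x = x - mobility * grad + noise_amp * noise[t]
            if np.any(x < lo - _DOMAIN_MARGIN) or np.any(x > hi + _DOMAIN_MARGIN):
                raise RuntimeError(
                    "integration step left the domain by more than "
                    f"{_DOMAIN_MARGIN} Å — reduce the time step"
                )
            # reflecting walls
            over_lo = x < lo
            if over_lo.any():
                x = np.where(over_lo, 2.0 * lo - x, x)
            over_hi = x > hi
            if over_hi.any():
                x = np.where(over_hi, 2.0 * hi - x, x)
        out[rec] = x

    windows = []
    for i, b in enumerate(biases):
        windows.append(
            UmbrellaWindow(
                bias=b,
                samples=out[:, i, :].copy(),
                stride=cfg.stride,
                t0=cfg.t0,
                label=f"window_{i:03d}",
            )
        )
    return windows


def sample_window(
    surface: AnalyticSurface,
    bias: BiasPotential,
    cfg: SamplerConfig,
    init: str = "equilibrium",
) -> UmbrellaWindow:
    """Sample a single umbrella window; seeded directly by ``cfg.seed``."""
    return sample_windows(surface, [bias], cfg, seeds=[cfg.seed], init=init)[0]
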