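"""Harmonic bias windows and umbrella-sampling bookkeeping.

The umbrella-sampling protocol mirrors the standard single-/two-ion channel
permeation setup: harmonic restraints of force constant 10 kcal/mol/Å²
applied to axial reaction coordinates, window centres stepped in 1.0 Å
increments, 0.5 ns per window with the first 50 ps discarded as
equilibration.  The harmonic convention is U(x) = ½·k·Σᵢ(xᵢ−cᵢ)², fixed here
and used consistently by the sampler and by WHAM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "BiasPotential",
    "UmbrellaWindow",
    "ReactionCoordinateDef",
    "build_windows_1d",
    "build_windows_2d",
    "bias_energy",
    "discard_equilibration",
    "compute_reaction_coordinates",
]

DEFAULT_FORCE_CONSTANT = 10.0  # kcal/mol/Å²


@dataclass(frozen=True)
class BiasPotential:
    """Harmonic restraint ½·k·Σ(xᵢ−cᵢ)² on 1 or 2 reaction coordinates."""

    center: tuple  # Å, one entry per coordinate
    k: float = DEFAULT_FORCE_CONSTANT  # kcal/mol/Å², shared by all components

    def __post_init__(self):
        center = tuple(float(c) for c in np.atleast_1d(self.center))
        object.__setattr__(self, "center", center)
        if self.k <= 0:
            raise ValueError(f"force constant must be positive, got {self.k}")
        if len(center) not in (1, 2):
            raise ValueError("bias dimensionality must be 1 or 2")

    @property
    def dim(self) -> int:
        return len(self.center)

    def energy(self, x):
        """Bias energy (kcal/mol) at position(s) x with trailing axis = dim."""
        return bias_energy(self, x)


def bias_energy(bias: BiasPotential, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    c = np.asarray(bias.center)
    if bias.dim == 1:
        # 1D positions are interpreted elementwise, whatever their shape
        return 0.5 * bias.k * (x - c[0]) ** 2
    if x.shape[-1] != bias.dim:
        raise ValueError(
            f"position has trailing axis {x.shape[-1:]}, bias is {bias.dim}-dimensional"
        )
    return 0.5 * bias.k * np.sum((x - c) ** 2, axis=-1)


@dataclass(frozen=True)
class UmbrellaWindow:
    """Reaction-coordinate series collected under one harmonic bias.

    ``samples`` has shape (n, dim); sample i was recorded at time
    ``t0 + i*stride`` (ps).  ``equil_discarded`` records how much leading
    signal has already been removed.
    """

    bias: BiasPotential
    samples: np.ndarray  # (n, dim), Å
    stride: float = 1.0  # ps between consecutive samples
    t0: float = 0.0  # ps, time of the first stored sample
    equil_discarded: float = 0.0  # ps
    label: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim == 1:
            samples = samples[:, None]
        object.__setattr__(self, "samples", samples)
        if samples.shape[1] != self.bias.dim:
            raise ValueError("sample dimensionality does not match the bias")
        if self.stride <= 0:
            raise ValueError("stride must be positive")

    @property
    def dim(self) -> int:
        return self.bias.dim

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.stride * np.arange(self.n_samples)

    @property
    def duration(self) -> float:
        """Total retained duration (ps): one stride per stored sample."""
        return self.n_samples * self.stride


def build_windows_1d(
    range_start: float,
    range_end: float,
    spacing: float = 1.0,
    k: float = DEFAULT_FORCE_CONSTANT,
) -> list[BiasPotential]:
    """Arithmetic ladder of 1D bias centres: start, start+spacing, … ≤ end."""
    if range_end < range_start:
        raise ValueError("range_end must be ≥ range_start")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = int(math.floor((range_end - range_start) / spacing + 1e-9)) + 1
    return [BiasPotential((range_start + i * spacing,), k) for i in range(n)]


def build_windows_2d(
    d1_range: Sequence[float],
    d2_range: Sequence[float],
    spacing: float = 1.0,
    k: float = DEFAULT_FORCE_CONSTANT,
    mask: Optional[Callable[[float, float], bool]] = None,
) -> list[BiasPotential]:
    """Cartesian grid of 2D bias centres, d1-major order, optionally masked.

    ``mask(d1, d2) -> bool`` keeps a centre when it returns True.
    """
    ladder1 = [b.center[0] for b in build_windows_1d(d1_range[0], d1_range[1], spacing, k)]
    ladder2 = [b.center[0] for b in build_windows_1d(d2_range[0], d2_range[1], spacing, k)]
    out = []
    for c1 in ladder1:
        for c2 in ladder2:
            if mask is None or mask(c1, c2):
                out.append(BiasPotential((c1, c2), k))
    return out


def discard_equilibration(window: UmbrellaWindow, t_equil: float = 50.0) -> UmbrellaWindow:
    """Drop all samples recorded at times < ``t_equil`` (ps).

    Idempotent for a fixed ``t_equil``: once the retained series starts at or
    after ``t_equil`` nothing further is removed.
    """
    if t_equil >= window.t0 + window.duration:
        raise ValueError(
            f"t_equil={t_equil} ps is not shorter than the window "
            f"({window.t0 + window.duration} ps)"
        )
    keep = window.times >= t_equil
    n_dropped = int(np.sum(~keep))
    if n_dropped == 0:
        return window
    return replace(
        window,
        samples=window.samples[keep],
        t0=float(window.times[keep][0]),
        equil_discarded=window.equil_discarded + n_dropped * window.stride,
    )


@dataclass(frozen=True)
class ReactionCoordinateDef:
    """Axial distance of a tagged ion from a reference carbonyl-oxygen ring.

    The coordinate is (ion z) − (mean z of the reference oxygens); positive
    when the ion sits extracellular to the ring.  ``reference_residue`` names
    the ring (e.g. "THR175" for d1, "LEU176" for d2); ``source`` selects
    backbone-carbonyl vs. sidechain oxygens.
    """

    ion_id: str
    reference_residue: str
    source: str = "backbone-carbonyl-O"


def compute_reaction_coordinates(frame, *defs: ReactionCoordinateDef) -> tuple:
    """Evaluate one or more axial reaction coordinates on a snapshot."""
    out = []
    for rc in defs:
        try:
            ion_z = frame.coords[frame.index_of(rc.ion_id)][2]
        except KeyError:
            raise ValueError(f"ion {rc.ion_id!r} not present in frame") from None
        ref_z = [
            frame.coords[i][2]
            for i, role in enumerate(frame.roles)
            if role.kind == rc.source and role.tag == rc.reference_residue
        ]
        if not ref_z:
            raise ValueError(
                f"no {rc.source} atoms of {rc.reference_residue} in frame"
            )
        out.append(float(ion_z - np.mean(ref_z)))
    return tuple(out)
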