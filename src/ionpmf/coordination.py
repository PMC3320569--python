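"""Structural analyses of snapshots: coordination shells, axial bands, cavity water.

An ion's coordination shell is the set of oxygen atoms strictly closer than
a species-specific cutoff — 2.8 Å for Na⁺, 3.2 Å for K⁺ — partitioned by
their source: water molecules, protein backbone carbonyls, and the Glu177 /
Ser178 side chains that line the selectivity filter.  Radial displacement
from the pore axis is reported per axial band, with the bands delimited by
the carbonyl- and sidechain-oxygen rings of the filter residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frames import Frame

__all__ = [
    "CoordinationProfile",
    "Landmark",
    "AxialBandSpec",
    "default_band_spec",
    "coordination_shell",
    "xy_displacement",
    "cavity_water_count",
    "subsample_frames",
    "pore_axis_xy",
]

#: Coordination-shell cutoffs (Å) per ion species; membership is strict "<".
COORDINATION_CUTOFF = {"Na": 2.8, "K": 3.2}

_OXYGEN_KINDS = ("water-O", "backbone-carbonyl-O", "sidechain-O")


@dataclass
class CoordinationProfile:
    """Source-partitioned coordinating-oxygen counts for one ion."""

    ion_id: str
    species: str
    cutoff: float  # Å
    counts: dict  # keys: water, backbone, glu177_sidechain, ser178_sidechain, other_sidechain

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def coordination_shell(frame: Frame, ion_id) -> CoordinationProfile:
    """Count oxygen atoms strictly within the ion's species cutoff.

    The partition follows the filter chemistry: water, backbone carbonyls
    (any residue), the Glu177 side chain and the Ser178 side chain; sidechain
    oxygens of any other residue land in ``other_sidechain`` so that the
    total always equals the sum over sources.
    """
    idx = frame.index_of(ion_id)
    role = frame.roles[idx]
    if role.kind != "ion":
        raise ValueError(f"{ion_id!r} is not an ion")
    if role.tag not in COORDINATION_CUTOFF:
        raise ValueError(f"no coordination cutoff defined for species {role.tag!r}")
    cutoff = COORDINATION_CUTOFF[role.tag]
    center = frame.coords[idx]
    counts = {
        "water": 0,
        "backbone": 0,
        "glu177_sidechain": 0,
        "ser178_sidechain": 0,
        "other_sidechain": 0,
    }
    for i, r in enumerate(frame.roles):
        if r.kind not in _OXYGEN_KINDS:
            continue
        if np.linalg.norm(frame.coords[i] - center) < cutoff:
            if r.kind == "water-O":
                counts["water"] += 1
            elif r.kind == "backbone-carbonyl-O":
                counts["backbone"] += 1
            elif r.tag == "GLU177":
                counts["glu177_sidechain"] += 1
            elif r.tag == "SER178":
                counts["ser178_sidechain"] += 1
            else:
                counts["other_sidechain"] += 1
    return CoordinationProfile(
        ion_id=ion_id, species=role.tag, cutoff=cutoff, counts=counts
    )


@dataclass(frozen=True)
class Landmark:
    """An axial position: mean z of a residue's oxygen ring, plus an offset."""

    residue: str  # e.g. "THR175"
    source: str = "backbone-carbonyl-O"  # or "sidechain-O"
    offset: float = 0.0  # Å

    def resolve(self, frame: Frame) -> float:
        sel = frame.select(self.source, self.residue.upper())
        if sel.size == 0:
            raise ValueError(
                f"landmark {self.residue} ({self.source}) resolves to no atoms"
            )
        return float(frame.coords[sel, 2].mean() + self.offset)


@dataclass(frozen=True)
class AxialBandSpec:
    """Ordered, contiguous axial bands delimited by landmark pairs."""

    bands: tuple  # of (label, lower Landmark, upper Landmark)

    def resolve(self, frame: Frame) -> list:
        out = []
        prev_hi = None
        for label, lo, hi in self.bands:
            z_lo, z_hi = lo.resolve(frame), hi.resolve(frame)
            if z_hi <= z_lo:
                raise ValueError(f"band {label!r} has non-positive height")
            if prev_hi is not None and abs(z_lo - prev_hi) > 1e-9:
                raise ValueError(f"band {label!r} is not contiguous with its predecessor")
            out.append((label, z_lo, z_hi))
            prev_hi = z_hi
        return out


def default_band_spec() -> AxialBandSpec:
    """The four standard filter bands:

    A — Thr175 carbonyl ring up to the Leu176 carbonyl ring;
    B — Leu176 carbonyl ring to 3 Å above it;
    C — 3 Å above Leu176 carbonyls to 1 Å below the Glu177 sidechain oxygens;
    D — 1 Å below to 1 Å above the Glu177 sidechain oxygens.
    """
    return AxialBandSpec(
        bands=(
            ("A", Landmark("THR175"), Landmark("LEU176")),
            ("B", Landmark("LEU176"), Landmark("LEU176", offset=3.0)),
            ("C", Landmark("LEU176", offset=3.0), Landmark("GLU177", "sidechain-O", -1.0)),
            ("D", Landmark("GLU177", "sidechain-O", -1.0), Landmark("GLU177", "sidechain-O", 1.0)),
        )
    )


def pore_axis_xy(frame: Frame) -> tuple:
    """Default pore axis: z line through the backbone-carbonyl-O centroid."""
    sel = frame.select("backbone-carbonyl-O")
    if sel.size == 0:
        return (0.0, 0.0)
    c = frame.coords[sel].mean(axis=0)
    return (float(c[0]), float(c[1]))


def xy_displacement(
    frame: Frame,
    ion_id,
    axis_xy: Optional[tuple] = None,
    band_spec: Optional[AxialBandSpec] = None,
):
    """Radial distance of an ion from the pore axis, with its axial band.

    Returns (radial distance Å, band label); the label is ``"outside"`` when
    the ion's z falls outside every band.  Bands are half-open [lo, hi).
    """
    idx = frame.index_of(ion_id)
    x, y, z = frame.coords[idx]
    if axis_xy is None:
        axis_xy = pore_axis_xy(frame)
    r = float(np.hypot(x - axis_xy[0], y - axis_xy[1]))
    if band_spec is None:
        band_spec = default_band_spec()
    label = "outside"
    for name, z_lo, z_hi in band_spec.resolve(frame):
        if z_lo <= z < z_hi:
            label = name
            break
    return r, label


def cavity_water_count(
    frame: Frame,
    z_range: Sequence[float],
    radial_cutoff: float = 6.0,
    axis_xy: Optional[tuple] = None,
) -> int:
    """Number of water oxygens inside an axial slab within a radial cutoff.

    The slab is half-open in z ([lo, hi)); radial membership is strict.
    The conventional cavity is the slab from 8 Å below the Thr175 carbonyl
    ring up to the ring, with a 6 Å radial cutoff.
    """
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    if axis_xy is None:
        axis_xy = pore_axis_xy(frame)
    sel = frame.select("water-O")
    if sel.size == 0:
        return 0
    xyz = frame.coords[sel]
    in_slab = (xyz[:, 2] >= z_lo) & (xyz[:, 2] < z_hi)
    r = np.hypot(xyz[:, 0] - axis_xy[0], xyz[:, 1] - axis_xy[1])
    return int(np.sum(in_slab & (r < radial_cutoff)))


def subsample_frames(
    trajectory: Sequence[Frame], stride: float = 20.0, t_start: float = 50.0
) -> list:
    """Pick frames at times t_start, t_start+stride, … by nearest matching.

    A target time is matched to the nearest available frame if it lies
    within half the trajectory's native stride; the sequence ends at the
    last frame time.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    if not trajectory:
        raise ValueError("empty trajectory")
    times = np.array([f.time for f in trajectory])
    order = np.argsort(times)
    times = times[order]
    native = np.median(np.diff(times)) if len(times) > 1 else stride
    if t_start > times[-1] + native / 2:
        raise ValueError(f"t_start={t_start} ps is beyond the last frame ({times[-1]} ps)")
    out = []
    t = t_start
    while t <= times[-1] + native / 2:
        i = int(np.argmin(np.abs(times - t)))
        if abs(times[i] - t) <= native / 2:
            out.append(trajectory[order[i]])
        t += stride
    if not out:
        raise ValueError("no frames selected")
    return out
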