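"""Shared fixtures: synthetic landscapes, sampled protocols, structure frames."""

import numpy as np
import pytest

from ionpmf.frames import (
    backbone_oxygen,
    generate_structure_fixture,
    ion,
    sidechain_oxygen,
    water_oxygen,
)
from ionpmf.langevin import SamplerConfig, sample_windows
from ionpmf.surfaces import make_double_well_1d, make_two_ion_surface_2d
from ionpmf.umbrella import build_windows_1d, discard_equilibration


@pytest.fixture(scope="session")
def double_well():
    """Standard asymmetric double well (barrier 3, ΔG 1) on the 1D protocol domain."""
    return make_double_well_1d(
        centers=(-3.0, 3.0), barrier=3.0, asymmetry=1.0, bounds=(-7.0, 16.0)
    )


@pytest.fixture(scope="session")
def symmetric_well_2d():
    return make_two_ion_surface_2d((0.0, 0.0), (6.0, 6.0), barrier=3.0)


@pytest.fixture(scope="session")
def protocol_windows_1d(double_well):
    """One realization of the 20-window 1D protocol, equilibration discarded."""
    biases = build_windows_1d(-5.0, 14.0, 1.0, 10.0)
    windows = sample_windows(double_well, biases, SamplerConfig(seed=1))
    return [discard_equilibration(w, 50.0) for w in windows]


def _ring(residue, kind, z, radius=2.3):
    """Four oxygens of one filter ring, square-symmetric around the z axis."""
    maker = backbone_oxygen if kind == "backbone" else sidechain_oxygen
    out = []
    for j, (cx, cy) in enumerate([(1, 0), (0, 1), (-1, 0), (0, -1)]):
        out.append(
            (
                f"{residue}:{kind}:{j}",
                maker(residue),
                (radius * cx, radius * cy, z),
            )
        )
    return out


@pytest.fixture()
def filter_frame():
    """Minimal selectivity-filter snapshot: Thr175/Leu176 carbonyl rings,
    Glu177/Ser178 sidechain rings, one Na+ ion and a few waters."""
    spec = []
    spec += _ring("THR175", "backbone", 0.0)
    spec += _ring("LEU176", "backbone", 3.0)
    spec += _ring("GLU177", "sidechain", 8.0)
    spec += _ring("SER178", "sidechain", 10.0)
    spec.append(("NA1", ion("Na"), (0.3, 0.0, 5.0)))
    for j, z in enumerate([-2.0, -4.0, 6.0]):
        spec.append((f"W{j}", water_oxygen(), (0.5, 0.5, z)))
    return generate_structure_fixture(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2012)
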