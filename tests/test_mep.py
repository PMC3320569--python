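"""Interpolation, string-method paths, barrier algebra, minimax cross-checks."""

import numpy as np
import pytest

from ionpmf.surfaces import (
    AnalyticSurface,
    make_two_ion_surface_2d,
    tabulate_surface,
)
from ionpmf.mep import (
    OutsideMaskError,
    find_minima_and_barriers,
    grid_minimax_value,
    interpolate_surface,
    profile_along_path,
    string_mep,
)
from ionpmf.wham import PMFGrid


def quadratic_grid(bin_width=0.25, span=4.0):
    x = np.arange(-span, span + bin_width / 2, bin_width)
    y = np.arange(-span, span + bin_width / 2, bin_width)
    X, Y = np.meshgrid(x, y, indexing="ij")
    V = X**2 + Y**2
    return PMFGrid(
        centers=(x, y), values=V, mask=np.ones_like(V, bool),
        counts=np.full_like(V, 1e6),
    )


def curved_valley_surface():
    """Two-basin landscape with a repulsive bump that bends the MEP off the
    straight inter-minimum segment."""
    base = make_two_ion_surface_2d((0, 0), (6, 6), barrier=3.0, asymmetry=1.0)

    def value(p):
        d = p - np.array([3.2, 2.2])
        return base.value_nd(p) + 4.0 * np.exp(-np.sum(d**2, axis=-1) / 2.0)

    return AnalyticSurface(dim=2, bounds=base.bounds, _value=value, _gradient=None)


class TestInterpolation:
    def test_cubic_reproduces_quadratic_off_grid(self):
        s = interpolate_surface(quadratic_grid())
        rng = np.random.default_rng(1)
        pts = rng.uniform(-3.0, 3.0, size=(300, 2))
        exact = np.sum(pts**2, axis=1)
        assert np.max(np.abs(s.value(pts) - exact)) < 1e-6

    def test_grid_values_reproduced_exactly_at_centers(self):
        grid = quadratic_grid()
        s = interpolate_surface(grid)
        mesh = np.stack(np.meshgrid(*grid.centers, indexing="ij"), axis=-1)
        inner = mesh[1:-1, 1:-1].reshape(-1, 2)
        expect = grid.values[1:-1, 1:-1].ravel()
        assert np.max(np.abs(s.value(inner) - expect)) < 1e-9

    def test_gradient_consistent_with_value(self):
        s = interpolate_surface(quadratic_grid())
        pts = np.array([[0.3, -1.2], [1.7, 2.1], [-2.2, 0.4]])
        g = s.gradient(pts)
        h = 1e-5
        for d in range(2):
            e = np.zeros(2); e[d] = h
            fd = (s.value(pts + e) - s.value(pts - e)) / (2 * h)
            assert np.max(np.abs(g[:, d] - fd)) < 1e-4

    def test_query_in_masked_hole_raises(self):
        grid = quadratic_grid()
        i = len(grid.centers[0]) // 2
        grid.mask[i, i] = False
        grid.values[i, i] = np.nan
        s = interpolate_surface(grid)
        with pytest.raises(OutsideMaskError):
            s.value(np.array([[grid.centers[0][i], grid.centers[1][i]]]))

    def test_query_outside_grid_raises(self):
        s = interpolate_surface(quadratic_grid(span=2.0))
        with pytest.raises(OutsideMaskError):
            s.value(np.array([[10.0, 0.0]]))


class TestStringMethod:
    def test_symmetric_surface_path_on_diagonal(self, symmetric_well_2d):
        """Mirror symmetry about d2 = d1 forces the MEP onto the diagonal;
        the path maximum is the analytic saddle."""
        pmf = tabulate_surface(symmetric_well_2d, 0.25)
        path = string_mep(interpolate_surface(pmf), (0, 0), (6, 6))
        assert path.converged and path.final_rms < 1e-3
        off_diag = np.max(np.abs(path.nodes[:, 0] - path.nodes[:, 1])) / np.sqrt(2)
        assert off_diag < 0.25  # within one bin width
        assert path.free_energy.max() == pytest.approx(3.0, abs=0.2)

    def test_quadratic_bowl_gives_straight_polyline_through_minimum(self):
        """Steepest descent from two collinear endpoints of a bowl meets at
        the minimum, so the MEP is the straight segment through it."""
        s = interpolate_surface(quadratic_grid())
        path = string_mep(s, (-2.0, 0.0), (2.0, 0.0), relax_endpoints=False)
        assert path.converged
        assert np.max(np.abs(path.nodes[:, 1])) < 0.05
        assert s.value(path.nodes).min() == pytest.approx(0.0, abs=1e-3)

    def test_curved_valley_matches_minimax_oracle(self):
        """On a surface whose MEP bends, the string saddle agrees with the
        exhaustive grid-minimax oracle within 0.2 kcal/mol and the path
        clearly leaves the straight segment."""
        surf = curved_valley_surface()
        pmf = tabulate_surface(surf, 0.25)
        s = interpolate_surface(pmf)
        path = string_mep(s, (0, 0), (6, 6), max_iter=5000)
        assert path.converged and path.iterations < 5000
        mm = grid_minimax_value(
            surf.value_nd, path.nodes[0], path.nodes[-1], ((-2, 8), (-2, 8)), 0.05
        )
        assert path.free_energy.max() == pytest.approx(mm, abs=0.2)
        assert np.max(np.abs(path.nodes[:, 0] - path.nodes[:, 1])) / np.sqrt(2) > 0.5

    def test_converged_path_is_stationary(self, symmetric_well_2d):
        pmf = tabulate_surface(symmetric_well_2d, 0.25)
        s = interpolate_surface(pmf)
        path = string_mep(s, (0, 0), (6, 6))
        rerun = string_mep(
            s, tuple(path.nodes[0]), tuple(path.nodes[-1]), relax_endpoints=False
        )
        disp = np.sqrt(np.mean(np.sum((rerun.nodes - path.nodes) ** 2, axis=1)))
        assert disp < 2e-3

    def test_disconnected_endpoints_rejected(self):
        grid = quadratic_grid()
        mid = len(grid.centers[0]) // 2
        grid.mask[mid, :] = False
        grid.values[mid, :] = np.nan
        s = interpolate_surface(grid)
        with pytest.raises(ValueError, match="component"):
            string_mep(s, (-2.0, 0.0), (2.0, 0.0))


class TestProfileAlongPath:
    def test_constant_surface_gives_flat_profile(self):
        grid = quadratic_grid()
        grid.values[:] = 1.5
        s = interpolate_surface(grid)
        nodes = np.linspace((-2, -2), (2, 2), 50)
        arc, F, out_nodes = profile_along_path(s, nodes)
        assert np.allclose(F, 1.5, atol=1e-9)
        assert arc[0] == 0.0 and np.all(np.diff(arc) > 0)
        assert out_nodes.shape == (50, 2)

    def test_node_count_preserved(self, symmetric_well_2d):
        s = interpolate_surface(tabulate_surface(symmetric_well_2d, 0.25))
        path = string_mep(s, (0, 0), (6, 6), n_points=200)
        assert path.n_points == 200 and len(path.free_energy) == 200

    def test_symmetric_profile_mirror_symmetry(self, symmetric_well_2d):
        s = interpolate_surface(tabulate_surface(symmetric_well_2d, 0.25))
        path = string_mep(s, (0, 0), (6, 6))
        F = path.free_energy
        assert np.max(np.abs(F - F[::-1])) < 0.05

    def test_equal_arc_length_spacing(self, symmetric_well_2d):
        s = interpolate_surface(tabulate_surface(symmetric_well_2d, 0.25))
        path = string_mep(s, (0, 0), (6, 6))
        seg = np.diff(path.arc_length)
        assert np.max(np.abs(seg - seg.mean())) / seg.mean() < 1e-6


class TestBarrierReport:
    def test_direct_reading_of_three_point_profile(self):
        rep = find_minima_and_barriers(np.array([0.0, 2.0, 0.5]), prominence=0.1)
        assert [m[0] for m in rep.minima] == [0, 2]
        (pair,) = rep.pairs
        assert pair["forward"] == pytest.approx(2.0)
        assert pair["backward"] == pytest.approx(1.5)
        assert pair["delta_g"] == pytest.approx(0.5)

    def test_monotone_profile_has_no_pairs(self):
        rep = find_minima_and_barriers(np.linspace(0, 3, 30))
        assert rep.pairs == []

    def test_small_ripple_merged_by_prominence(self):
        F = np.array([0.0, 1.0, 0.97, 1.02, 2.0, 0.3])
        rep = find_minima_and_barriers(F, prominence=0.1)
        assert [m[0] for m in rep.minima] == [0, 5]

    def test_forward_minus_backward_equals_delta_g_exactly(self):
        rng = np.random.default_rng(7)
        F = np.cumsum(rng.normal(0, 0.5, 300))
        rep = find_minima_and_barriers(F, prominence=0.25)
        for pair in rep.pairs:
            assert pair["forward"] - pair["backward"] == pair["delta_g"]
            assert pair["forward"] >= 0 and pair["backward"] >= 0
            # the uphill direction carries at least the full ΔG
            assert pair["forward"] + 1e-12 >= max(0.0, pair["delta_g"])
            assert pair["backward"] + 1e-12 >= max(0.0, -pair["delta_g"])

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError):
            find_minima_and_barriers(np.array([0.0, 1.0]))


def test_valley_property_of_converged_path():
    """At interior nodes of a converged path the gradient component
    perpendicular to the path is small on average."""
    surf = curved_valley_surface()
    s = interpolate_surface(tabulate_surface(surf, 0.25))
    path = string_mep(s, (0, 0), (6, 6), max_iter=5000)
    nodes = path.nodes
    g = s.gradient(nodes)
    tang = np.gradient(nodes, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    g_perp = g - np.sum(g * tang, axis=1, keepdims=True) * tang
    mean_perp = np.mean(np.linalg.norm(g_perp[1:-1], axis=1))
    assert mean_perp < 0.1
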