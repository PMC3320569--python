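"""WHAM solver: exact reductions, an independent likelihood oracle, invariances.

The oracle used here parametrizes the *PMF values themselves* (one free
energy per bin, first bin gauged to zero) and maximizes the multinomial
likelihood of the observed per-window counts with a generic optimizer —
a code path completely separate from the solver's self-consistent
iteration over per-window constants.
"""

import numpy as np
import pytest
from scipy import optimize
from scipy.special import logsumexp

from ionpmf.constants import thermal_energy
from ionpmf.langevin import SamplerConfig, sample_window
from ionpmf.surfaces import make_double_well_1d
from ionpmf.umbrella import BiasPotential, UmbrellaWindow, bias_energy
from ionpmf.wham import (
    HistogramSet,
    WhamConnectivityError,
    align_pmf,
    histogram_windows,
    pmf_difference,
    solve_wham,
    wham_residual,
)


def direct_likelihood_pmf(h: HistogramSet) -> np.ndarray:
    """Oracle: maximize the multinomial window likelihood over bin free
    energies F_j directly (F_0 = 0 gauge).  Returns F on occupied bins."""
    kT = thermal_energy(h.temperature)
    centers = h.centers[0]
    occ = h.total_counts.ravel() > 0
    x = centers[occ]
    counts = h.counts.reshape(len(h.biases), -1)[:, occ]
    c = np.array([bias_energy(b, x) for b in h.biases])  # (n_w, n_bins)
    N = counts.sum(axis=1)

    N = counts.sum(axis=1)
    n_tot = counts.sum(axis=0)

    def nll(F_free):
        F = np.concatenate([[0.0], F_free])
        logits = -(F[None, :] + c) / kT
        log_p = logits - logsumexp(logits, axis=1, keepdims=True)
        val = -float(np.sum(counts * log_p))
        grad = (n_tot - N @ np.exp(log_p)) / kT
        return val, grad[1:]

    n = occ.sum()
    res = optimize.minimize(
        nll, np.zeros(n - 1), jac=True, method="L-BFGS-B",
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-11},
    )
    assert res.success or res.fun is not None
    return np.concatenate([[0.0], res.x])


def tiny_histogram(seed=0, n_windows=3, n_bins=12):
    """Small synthetic HistogramSet with overlapping windows."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    biases = [BiasPotential((c,), 8.0) for c in np.linspace(-0.5, 0.5, n_windows)]
    kT = thermal_energy(300.0)
    F_true = 2.0 * centers**2
    counts = np.zeros((n_windows, n_bins))
    for i, b in enumerate(biases):
        w = np.exp(-(F_true + bias_energy(b, centers)) / kT)
        counts[i] = rng.multinomial(400, w / w.sum())
    return HistogramSet(
        edges=(edges,), counts=counts,
        totals=counts.sum(axis=1), biases=biases, temperature=300.0,
    )


class TestExactReductions:
    def test_single_unbiased_window_reduces_to_empirical_estimator(self):
        """With one (effectively) unbiased window, WHAM must return exactly
        −kT ln(frequency) up to the zero shift, bin by bin."""
        rng = np.random.default_rng(3)
        samples = rng.normal(0.0, 0.8, size=2000)
        w = UmbrellaWindow(BiasPotential((0.0,), 1e-9), samples[:, None])
        pmf = solve_wham(histogram_windows([w], 0.2), tol=1e-12)
        h = histogram_windows([w], 0.2)
        counts = h.total_counts
        kT = thermal_energy(300.0)
        expected = -kT * np.log(counts[counts > 0] / counts.sum())
        expected -= expected.min()
        assert np.allclose(pmf.values[pmf.mask], expected, atol=1e-6)

    def test_coincident_windows_match_pooled_counts(self):
        rng = np.random.default_rng(4)
        bias = BiasPotential((0.1,), 5.0)
        a = UmbrellaWindow(bias, rng.normal(0.1, 0.4, 500)[:, None])
        b = UmbrellaWindow(bias, rng.normal(0.1, 0.4, 500)[:, None])
        pooled = UmbrellaWindow(bias, np.concatenate([a.samples, b.samples]))
        bounds = [(-2.0, 2.0)]
        split_pmf = solve_wham(histogram_windows([a, b], 0.2, bounds), tol=1e-12)
        pool_pmf = solve_wham(histogram_windows([pooled], 0.2, bounds), tol=1e-12)
        assert np.allclose(
            split_pmf.values[split_pmf.mask],
            pool_pmf.values[pool_pmf.mask],
            atol=1e-10,
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,n_windows,n_bins", [(0, 3, 12), (1, 2, 20), (2, 3, 8)])
    def test_matches_direct_likelihood_minimization(self, seed, n_windows, n_bins):
        h = tiny_histogram(seed, n_windows, n_bins)
        pmf = solve_wham(h, tol=1e-12)
        F_impl = pmf.values.ravel()[h.total_counts.ravel() > 0]
        F_oracle = direct_likelihood_pmf(h)
        # compare up to the gauge constant
        diff = (F_impl - F_impl[0]) - F_oracle
        diff -= diff.mean()  # compare up to the gauge constant
        assert np.max(np.abs(diff)) < 1e-6

    def test_self_consistency_residual_below_1e9(self):
        h = tiny_histogram(0)
        pmf = solve_wham(h, tol=1e-10)
        f = np.array(pmf.meta["window_free_energies"])
        assert wham_residual(h, f) < 1e-9


class TestInvariances:
    def test_window_reordering_leaves_pmf_unchanged(self, protocol_windows_1d):
        ws = protocol_windows_1d[:6]
        bounds = [(-7.0, 1.0)]
        a = solve_wham(histogram_windows(ws, 0.1, bounds))
        b = solve_wham(histogram_windows(ws[::-1], 0.1, bounds))
        assert np.allclose(
            a.values[a.mask], b.values[b.mask], atol=1e-6, equal_nan=True
        )

    def test_temperature_scales_unbiased_well_depth_linearly(self):
        rng = np.random.default_rng(8)
        samples = rng.normal(0.0, 0.5, 4000)[:, None]
        w = UmbrellaWindow(BiasPotential((0.0,), 1e-9), samples)
        bounds = [(-2.0, 2.0)]
        p300 = solve_wham(histogram_windows([w], 0.25, bounds, temperature=300.0))
        p600 = solve_wham(histogram_windows([w], 0.25, bounds, temperature=600.0))
        ratio = p600.values[p600.mask][p300.values[p300.mask] > 0.1] / \
            p300.values[p300.mask][p300.values[p300.mask] > 0.1]
        assert np.allclose(ratio, 2.0, atol=1e-6)

    def test_disconnected_coverage_raises_with_components(self):
        rng = np.random.default_rng(9)
        a = UmbrellaWindow(BiasPotential((-4.0,), 10.0), rng.normal(-4, 0.2, 300)[:, None])
        b = UmbrellaWindow(BiasPotential((4.0,), 10.0), rng.normal(4, 0.2, 300)[:, None])
        with pytest.raises(WhamConnectivityError) as exc:
            solve_wham(histogram_windows([a, b], 0.1))
        assert len(exc.value.components) == 2


class TestHistogramming:
    def test_half_open_binning(self):
        w = UmbrellaWindow(
            BiasPotential((0.0,), 1.0), np.array([[0.05], [0.15], [0.15]])
        )
        h = histogram_windows([w], 0.1, bounds=[(0.0, 0.5)])
        assert h.counts[0, 0] == 1 and h.counts[0, 1] == 2

    def test_sample_on_interior_edge_goes_right(self):
        w = UmbrellaWindow(BiasPotential((0.0,), 1.0), np.array([[0.1]]))
        h = histogram_windows([w], 0.1, bounds=[(0.0, 0.5)])
        assert h.counts[0, 1] == 1

    def test_total_counts_conserved(self, protocol_windows_1d):
        h = histogram_windows(protocol_windows_1d, 0.1)
        assert h.total_counts.sum() == 20 * 450

    def test_empty_window_list_rejected(self):
        with pytest.raises(ValueError):
            histogram_windows([], 0.1)


class TestAlignmentAndDifferences:
    def _pmf(self, values):
        from ionpmf.wham import PMFGrid

        v = np.asarray(values, dtype=float)
        return PMFGrid(
            centers=(np.arange(len(v), dtype=float),),
            values=v,
            mask=np.isfinite(v),
            counts=np.where(np.isfinite(v), 10.0, 0.0),
        )

    def test_min_zero_shift(self):
        p = align_pmf(self._pmf([2.0, 3.0, 5.0]), "min-zero")
        assert list(p.values) == [0.0, 1.0, 3.0]

    def test_min_zero_idempotent(self):
        p = align_pmf(self._pmf([0.0, 1.0, 3.0]), "min-zero")
        assert list(p.values) == [0.0, 1.0, 3.0]

    def test_anchor_shift(self):
        p = align_pmf(self._pmf([2.0, 3.0, 5.0]), "anchor", anchor=1)
        assert list(p.values) == [-1.0, 0.0, 2.0]

    def test_anchor_on_unsampled_bin_rejected(self):
        with pytest.raises(ValueError):
            align_pmf(self._pmf([2.0, np.nan, 5.0]), "anchor", anchor=1)

    def test_difference_antisymmetric_and_convention_free(self):
        p = self._pmf([2.0, 3.0, 5.0])
        assert pmf_difference(p, 2, 0) == pytest.approx(3.0)
        assert pmf_difference(p, 0, 2) == pytest.approx(-3.0)
        assert pmf_difference(p, 1, 1) == 0.0
        shifted = align_pmf(p, "anchor", anchor=2)
        assert pmf_difference(shifted, 2, 0) == pytest.approx(3.0)

    def test_difference_at_unsampled_bin_rejected(self):
        with pytest.raises(ValueError):
            pmf_difference(self._pmf([2.0, np.nan, 5.0]), 0, 1)


def test_recovery_improves_with_more_samples():
    """Average max-norm PMF error over well-sampled bins decreases when
    samples per window grow tenfold (450 → 4500)."""
    surf = make_double_well_1d(centers=(-2.0, 2.0), barrier=2.0, asymmetry=0.5,
                               width=0.8, bounds=(-6.0, 6.0))
    from ionpmf.langevin import sample_windows
    from ionpmf.umbrella import build_windows_1d, discard_equilibration

    biases = build_windows_1d(-4.0, 4.0, 1.0, 10.0)

    def recovery_error(n_total, seed):
        cfg = SamplerConfig(seed=seed, n_samples=n_total + 50)
        ws = [discard_equilibration(w, 50.0) for w in sample_windows(surf, biases, cfg)]
        pmf = solve_wham(histogram_windows(ws, 0.1))
        sel = pmf.counts >= 0.1 * n_total  # same relative occupancy cut
        x = pmf.centers[0][sel]
        d = pmf.values[sel] - surf.value(x)
        d -= d.mean()
        return np.max(np.abs(d))

    seeds = (21, 22, 23, 24, 25)
    small = np.mean([recovery_error(450, s) for s in seeds])
    large = np.mean([recovery_error(4500, s) for s in seeds])
    assert large < small
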