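"""Density maps and the MDF matrix against brute-force oracles, plus the
structural invariants of the correlation matrix and its std statistic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from mdflow import Recording
from mdflow.density import (
    GAUSS_TRUNCATE,
    WindowSpec,
    compute_bounds,
    density_map,
    density_stack,
    make_windows,
)
from mdflow.mdf import (
    ManifoldDensityFlow,
    MDFMatrix,
    complexity_profile,
    mdf_matrix,
    mdf_mean,
    mdf_std,
)

# ---------------------------------------------------------------- oracles


def oracle_density_map(comps, start, length, bounds, n_bins, smooth_sd):
    """Independent density map: per-point bin assignment, direct truncated
    Gaussian convolution with symmetric (reflect) padding, normalization."""
    d = comps.shape[0]
    hist = np.zeros((n_bins,) * d)
    for t in range(start, start + length):
        idx = []
        for k in range(d):
            lo, hi = bounds[k]
            frac = (comps[k, t] - lo) / (hi - lo)
            i = min(int(np.floor(frac * n_bins)), n_bins - 1)
            idx.append(max(i, 0))
        hist[tuple(idx)] += 1
    if smooth_sd > 0:
        radius = int(GAUSS_TRUNCATE * smooth_sd + 0.5)
        taps = np.exp(-0.5 * (np.arange(-radius, radius + 1) / smooth_sd) ** 2)
        taps /= taps.sum()
        for axis in range(d):
            padded = np.pad(
                hist, [(radius, radius) if a == axis else (0, 0) for a in range(d)],
                mode="symmetric",
            )
            out = np.zeros_like(hist)
            for off_i, w in enumerate(taps):
                sl = [slice(None)] * d
                sl[axis] = slice(off_i, off_i + n_bins)
                out += w * padded[tuple(sl)]
            hist = out
    return hist / hist.sum()


def oracle_pearson(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


# ---------------------------------------------------------------- windows


class TestMakeWindows:
    def test_basic_count(self):
        starts = make_windows(100, WindowSpec(50, 25))
        assert starts.tolist() == [0, 25, 50]

    def test_single_window_at_boundary(self):
        assert make_windows(50, WindowSpec(50, 25)).tolist() == [0]

    def test_trailing_partial_dropped(self):
        starts = make_windows(99, WindowSpec(50, 25))
        assert starts.tolist() == [0, 25]

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            make_windows(49, WindowSpec(50, 25))

    def test_seconds_conversion_matches_empirical_setting(self):
        # 15-s windows at 100 Hz are 1500 samples
        spec = WindowSpec.from_seconds(15.0, 0.1, 100.0)
        assert spec.length_samples == 1500
        assert spec.slide_samples == 10

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(1, 1)
        with pytest.raises(ValueError):
            WindowSpec(10, 0)


# ---------------------------------------------------------------- density


class TestDensityMap:
    def test_delta_input_blob_at_right_bin(self):
        comps = np.vstack([np.full(50, 0.31), np.full(50, -0.72)])
        # bounds wider than the data so they are not degenerate
        bounds = np.array([[-1.0, 1.0], [-1.0, 1.0]])
        dm = density_map(comps, (0, 50), bounds, n_bins=16, smooth_sd=1.5)
        assert dm.grid.sum() == pytest.approx(1.0, abs=1e-9)
        peak = np.unravel_index(np.argmax(dm.grid), dm.grid.shape)
        assert peak == (int((0.31 + 1) / 2 * 16), int((-0.72 + 1) / 2 * 16))

    def test_normalization(self, rng):
        comps = rng.normal(size=(2, 300))
        dm = density_map(comps, (0, 300), n_bins=32, smooth_sd=4.0)
        assert abs(dm.grid.sum() - 1.0) < 1e-9
        assert np.all(dm.grid >= 0)

    def test_matches_bruteforce_oracle_two_clusters(self, rng):
        comps = np.hstack(
            [rng.normal(-1, 0.2, size=(2, 60)), rng.normal(1, 0.2, size=(2, 60))]
        )
        bounds = compute_bounds(comps)
        dm = density_map(comps, (10, 80), bounds, n_bins=16, smooth_sd=2.0)
        expected = oracle_density_map(comps, 10, 80, bounds, 16, 2.0)
        assert np.abs(dm.grid - expected).max() <= 1e-10

    def test_matches_oracle_3d(self, rng):
        comps = rng.normal(size=(3, 200))
        bounds = compute_bounds(comps)
        dm = density_map(comps, (0, 200), bounds, n_bins=8, smooth_sd=1.0)
        expected = oracle_density_map(comps, 0, 200, bounds, 8, 1.0)
        assert np.abs(dm.grid - expected).max() <= 1e-10

    def test_window_outside_data_raises(self, rng):
        comps = rng.normal(size=(2, 100))
        with pytest.raises(ValueError):
            density_map(comps, (60, 50))

    def test_degenerate_bounds_raise(self):
        comps = np.vstack([np.zeros(100), np.linspace(0, 1, 100)])
        with pytest.raises(ValueError, match="degenerate"):
            compute_bounds(comps)


# ---------------------------------------------------------------- MDF


class TestMDFMatrix:
    def test_periodic_latent_gives_all_ones(self):
        period = 50
        base = np.vstack(
            [np.sin(2 * np.pi * np.arange(period) / period),
             np.cos(2 * np.pi * np.arange(period) / period)]
        )
        comps = np.tile(base, 8)  # 400 samples
        m = mdf_matrix(comps, WindowSpec(100, 50), n_bins=16, smooth_sd=2.0)
        assert_allclose(m.values, 1.0, atol=1e-12)

    def test_symmetry_and_diagonal(self, short_sim):
        m = mdf_matrix(short_sim.trajectory, WindowSpec(800, 400), n_bins=32, smooth_sd=4.0)
        assert np.array_equal(m.values, m.values.T)
        assert_allclose(np.diag(m.values), 1.0, atol=1e-12)
        assert m.values.min() >= -1 and m.values.max() <= 1

    def test_window_count_contract(self, short_sim):
        m = mdf_matrix(short_sim.trajectory, WindowSpec(800, 400))
        assert m.n_windows == (short_sim.trajectory.shape[1] - 800) // 400 + 1

    def test_matches_bruteforce_oracle(self, rng):
        comps = rng.normal(size=(2, 260)).cumsum(axis=1)  # wandering trajectory
        spec = WindowSpec(100, 50)  # 4 windows
        bounds = compute_bounds(comps)
        m = mdf_matrix(comps, spec, n_bins=16, smooth_sd=2.0)
        maps = [
            oracle_density_map(comps, s, 100, bounds, 16, 2.0)
            for s in (0, 50, 100, 150)
        ]
        for i in range(4):
            for j in range(4):
                expected = 1.0 if i == j else oracle_pearson(maps[i], maps[j])
                assert abs(m.values[i, j] - expected) <= 1e-10

    def test_histogram_rescaling_invariance(self, rng):
        """Pearson affine invariance: scaling all counts leaves MDF unchanged."""
        comps = rng.normal(size=(2, 300)).cumsum(axis=1)
        spec = WindowSpec(100, 100)
        bounds = compute_bounds(comps)
        maps = density_stack(comps, make_windows(300, spec), 100, bounds, 16, 2.0)
        flat = maps.reshape(len(maps), -1)
        from mdflow.mdf import _pearson_rows

        base = _pearson_rows(flat.copy())
        scaled = _pearson_rows(flat * 37.5)
        assert_allclose(scaled, base, atol=1e-12)


class TestMDFStatistics:
    def test_all_ones_matrix_std_zero(self):
        m = np.ones((4, 4))
        assert mdf_std(m) == 0.0

    def test_two_by_two_std_zero(self):
        m = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert mdf_std(m) == 0.0
        assert mdf_mean(m) == pytest.approx(0.3)

    def test_hand_computed_three_by_three(self):
        # upper entries (0.2, 0.4, 0.6): mean 0.4, population std sqrt(2/75)
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.2
        m[0, 2] = m[2, 0] = 0.4
        m[1, 2] = m[2, 1] = 0.6
        assert mdf_mean(m) == pytest.approx(0.4)
        assert mdf_std(m) == pytest.approx(0.16329931618554522, abs=1e-12)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            mdf_std(np.array([[1.0]]))

    @given(st.integers(min_value=2, max_value=8), st.integers(min_value=0, max_value=2**31 - 1))
    def test_std_bounds_property(self, n, seed):
        """Upper-triangle std of any correlation-valued matrix lies in [0, 1]."""
        r = np.random.default_rng(seed).uniform(-1, 1, size=(n, n))
        sym = (r + r.T) / 2
        np.fill_diagonal(sym, 1.0)
        assert 0.0 <= mdf_std(sym) <= 1.0


class TestComplexityProfile:
    def test_profile_shapes_and_positivity(self, small_recording):
        prof = complexity_profile(
            small_recording, [4.0, 8.0], 2.0, seed=0, n_bins=32, smooth_sd=2.0
        )
        assert sorted(prof) == [4.0, 8.0]
        assert all(v > 0 for v in prof.values())

    def test_constant_latent_is_degenerate(self):
        comps = np.full((2, 400), 0.7)
        with pytest.raises(ValueError, match="degenerate"):
            mdf_matrix(comps, WindowSpec(100, 100), n_bins=16, smooth_sd=2.0)

    def test_dead_channels_rejected_before_embedding(self):
        rec = Recording(data=np.zeros((4, 400)) + np.arange(4)[:, None], fs=100.0)
        with pytest.raises(ValueError, match="zero-variance"):
            complexity_profile(rec, [1.0], 0.5, seed=0, n_bins=16, smooth_sd=2.0)


class TestModelResults:
    def test_model_fit_summary_and_plots(self, small_recording):
        model = ManifoldDensityFlow(
            small_recording, window_length_s=8.0, slide_s=2.0, n_bins=32,
            smooth_sd=4.0, seed=0,
        )
        res = model.fit()
        assert res.std == pytest.approx(mdf_std(res.matrix))
        text = res.summary()
        assert "MDF std" in text and f"{res.std:.4f}" in text
        ax = res.plot_matrix()
        assert ax.images
        ax2 = res.plot_latent()
        assert ax2.lines

    def test_array_input_requires_fs(self, rng):
        with pytest.raises(ValueError, match="fs"):
            ManifoldDensityFlow(rng.normal(size=(4, 1000)))

    def test_mdfmatrix_validation(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            MDFMatrix(values=bad, window_starts=np.array([0, 1]), window_spec=WindowSpec(2, 1))
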