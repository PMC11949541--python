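"""Bistable-network simulator: drift, Heun scheme, reproducibility,
deterministic-limit accuracy, and noise-driven state statistics."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from mdflow.sim import (
    DEFAULT_NOISE_GRID,
    SimConfig,
    count_well_transitions,
    drift,
    heun_step,
    simulate,
)


def logistic_cubic_solution(t, x0):
    """Closed form of dx/dt = x - x^3: x(t) = x0 e^t / sqrt(1 + x0^2(e^2t - 1))."""
    et = np.exp(t)
    return x0 * et / np.sqrt(1.0 + x0**2 * (np.exp(2 * t) - 1.0))


class TestDrift:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (1.0, 0.0), (-1.0, 0.0), (0.5, 0.375), (-0.5, -0.375), (2.0, -6.0)],
    )
    def test_pointwise(self, x, expected):
        assert drift(np.array([x]))[0] == pytest.approx(expected, abs=1e-15)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            drift(np.array([np.nan]))


class TestHeunStep:
    def test_fixed_point_is_exact(self):
        out = heun_step(np.array([1.0, -1.0]), 0.01, 0.0, np.zeros(2))
        assert_allclose(out, [1.0, -1.0], rtol=0, atol=0)

    def test_matches_hand_computed_two_stage_value(self):
        # x=0.5, dt=0.01, no noise: f0=0.375, predictor=0.50375,
        # f1=(1-0.50375^2)*0.50375, corrector = 0.5 + (f0+f1)*dt/2
        x, dt = 0.5, 0.01
        f0 = (1 - x**2) * x
        xp = x + f0 * dt
        f1 = (1 - xp**2) * xp
        expected = x + 0.5 * (f0 + f1) * dt
        out = heun_step(np.array([x]), dt, 0.0, np.zeros(1))
        assert_allclose(out, [expected], rtol=0, atol=1e-16)

    def test_zero_increment_equals_noiseless(self):
        x = np.array([0.3, -0.7])
        a = heun_step(x, 0.01, 0.5, np.zeros(2))
        b = heun_step(x, 0.01, 0.0, np.zeros(2))
        assert_allclose(a, b, rtol=0, atol=0)

    def test_rejects_bad_dt(self):
        with pytest.raises(ValueError):
            heun_step(np.array([0.0]), -0.01, 0.1, np.zeros(1))

    def test_kernel_agrees_with_reference_step(self):
        """The compiled path must reproduce the reference Heun arithmetic."""
        cfg = SimConfig(n_vars=3, noise_sigma=0.3, dt=0.01, t_end=0.5, seed=5)
        res = simulate(cfg)
        rng = np.random.default_rng(5)
        x = rng.choice(np.array([-1.0, 1.0]), size=3)
        dW = rng.normal(0.0, np.sqrt(0.01), size=(cfg.n_samples - 1, 3))
        for k in range(cfg.n_samples - 1):
            x = heun_step(x, 0.01, 0.3, dW[k])
        assert_allclose(x, res.trajectory[:, -1], rtol=0, atol=1e-13)


class TestSimulate:
    def test_sample_count_contract(self):
        cfg = SimConfig(n_vars=1, noise_sigma=0.1, dt=0.01, t_end=5.0, seed=0)
        assert simulate(cfg).trajectory.shape == (1, 500)

    def test_fixed_point_stays_fixed(self):
        cfg = SimConfig(
            n_vars=3, noise_sigma=0.0, dt=0.01, t_end=2.0, seed=0, x0=np.ones(3)
        )
        assert_allclose(simulate(cfg).trajectory, 1.0, rtol=0, atol=0)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_vars=2, noise_sigma=0.3, dt=0.01, t_end=5.0, seed=9)
        a = simulate(cfg).trajectory
        b = simulate(cfg).trajectory
        assert np.array_equal(a, b)

    def test_deterministic_limit_matches_closed_form(self):
        cfg = SimConfig(
            n_vars=1, noise_sigma=0.0, dt=0.01, t_end=10.0, seed=0, x0=np.array([0.1])
        )
        res = simulate(cfg)
        exact = logistic_cubic_solution(res.times, 0.1)
        assert np.max(np.abs(res.trajectory[0] - exact)) < 1e-4

    def test_heun_error_is_second_order(self):
        """Halving dt reduces the max error against the closed form ~4x."""
        errs = {}
        for dt in (0.01, 0.005):
            cfg = SimConfig(
                n_vars=1, noise_sigma=0.0, dt=dt, t_end=10.0, seed=0, x0=np.array([0.1])
            )
            res = simulate(cfg)
            exact = logistic_cubic_solution(res.times, 0.1)
            errs[dt] = np.max(np.abs(res.trajectory[0] - exact))
        ratio = errs[0.01] / errs[0.005]
        assert 3.0 < ratio < 5.0

    def test_burn_in_discards_transient(self):
        cfg = SimConfig(
            n_vars=1, noise_sigma=0.0, dt=0.01, t_end=1.0, seed=0,
            x0=np.array([0.1]), burn_in=10.0,
        )
        # after 10 time units the deterministic orbit has converged to +1
        traj = simulate(cfg).trajectory
        assert traj.shape == (1, 100)
        assert np.all(np.abs(traj - 1.0) < 1e-3)

    def test_orthant_coverage_scales_with_n_vars(self):
        """Moderate noise visits all 2^N sign patterns in a long run."""
        for n in (2, 3):
            res = simulate(SimConfig(n_vars=n, noise_sigma=0.35, dt=0.01, t_end=300.0, seed=1))
            signs = (res.trajectory > 0).astype(int)
            codes = np.zeros(signs.shape[1], dtype=int)
            for i in range(n):
                codes = codes * 2 + signs[i]
            assert len(np.unique(codes)) == 2**n

    def test_transition_rate_monotone_in_noise(self):
        """Mean up/down switching rate rises with sigma (20 seeds)."""
        mean_counts = []
        for sigma in DEFAULT_NOISE_GRID:
            counts = [
                count_well_transitions(
                    simulate(
                        SimConfig(n_vars=2, noise_sigma=sigma, dt=0.01, t_end=50.0, seed=s)
                    ).trajectory
                ).mean()
                for s in range(20)
            ]
            mean_counts.append(np.mean(counts))
        assert mean_counts[0] < mean_counts[1] < mean_counts[2]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_vars=0, noise_sigma=0.1),
            dict(n_vars=1, noise_sigma=-0.1),
            dict(n_vars=1, noise_sigma=0.1, dt=-0.01),
            dict(n_vars=1, noise_sigma=0.1, dt=0.01, t_end=0.005),
            dict(n_vars=2, noise_sigma=0.1, x0=np.zeros(3)),
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**{"dt": 0.01, "t_end": 1.0, **kwargs})
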