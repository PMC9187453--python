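"""Smoothed-L0 surrogate, energy/gradient consistency, and the solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sl0ct import (DivergenceError, ImageGrid, NoiseModel, ScanGeometry,
                   SL0Params, Sinogram, abdominal_phantom, add_noise,
                   build_projection_operator, el_residual, energy,
                   fbp_reconstruct, forward_project, l0art_reconstruct,
                   lambda_weights, smoothed_l0_sum, smoothed_l0_value,
                   std_metric)
from sl0ct.l0art import sl0_recover


class TestSurrogate:
    def test_zero_argument_gives_zero(self):
        assert smoothed_l0_value(0.0, 2.3) == 0.0

    def test_closed_form_at_t_equals_beta(self):
        assert smoothed_l0_value(1.0, 1.0) == pytest.approx(
            1.0 - np.exp(-0.5), abs=1e-12)

    def test_limit_is_one_far_from_zero(self):
        assert smoothed_l0_value(100.0, 1.0) == pytest.approx(1.0, abs=1e-10)

    def test_sum_approaches_counting_norm(self):
        assert smoothed_l0_sum([2.0, 0.0, 0.0], 1e-3) == pytest.approx(
            1.0, abs=1e-10)

    def test_sum_of_zero_vector_is_zero(self):
        assert smoothed_l0_sum(np.zeros(5), 0.1) == 0.0
        assert smoothed_l0_sum(np.empty(0), 0.1) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_sum_monotone_as_beta_decreases(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.normal(size=20)
        betas = [2.0, 1.0, 0.5, 0.1, 0.01]
        sums = [smoothed_l0_sum(coeffs, b) for b in betas]
        assert all(a <= b + 1e-12 for a, b in zip(sums, sums[1:]))

    def test_sum_bounded_by_counting_norm(self, rng):
        coeffs = rng.normal(size=50)
        coeffs[rng.random(50) < 0.5] = 0.0
        for beta in (1e-3, 0.1, 10.0):
            assert smoothed_l0_sum(coeffs, beta) <= \
                np.count_nonzero(coeffs) + 1e-12

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            smoothed_l0_value(1.0, 0.0)
        with pytest.raises(ValueError):
            lambda_weights([1.0], -1.0)


class TestLambdaWeights:
    def test_analytic_limit_at_zero(self):
        beta = 0.37
        assert lambda_weights(0.0, beta) == pytest.approx(1 / beta ** 2)

    def test_closed_form_at_t_equals_beta(self):
        assert lambda_weights(1.0, 1.0) == pytest.approx(np.exp(-0.5))

    def test_monotone_decreasing_in_magnitude(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 5.0])
        w = lambda_weights(t, 0.8)
        assert np.all(np.diff(w) < 0)
        assert np.all((w > 0) & (w <= 1 / 0.8 ** 2))


class TestEnergyAndResidual:
    def test_zero_image_zero_data_zero_energy(self, tiny_system):
        params = SL0Params(transform="gradient")
        n, m = tiny_system.n_pixels, tiny_system.n_rays
        assert energy(np.zeros(n), np.zeros(m), tiny_system, params, 1.0) == 0

    def test_constant_image_consistent_data_zero_energy(self, tiny_system):
        params = SL0Params(transform="gradient")
        x = np.full(tiny_system.n_pixels, 2.5)
        p = tiny_system.matrix @ x
        assert energy(x, p, tiny_system, params, 1.0) == pytest.approx(0.0)
        r = el_residual(x, p, tiny_system, params, 1.0)
        assert np.max(np.abs(r)) < 1e-12

    def test_energy_matches_termwise_computation(self, tiny_system, rng):
        params = SL0Params(transform="gradient", kappa=0.6)
        x = rng.normal(size=tiny_system.n_pixels)
        p = rng.normal(size=tiny_system.n_rays)
        beta = 0.4
        # independent term-by-term evaluation
        v = x.reshape(8, 8)
        gx = np.diff(v, axis=1, append=v[:, -1:]).ravel()
        gy = np.diff(v, axis=0, append=v[-1:, :]).ravel()
        coeffs = np.concatenate([gx, gy])
        expected = sum(1.0 - np.exp(-c * c / (2 * beta * beta))
                       for c in coeffs)
        resid = tiny_system.matrix @ x - p
        expected += 0.6 * sum(r * r for r in resid)
        assert energy(x, p, tiny_system, params, beta) == pytest.approx(
            expected, rel=1e-12)

    @pytest.mark.parametrize("transform", ["gradient", "identity"])
    def test_residual_matches_finite_differences(self, tiny_system, rng,
                                                 transform):
        params = SL0Params(transform=transform, kappa=0.7)
        x = rng.normal(size=tiny_system.n_pixels)
        p = rng.normal(size=tiny_system.n_rays)
        beta = 0.5
        r = el_residual(x, p, tiny_system, params, beta)
        h = 1e-6
        for _ in range(5):
            d = rng.normal(size=x.size)
            d /= np.linalg.norm(d)
            fd = (energy(x + h * d, p, tiny_system, params, beta)
                  - energy(x - h * d, p, tiny_system, params, beta)) / (2 * h)
            assert fd == pytest.approx(float(r @ d), rel=1e-4)

    def test_kappa_zero_residual_independent_of_data(self, tiny_system, rng):
        params = SL0Params(transform="gradient", kappa=0.0)
        x = rng.normal(size=tiny_system.n_pixels)
        p1 = rng.normal(size=tiny_system.n_rays)
        p2 = rng.normal(size=tiny_system.n_rays)
        r1 = el_residual(x, p1, tiny_system, params, 0.5)
        r2 = el_residual(x, p2, tiny_system, params, 0.5)
        assert np.array_equal(r1, r2)


@pytest.fixture(scope="module")
def ct_scan():
    ph = abdominal_phantom(64, seed=5)
    geom = ScanGeometry.uniform(30, 95)
    A = build_projection_operator(geom, 64)
    sino = add_noise(forward_project(A, ph),
                     NoiseModel(kind="gaussian", level=0.01, seed=42))
    return ph, A, sino


class TestSolver:
    def test_huge_outer_tolerance_runs_single_outer_iteration(self, ct_scan):
        _, A, sino = ct_scan
        _, state = l0art_reconstruct(A, sino, SL0Params(mu_outer=1e6))
        assert state.outer_index == 0

    def test_beta_anneals_geometrically(self, ct_scan):
        _, A, sino = ct_scan
        params = SL0Params(beta0=1.0, gamma=0.5, max_outer=6, mu_outer=1e-12)
        _, state = l0art_reconstruct(A, sino, params)
        expected = [0.5 ** (k + 1) for k in range(len(state.beta_trace))]
        assert state.beta_trace == pytest.approx(expected, rel=1e-12)
        assert all(b1 > b2 for b1, b2 in
                   zip(state.beta_trace, state.beta_trace[1:]))

    def test_energy_non_increasing_within_inner_loops(self, ct_scan):
        _, A, sino = ct_scan
        _, state = l0art_reconstruct(A, sino, SL0Params(max_outer=5))
        by_outer = {}
        for entry in state.log:
            by_outer.setdefault(entry["outer"], []).append(entry["energy"])
        for energies in by_outer.values():
            assert all(a >= b - 1e-12 for a, b in zip(energies, energies[1:]))

    def test_deterministic(self, ct_scan):
        _, A, sino = ct_scan
        img1, _ = l0art_reconstruct(A, sino, SL0Params(max_outer=3))
        img2, _ = l0art_reconstruct(A, sino, SL0Params(max_outer=3))
        assert np.array_equal(img1.values, img2.values)

    def test_all_zero_sinogram_returns_zero_image(self, ct_scan):
        _, A, sino = ct_scan
        zero = Sinogram(np.zeros_like(sino.values), sino.geometry)
        img, _ = l0art_reconstruct(A, zero)
        assert not np.any(img.values)

    def test_beats_fbp_on_sparse_noisy_views(self, ct_scan):
        """The headline comparison: lower STD than FBP on the same data."""
        ph, A, sino = ct_scan
        l0, _ = l0art_reconstruct(A, sino)
        fbp = fbp_reconstruct(sino, 64)
        assert std_metric(l0, ph) < std_metric(fbp, ph)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SL0Params(gamma=1.5)
        with pytest.raises(ValueError):
            SL0Params(beta0=-1.0)
        with pytest.raises(ValueError):
            SL0Params(transform="wavelet")


class TestSparseRecovery:
    def make_instance(self, seed, n=20, m=50, k=3):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(n, m)) / np.sqrt(n)
        support = np.sort(rng.choice(m, size=k, replace=False))
        x_true = np.zeros(m)
        x_true[support] = rng.uniform(0.5, 1.5, size=k)
        return M, x_true, support

    @pytest.mark.parametrize("seed", [42, 7])
    def test_recovers_exact_support_and_values(self, seed):
        M, x_true, support = self.make_instance(seed)
        x_hat, _ = sl0_recover(M, M @ x_true)
        top = np.sort(np.argsort(-np.abs(x_hat))[:3])
        assert np.array_equal(top, support)
        assert np.max(np.abs(x_hat - x_true)) < 1e-4

    def test_projection_keeps_measurements_consistent(self, rng):
        """Orthonormal rows: every accepted iterate stays on A x = p."""
        Q, _ = np.linalg.qr(rng.normal(size=(50, 20)))
        M = Q.T  # 20 x 50 with orthonormal rows
        x_true = np.zeros(50)
        x_true[[3, 30, 44]] = [1.0, -0.8, 1.2]
        p = M @ x_true
        x_hat, _ = sl0_recover(M, p)
        assert np.linalg.norm(M @ x_hat - p) < 1e-8

    def test_divergence_error_carries_trace(self, rng):
        # an absurdly large step factor forces energy increase every step
        M = rng.normal(size=(5, 9))
        p = rng.normal(size=5)
        params = SL0Params(transform="identity", step_size=1e9,
                           beta0=1.0, gamma=0.9, max_outer=8)
        with pytest.raises(DivergenceError):
            sl0_recover(M, p, params, x0=rng.normal(size=9))
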