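"""Noise covariance, depth weighting, wMNE/dSPM/sLORETA, GCV, application."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.base import clone

from conftest import tetrahedron_space
from slmcompare.forward import LeadField
from slmcompare.inverse import (
    InverseSolver,
    NoiseCovariance,
    apply_inverse,
    depth_weights,
    dspm_operator,
    estimate_noise_covariance,
    gcv_alpha,
    mne_operator,
    resolution_matrix,
    sloreta_operator,
    wmne_operator,
)


def small_lead_field(matrix: np.ndarray, n_electrode_names: int | None = None) -> LeadField:
    """Wrap an arbitrary (N_e, 12) matrix over a 4-vertex space."""
    space = tetrahedron_space()
    n_e = matrix.shape[0]
    return LeadField(matrix, [f"ch{i}" for i in range(n_e)], space, average_reference=False)


class TestNoiseCovariance:
    def test_tikhonov_loading_raises_trace_by_epsilon(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 50))
        raw = np.cov(data, bias=True)
        cov = estimate_noise_covariance(data, epsilon=0.1)
        assert np.trace(cov.matrix) == pytest.approx(1.1 * np.trace(raw))

    def test_hand_computed_two_channel_case(self):
        # alternating (+1, 0) / (-1, 0) samples: population covariance
        # [[1, 0], [0, 0]]; loading adds 0.1 * (1/2) to the diagonal
        data = np.array([[1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0]])
        cov = estimate_noise_covariance(data, epsilon=0.1)
        np.testing.assert_allclose(cov.matrix, [[1.05, 0.0], [0.0, 0.05]])
        assert np.linalg.eigvalsh(cov.matrix).min() == pytest.approx(0.05)

    def test_identity_recovered_from_white_noise(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 200_000))
        cov = estimate_noise_covariance(data, epsilon=0.0)
        np.testing.assert_allclose(cov.matrix, np.eye(3), atol=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            estimate_noise_covariance(np.zeros((8, 5)))

    def test_segments_are_concatenated(self):
        rng = np.random.default_rng(2)
        parts = [rng.normal(size=(3, 40)) for _ in range(3)]
        whole = estimate_noise_covariance(np.concatenate(parts, axis=1))
        chunks = estimate_noise_covariance(parts)
        np.testing.assert_allclose(whole.matrix, chunks.matrix)


class TestDepthWeights:
    def test_unit_norm_triple(self):
        m = np.zeros((3, 12))
        m[0, 0] = m[1, 1] = m[2, 2] = 1.0  # vertex 0: three unit columns
        m[0, 3:12:1] = np.tile([1, 0, 0], 3)  # keep other vertices non-zero
        w = depth_weights(small_lead_field(m), gamma=0.5, limit=1e9)
        assert w.values[0] == pytest.approx(3 ** -0.5)

    def test_cap_rule(self):
        m = np.zeros((2, 12))
        # squared column-norm sums per vertex: 400, 1, 1, 1
        m[0, 0] = 20.0
        m[0, [3, 6, 9]] = 1.0
        w = depth_weights(small_lead_field(m), gamma=0.5, limit=10.0)
        # raw weights 1/20 and 1 -> ratio 20, capped to 10
        assert w.values.max() / w.values.min() == pytest.approx(10.0)
        assert w.values[0] == pytest.approx(1 / 20)

    def test_gamma_zero_gives_unit_weights(self, lead162):
        w = depth_weights(lead162, gamma=0.0)
        np.testing.assert_allclose(w.values, 1.0)

    def test_zero_column_triple_rejected(self):
        m = np.zeros((2, 12))
        m[0, [0, 3, 6]] = 1.0  # vertex 3 all-zero
        with pytest.raises(ValueError, match="vertices"):
            depth_weights(small_lead_field(m))


class TestMinimumNorm:
    def test_identity_system_small_alpha(self):
        lf = small_lead_field(np.eye(12))
        cov = NoiseCovariance(np.eye(12))
        g = wmne_operator(lf, cov, None, alpha=1e-10).matrix
        np.testing.assert_allclose(g, np.eye(12), atol=1e-8)

    def test_heavy_regularization_shrinks_operator(self):
        rng = np.random.default_rng(3)
        lf = small_lead_field(rng.normal(size=(6, 12)))
        cov = NoiseCovariance(np.eye(6))
        g = wmne_operator(lf, cov, None, alpha=1e6).matrix
        assert np.linalg.norm(g) < 1e-3

    def test_estimate_minimizes_tikhonov_objective(self):
        rng = np.random.default_rng(4)
        L = rng.normal(size=(6, 12))
        lf = small_lead_field(L)
        cov_m = np.eye(6) * 0.5 + 0.05 * np.ones((6, 6))
        cov = NoiseCovariance(cov_m)
        w = depth_weights(lf, gamma=0.5)
        alpha = 0.8
        g = wmne_operator(lf, cov, w, alpha).matrix
        d = rng.normal(size=6)
        s_hat = g @ d
        ci = np.linalg.inv(cov_m)
        penalty = np.repeat(1.0 / w.values, 3)

        def objective(s):
            r = d - L @ s
            return r @ ci @ r + alpha * np.sum(penalty * s**2)

        base = objective(s_hat)
        for _ in range(1000):
            delta = rng.normal(scale=0.01, size=12)
            assert objective(s_hat + delta) >= base - 1e-12

    def test_wmne_with_unit_weights_equals_mne(self, lead162):
        cov = NoiseCovariance(np.eye(32))
        from slmcompare.inverse import DepthWeights

        unit = DepthWeights(np.ones(lead162.n_sources))
        np.testing.assert_array_equal(
            wmne_operator(lead162, cov, unit, 0.5).matrix,
            mne_operator(lead162, cov, 0.5).matrix,
        )

    def test_matches_independent_tikhonov_solver(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(8, 12))
        lf = small_lead_field(L)
        cov_m = np.cov(rng.normal(size=(8, 100)), bias=True) + 0.5 * np.eye(8)
        cov = NoiseCovariance(cov_m)
        w = depth_weights(lf)
        alpha = 0.3
        g = wmne_operator(lf, cov, w, alpha).matrix
        cs_inv = np.diag(np.repeat(1.0 / w.values, 3))
        ci = np.linalg.inv(cov_m)
        g_normal = np.linalg.solve(L.T @ ci @ L + alpha * cs_inv, L.T @ ci)
        np.testing.assert_allclose(g, g_normal, rtol=1e-8, atol=1e-12)

    def test_alpha_monotonically_shrinks_estimates(self, lead162):
        rng = np.random.default_rng(6)
        cov = NoiseCovariance(np.eye(32))
        d = rng.normal(size=32)
        norms = []
        for alpha in np.logspace(-4, 2, 8):
            g = mne_operator(lead162, cov, alpha).matrix
            norms.append(np.linalg.norm(g @ (d - d.mean())))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))


class TestGCV:
    def test_noiseless_consistent_data_falls_back(self, lead162):
        s = np.zeros(3 * lead162.n_sources)
        s[3 * 50] = 4.0
        d = lead162.matrix @ s
        assert gcv_alpha(lead162, d, NoiseCovariance(np.eye(32))) == pytest.approx(1 / 3)

    def test_singleton_grid(self, lead162):
        rng = np.random.default_rng(7)
        d = rng.normal(size=32)
        assert gcv_alpha(lead162, d, NoiseCovariance(np.eye(32)), grid=np.array([0.5])) == 0.5

    def test_matches_exhaustive_dense_evaluation(self, lead162):
        rng = np.random.default_rng(8)
        s = np.zeros(3 * lead162.n_sources)
        s[3 * 50] = 4.0
        d = (lead162.matrix @ s)[:, None] + rng.normal(scale=0.05, size=(32, 3))
        cov = NoiseCovariance(np.eye(32) * 0.7)
        grid = np.logspace(-3, 1, 12)
        got = gcv_alpha(lead162, d, cov, grid=grid, fallback_below=0.0)
        # dense oracle: build H explicitly per grid point
        white = cov.inv_sqrt()
        k = white @ lead162.matrix
        dt = white @ d
        scores = []
        for a in grid:
            h = k @ k.T @ np.linalg.inv(k @ k.T + a * np.eye(32))
            resid = np.linalg.norm(dt - h @ dt) ** 2
            scores.append(resid / np.trace(np.eye(32) - h) ** 2)
        assert got == grid[int(np.argmin(scores))]

    def test_zero_data_rejected(self, lead162):
        with pytest.raises(ValueError, match="zero"):
            gcv_alpha(lead162, np.zeros(32), NoiseCovariance(np.eye(32)))


class TestDSPM:
    def test_row_scaling_hand_case(self):
        # identity noise covariance; one point's combined squared row norm 4
        g = np.zeros((12, 6))
        g[0, 0] = 2.0  # vertex 0: sum over its 3 rows of |g|^2 = 4
        g[3:, 0] = 1.0  # keep remaining vertices non-degenerate
        from slmcompare.inverse import InverseOperator

        base = InverseOperator(g, "wmne", alpha=0.1, average_reference=False)
        cov = NoiseCovariance(np.eye(6))
        ds = dspm_operator(base, cov)
        np.testing.assert_allclose(ds.matrix[0], g[0] / 2.0)

    def test_unit_noise_variance_after_normalization(self, lead162):
        cov = estimate_noise_covariance(np.random.default_rng(9).normal(size=(32, 200)))
        base = wmne_operator(lead162, cov, depth_weights(lead162), 0.5)
        ds = dspm_operator(base, cov)
        gq = ds.matrix @ cov.matrix
        var = (gq * ds.matrix).sum(axis=1).reshape(-1, 3).sum(axis=1)
        np.testing.assert_allclose(var, 1.0, rtol=1e-10)

    def test_rows_keep_their_direction(self, lead162):
        cov = NoiseCovariance(np.eye(32))
        base = wmne_operator(lead162, cov, depth_weights(lead162), 0.5)
        ds = dspm_operator(base, cov)
        cos = (ds.matrix * base.matrix).sum(axis=1) / (
            np.linalg.norm(ds.matrix, axis=1) * np.linalg.norm(base.matrix, axis=1)
        )
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)


class TestSLORETA:
    def test_identity_resolution_leaves_operator_unchanged(self):
        lf = small_lead_field(np.eye(12))
        cov = NoiseCovariance(np.eye(12))
        base = mne_operator(lf, cov, alpha=1e-12)
        slo = sloreta_operator(base, lf)
        np.testing.assert_allclose(slo.matrix, base.matrix, atol=1e-5)

    def test_diagonal_block_inverse_sqrt(self):
        from slmcompare.inverse import _inv_sqrt_3x3

        s = _inv_sqrt_3x3(np.diag([4.0, 9.0, 16.0]), 1.0)
        np.testing.assert_allclose(s, np.diag([0.5, 1 / 3, 0.25]))

    def test_random_spd_inverse_sqrt_identity(self):
        from slmcompare.inverse import _inv_sqrt_3x3

        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            b = a @ a.T + 0.1 * np.eye(3)
            s = _inv_sqrt_3x3(b, 1.0)
            np.testing.assert_allclose(s @ b @ s, np.eye(3), atol=1e-10)

    def test_single_source_exact_localization(self, lead162):
        cov = NoiseCovariance(np.eye(32))
        slo = sloreta_operator(mne_operator(lead162, cov, 0.1), lead162)
        rng = np.random.default_rng(11)
        for v in rng.choice(lead162.n_sources, 20, replace=False):
            m = rng.normal(size=3)
            d = lead162.matrix[:, 3 * v : 3 * v + 3] @ m
            est = apply_inverse(slo, d)
            assert int(est.norms[:, 0].argmax()) == v

    def test_mixing_confined_to_source_triples(self, lead162):
        cov = NoiseCovariance(np.eye(32))
        base = mne_operator(lead162, cov, 0.2)
        slo = sloreta_operator(base, lead162)
        # each sLORETA row is a combination of its own point's base rows only
        for p in (0, 57):
            rows = slo.matrix[3 * p : 3 * p + 3]
            base_rows = base.matrix[3 * p : 3 * p + 3]
            coeff, *_ = np.linalg.lstsq(base_rows.T, rows.T, rcond=None)
            np.testing.assert_allclose(base_rows.T @ coeff, rows.T, atol=1e-10)


class TestApplyInverse:
    def test_zero_data(self, lead162):
        op = mne_operator(lead162, NoiseCovariance(np.eye(32)), 0.5)
        est = apply_inverse(op, np.zeros((32, 4)))
        assert not est.components.any()
        assert not est.norms.any()

    def test_norm_is_euclidean_across_components(self):
        from slmcompare.inverse import SourceEstimate

        est = SourceEstimate(np.array([[3.0], [4.0], [0.0]]).reshape(1, 3, 1))
        assert est.norms[0, 0] == pytest.approx(5.0)

    def test_linearity(self, lead162):
        op = mne_operator(lead162, NoiseCovariance(np.eye(32)), 0.5)
        rng = np.random.default_rng(12)
        d1, d2 = rng.normal(size=(2, 32, 3))
        lhs = apply_inverse(op, d1 + d2).components
        rhs = apply_inverse(op, d1).components + apply_inverse(op, d2).components
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_channel_mismatch_reported(self, lead162):
        op = mne_operator(lead162, NoiseCovariance(np.eye(32)), 0.5)
        with pytest.raises(ValueError, match="32"):
            apply_inverse(op, np.zeros((16, 4)))

    def test_resolution_matrix_shape_and_identity_case(self):
        lf = small_lead_field(np.eye(12))
        op = mne_operator(lf, NoiseCovariance(np.eye(12)), 1e-12)
        a = resolution_matrix(op, lf)
        np.testing.assert_allclose(a, np.eye(12), atol=1e-8)


class TestInverseSolverEstimator:
    def test_sklearn_protocol(self, lead162):
        solver = InverseSolver(lead162, method="sloreta", alpha=0.3)
        params = solver.get_params()
        assert params["method"] == "sloreta"
        cloned = clone(solver)
        assert cloned.get_params()["alpha"] == 0.3

    def test_fit_then_transform_shapes(self, lead162):
        rng = np.random.default_rng(13)
        noise = rng.normal(size=(100, 32))
        gcv_data = rng.normal(size=(5, 32))
        solver = InverseSolver(lead162, method="wmne").fit(noise, gcv_data=gcv_data)
        assert solver.alpha_ > 0
        assert solver.operator_.method == "wmne"
        out = solver.transform(rng.normal(size=(7, 32)))
        assert out.shape == (7, 3 * lead162.n_sources)

    def test_sloreta_uses_unweighted_base(self, lead162):
        rng = np.random.default_rng(14)
        noise = rng.normal(size=(100, 32))
        solver = InverseSolver(lead162, method="sloreta", alpha=0.5).fit(noise)
        assert solver.weights_ is None
        assert solver.operator_.base == "mne"
        solver_w = InverseSolver(lead162, method="dspm", alpha=0.5).fit(noise)
        assert solver_w.weights_ is not None
        assert solver_w.operator_.base == "wmne"
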