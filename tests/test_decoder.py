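"""Tests of searchlight assembly, shrinkage and maximum-likelihood decoding."""

import numpy as np
import pytest
from scipy import stats

import fcdecode as fc
from fcdecode.decoder import (build_searchlight_model, decode_block,
                              extract_searchlight, mixing_coefficient)
from fcdecode.encoding import make_cv_folds


def full_lattice(n=9):
    ax = np.arange(n)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)


class TestSearchlight:
    def test_radius_zero_is_center_only(self):
        coords = full_lattice(5)
        idx = extract_searchlight(coords, (2, 2, 2), radius=0)
        assert idx.size == 1
        assert np.array_equal(coords[idx[0]], [2, 2, 2])

    def test_interior_radius4_has_257_members(self):
        coords = full_lattice(9)
        idx = extract_searchlight(coords, (4, 4, 4), radius=4)
        assert idx.size == 257

    def test_corner_searchlight_clipped(self):
        coords = full_lattice(8)
        idx = extract_searchlight(coords, (0, 0, 0), radius=4)
        assert idx.size < 257
        center_row = np.flatnonzero((coords == 0).all(axis=1))[0]
        assert center_row in idx


class TestResidualCovariance:
    def test_zero_residuals_zero_matrix(self):
        B = np.ones((5, 3))
        assert np.array_equal(fc.residual_covariance(B, B), np.zeros((3, 3)))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(41)
        B = rng.standard_normal((5, 3))
        H = rng.standard_normal((5, 3))
        S = fc.residual_covariance(B, H)
        R = B - H
        oracle = np.empty((3, 3))
        for a in range(3):
            for b in range(3):
                oracle[a, b] = sum(R[i, a] * R[i, b] for i in range(5)) / 5
        assert np.allclose(S, oracle, atol=1e-10)

    def test_positive_semidefinite_and_symmetric(self):
        rng = np.random.default_rng(42)
        S = fc.residual_covariance(rng.standard_normal((10, 4)), np.zeros((10, 4)))
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() >= -1e-12

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            fc.residual_covariance(np.empty((0, 3)), np.empty((0, 3)))


class TestMixingCoefficient:
    def test_equal_counts_give_half(self):
        assert mixing_coefficient(7, 7, "arctan") == pytest.approx(0.5)
        assert mixing_coefficient(7, 7, "logistic") == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        # r = (v/t) / (1 + v/t): ratio 3 -> 0.75
        assert mixing_coefficient(3, 1, "logistic") == pytest.approx(0.75)

    def test_limits(self):
        assert mixing_coefficient(10**8, 1, "logistic") == pytest.approx(1.0, abs=1e-6)
        assert mixing_coefficient(1, 10**8, "logistic") == pytest.approx(0.0, abs=1e-6)
        # arctan approaches the limits from inside (0, 1), more slowly
        assert mixing_coefficient(10**8, 1, "arctan") < 1.0
        assert mixing_coefficient(10**8, 1, "arctan") > 0.98
        assert mixing_coefficient(1, 10**8, "arctan") < 0.02

    @pytest.mark.parametrize("method", ["arctan", "logistic"])
    def test_strictly_increasing_in_ratio(self, method):
        ratios = np.geomspace(1e-4, 1e4, 41)
        r = [mixing_coefficient(int(1e6 * x), int(1e6), method) for x in ratios]
        assert np.all(np.diff(r) > 0)
        assert all(0 < ri < 1 for ri in r)

    def test_printed_arctan_violates_stated_properties(self):
        # the uncorrected form is 0 at v = t and tends to 1/2, not 1
        assert mixing_coefficient(5, 5, "printed-arctan") == pytest.approx(0.0)
        assert mixing_coefficient(10**8, 1, "printed-arctan") < 0.5

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            mixing_coefficient(0, 5)


class TestShrinkage:
    def test_full_shrinkage_is_diagonal(self):
        rng = np.random.default_rng(43)
        A = rng.standard_normal((4, 4))
        S = A @ A.T
        out = fc.shrink_covariance(S, 1.0)
        assert np.allclose(out, np.diag(np.diag(S)))

    def test_no_shrinkage_is_identity_operation(self):
        rng = np.random.default_rng(44)
        A = rng.standard_normal((4, 4))
        S = A @ A.T
        assert np.allclose(fc.shrink_covariance(S, 0.0), S)

    def test_diagonal_invariant_for_any_mixing(self):
        rng = np.random.default_rng(45)
        A = rng.standard_normal((5, 5))
        S = A @ A.T
        for r in (0.2, 0.5, 0.9):
            assert np.allclose(np.diag(fc.shrink_covariance(S, r)), np.diag(S))

    def test_eigenvalue_floor(self):
        rng = np.random.default_rng(46)
        R = rng.standard_normal((3, 8))     # rank-deficient: v > t
        S = (R.T @ R) / 3
        r = mixing_coefficient(8, 3)
        shrunk = fc.shrink_covariance(S, r)
        assert np.linalg.eigvalsh(shrunk).min() >= r * np.diag(S).min() - 1e-10


class TestLogLikelihoodProfile:
    def _toy_model(self, rng, v=3):
        grid = np.arange(1.0, 361.0)
        G = np.column_stack([np.cos(np.deg2rad(grid - p)) for p in
                             np.linspace(0, 300, v)])
        A = rng.standard_normal((v, v))
        Sigma = A @ A.T + v * np.eye(v)
        return fc.SearchlightModel(center=np.zeros(3), member_idx=np.arange(v),
                                   models=[None] * v, G=G, Sigma=Sigma,
                                   mixing_r=0.5, t_train=10, grid=grid)

    def test_agrees_with_multivariate_normal_oracle(self):
        rng = np.random.default_rng(47)
        m = self._toy_model(rng)
        beta = rng.standard_normal(3)
        ll = fc.loglik_profile(beta, m)
        oracle = np.array([stats.multivariate_normal.logpdf(beta, m.G[i], m.Sigma)
                           for i in range(360)])
        assert np.allclose(ll, oracle, atol=1e-8)

    def test_profile_peaks_at_generating_direction(self):
        rng = np.random.default_rng(48)
        m = self._toy_model(rng)
        beta = m.G[136]     # exactly g(137 deg)
        assert fc.decode_trial(fc.loglik_profile(beta, m), m.grid) == 137.0

    def test_isotropic_covariance_reduces_to_nearest_pattern(self):
        grid = np.arange(1.0, 361.0)
        G = np.column_stack([np.cos(np.deg2rad(grid)),
                             np.sin(np.deg2rad(grid))])
        m = fc.SearchlightModel(center=np.zeros(3), member_idx=np.arange(2),
                                models=[None, None], G=G,
                                Sigma=0.3 * np.eye(2), mixing_r=0.0,
                                t_train=10, grid=grid)
        rng = np.random.default_rng(49)
        for _ in range(20):
            beta = rng.standard_normal(2)
            ll = fc.loglik_profile(beta, m)
            nearest = np.argmin(((G - beta) ** 2).sum(axis=1))
            assert np.argmax(ll) == nearest


class TestDecode:
    def test_unique_maximum(self):
        p = np.zeros(360)
        p[136] = 1.0    # grid value 137
        assert fc.decode_trial(p) == 137.0

    def test_flat_profile_tie_breaks_to_one_degree(self):
        assert fc.decode_trial(np.zeros(360)) == 1.0

    def test_decoded_360_reported_as_zero(self):
        p = np.zeros(360)
        p[-1] = 1.0
        assert fc.decode_trial(p) == 0.0

    def test_nonfinite_profile_rejected(self):
        p = np.zeros(360)
        p[5] = np.nan
        with pytest.raises(ValueError):
            fc.decode_trial(p)

    def test_noiseless_injective_population_decodes_every_direction(self):
        grid = np.arange(1.0, 361.0)
        G = np.column_stack([np.exp(np.cos(np.deg2rad(grid)) - 1),
                             np.exp(np.cos(np.deg2rad(grid - 90)) - 1)])
        m = fc.SearchlightModel(center=np.zeros(3), member_idx=np.arange(2),
                                models=[None, None], G=G,
                                Sigma=0.1 * np.eye(2), mixing_r=0.0,
                                t_train=10, grid=grid)
        decoded = decode_block(G, m)
        assert np.allclose(decoded, np.mod(grid, 360.0))


class TestReconstruction:
    def test_each_trial_decoded_exactly_once(self, session_trials,
                                             cluster_betas):
        cv = make_cv_folds(session_trials, "full", "stimulus")
        res, _ = fc.run_reconstruction(cluster_betas, session_trials, cv,
                                       fit="ensemble", seed=0)
        assert len(res) == 160
        assert res["trial_id"].is_unique

    def test_rotation_equivariance_of_decoding(self):
        rng = np.random.default_rng(50)
        th = rng.uniform(0, 360, 80)
        # rotation-covariant population: pure first harmonics
        def responses(angles):
            return np.column_stack([
                np.cos(np.deg2rad(angles - p)) for p in (0, 60, 120, 200, 280)
            ]) + 0.05 * noise
        noise = rng.standard_normal((80, 5))
        delta = 40.0
        B0, B1 = responses(th), responses(np.mod(th + delta, 360))
        m0 = build_searchlight_model(B0[:60], th[:60], fit="ensemble")
        m1 = build_searchlight_model(B1[:60], np.mod(th[:60] + delta, 360),
                                     fit="ensemble")
        d0 = decode_block(B0[60:], m0)
        d1 = decode_block(B1[60:], m1)
        dd = fc.circdist_deg(np.mod(d0 + delta, 360), d1)
        assert np.median(dd) <= 2.0
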