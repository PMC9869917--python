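"""Background statistics and the five covariance-conditioning routes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mpmri_anomaly as mp
from mpmri_anomaly import background as bg

from conftest import random_spd


def stats_from(cov, mu=None, n=1000):
    c = cov.shape[0]
    return bg.BackgroundStats(
        mu=np.zeros(c) if mu is None else mu, cov=np.asarray(cov, float), n=n
    )


class TestComputeStats:
    def test_two_channel_hand_example(self):
        cube = np.array([[0.0, 0], [2, 0], [0, 2], [2, 2]]).reshape(4, 1, 2)
        stats = bg.compute_stats(cube, np.ones((4, 1), bool))
        np.testing.assert_allclose(stats.mu, [1.0, 1.0])
        np.testing.assert_allclose(stats.cov, np.diag([4 / 3, 4 / 3]))
        assert stats.n == 4

    def test_constant_channel_flagged_singular(self):
        rng = np.random.default_rng(0)
        cube = rng.normal(size=(50, 1, 3))
        cube[..., 1] = 2.5
        stats = bg.compute_stats(cube, np.ones((50, 1), bool))
        assert np.all(stats.cov[1] == 0) and np.all(stats.cov[:, 1] == 0)
        assert stats.is_singular()

    def test_phantom_covariance_recovered(self, big_background):
        x, mean, cov = big_background
        stats = bg.compute_stats(x.reshape(-1, 1, 7), np.ones((x.shape[0], 1), bool))
        scale = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert np.all(np.abs(stats.cov - cov) / scale < 0.05)

    def test_too_few_voxels_rejected(self):
        cube = np.zeros((5, 1, 7))
        with pytest.raises(ValueError, match="rank-deficient"):
            bg.compute_stats(cube, np.ones((5, 1), bool))


class TestFilterPCs:
    def test_diagonal_cov_axis_aligned(self):
        cs = bg.filter_pcs(stats_from(np.diag([4.0, 2.0, 1.0])), k=1)
        np.testing.assert_allclose(cs.inv_op, np.diag([0.25, 0.5, 0.0]), atol=1e-12)
        assert cs.retained.tolist() == [True, True, False]

    def test_k_zero_equals_full_inverse(self):
        rng = np.random.default_rng(1)
        cov = random_spd(rng, 7)
        stats = stats_from(cov)
        np.testing.assert_allclose(
            bg.filter_pcs(stats, 0).inv_op,
            bg.condition_unprocessed(stats).inv_op,
            atol=1e-9,
        )

    @pytest.mark.parametrize("k", [3, 4])
    def test_pseudo_inverse_identity(self, k):
        """A @ Sigma @ A == A for the rank-(C-k) subspace pseudo-inverse."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            cov = random_spd(rng, 7)
            a = bg.filter_pcs(stats_from(cov), k).inv_op
            np.testing.assert_allclose(a @ cov @ a, a, atol=1e-9)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bg.filter_pcs(stats_from(np.eye(7)), 7)


class TestShrink:
    def test_gamma_zero_reproduces_cov(self):
        rng = np.random.default_rng(3)
        cov = random_spd(rng, 7)
        for mode in ("regularized", "modified_regularized"):
            np.testing.assert_array_equal(bg.shrunk_cov(cov, 0.0, mode), cov)

    def test_gamma_one_limits(self):
        rng = np.random.default_rng(4)
        cov = random_spd(rng, 7)
        np.testing.assert_allclose(
            bg.shrunk_cov(cov, 1.0, "regularized"), np.diag(np.diag(cov))
        )
        np.testing.assert_allclose(
            bg.shrunk_cov(cov, 1.0, "modified_regularized"),
            (np.trace(cov) / 7) * np.eye(7),
        )

    def test_half_mixing_hand_example(self):
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        np.testing.assert_allclose(
            bg.shrunk_cov(cov, 0.5, "regularized"),
            np.array([[2.0, 0.5], [0.5, 2.0]]),
        )

    @given(
        g1=st.floats(0, 1), g2=st.floats(0, 1),
        seed=st.integers(0, 10), mode=st.sampled_from(
            ["regularized", "modified_regularized"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_lipschitz_continuity_in_gamma(self, g1, g2, seed, mode):
        """||CM(g1) - CM(g2)|| <= |g1-g2| * ||D - cov||."""
        cov = random_spd(np.random.default_rng(seed), 5)
        d = bg.shrink_target(cov, mode)
        lhs = np.linalg.norm(bg.shrunk_cov(cov, g1, mode) - bg.shrunk_cov(cov, g2, mode))
        assert lhs <= abs(g1 - g2) * np.linalg.norm(d - cov) + 1e-9

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            bg.shrunk_cov(np.eye(3), 1.5, "regularized")


class TestSelectGamma:
    def test_grid_contract(self, big_background):
        x, _, _ = big_background
        sub = x[:2000].reshape(-1, 1, 7)
        g, curve = bg.select_gamma(sub, np.ones((2000, 1), bool), "regularized")
        assert curve.shape == (21,)
        assert g in bg.GAMMA_GRID
        assert curve[np.where(bg.GAMMA_GRID == g)[0][0]] == curve.max()

    def test_large_sample_needs_little_shrinkage(self, big_background):
        x, _, _ = big_background
        cube = x.reshape(-1, 1, 7)
        mask = np.ones((x.shape[0], 1), bool)
        for mode in ("regularized", "modified_regularized"):
            g, _ = bg.select_gamma(cube, mask, mode)
            assert g <= 0.1

    def test_tiny_sample_shrinks(self, big_background):
        x, _, _ = big_background
        sub = x[:15].reshape(15, 1, 7)
        g, _ = bg.select_gamma(sub, np.ones((15, 1), bool), "regularized")
        assert g > 0.0


class TestEVM:
    @staticmethod
    def outlier_cube(seed=3, n=10_000, frac=0.05, scale=10.0):
        rng = np.random.default_rng(seed)
        cov = mp.phantom.default_background_cov()
        x = mp.phantom.default_background_mean() + rng.standard_normal(
            (n, 7)
        ) @ np.linalg.cholesky(cov).T
        idx = rng.choice(n, int(frac * n), replace=False)
        u = rng.standard_normal((idx.size, 7))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        x[idx] += scale * u * np.sqrt(np.diag(cov))
        om = np.zeros(n, bool)
        om[idx] = True
        return x.reshape(100, -1, 7), om.reshape(100, -1)

    def test_single_trial_contract(self):
        """trials=1 returns exactly the stats of the one seeded 90% subset."""
        cube, _ = self.outlier_cube()
        mask = np.ones(cube.shape[:2], bool)
        cs = bg.evm(cube, mask, trials=1, seed=9)
        x = cube.reshape(-1, 7)
        rng = np.random.default_rng(np.random.SeedSequence(9))
        idx = rng.choice(x.shape[0], size=x.shape[0] - 1000, replace=False)
        np.testing.assert_allclose(cs.mu, x[idx].mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(cs.cov, np.cov(x[idx], rowvar=False), rtol=1e-10)

    def test_outliers_shrink_the_ellipsoid(self):
        cube, _ = self.outlier_cube()
        mask = np.ones(cube.shape[:2], bool)
        cs = bg.evm(cube, mask, trials=200, seed=0)
        stats = bg.compute_stats(cube, mask)
        assert np.linalg.slogdet(cs.cov)[1] < np.linalg.slogdet(stats.cov)[1]

    def test_no_pathological_collapse_without_outliers(self, big_background):
        x, _, _ = big_background
        cube = x.reshape(x.shape[0], 1, 7)
        mask = np.ones(cube.shape[:2], bool)
        cs = bg.evm(cube, mask, trials=200, seed=1)
        stats = bg.compute_stats(cube, mask)
        ratio = np.exp(
            np.linalg.slogdet(cs.cov)[1] - np.linalg.slogdet(stats.cov)[1]
        )
        assert 0.5 <= ratio <= 1.0

    def test_minimum_volume_non_increasing_in_trials(self):
        cube, _ = self.outlier_cube()
        mask = np.ones(cube.shape[:2], bool)
        vols = [
            bg.evm(cube, mask, trials=t, seed=5).params["min_log_volume"]
            for t in (10, 50, 200)
        ]
        assert vols[0] >= vols[1] >= vols[2]


@pytest.mark.parametrize("method", ["unprocessed", "delete_pc_3", "delete_pc_4", "evm"])
def test_all_operators_symmetric_psd(method, default_case):
    _, _, cube, masks = default_case
    normal = masks["prostate"] & ~masks["tumor"]
    cs = bg.condition(cube, normal, method, seed=0)
    np.testing.assert_allclose(cs.inv_op, cs.inv_op.T, atol=1e-10)
    assert np.linalg.eigvalsh(cs.inv_op).min() >= -1e-10


def test_shrink_cv_records_curve(default_case):
    _, _, cube, masks = default_case
    normal = masks["prostate"] & ~masks["tumor"]
    cs = bg.condition(cube, normal, "regularized")
    assert cs.method == "regularized"
    assert cs.params["likelihood_curve"].shape == (21,)
    assert 0.0 <= cs.params["gamma"] <= 1.0
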