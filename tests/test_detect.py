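"""RX and ACE scoring against independent linear-algebra oracles."""

import numpy as np
import pytest

import mpmri_anomaly as mp
from mpmri_anomaly import background as bg, detect

from conftest import random_spd


def conditioned(mu, cov):
    return bg.condition_unprocessed(bg.BackgroundStats(mu=mu, cov=cov, n=1000))


class TestRX:
    def test_zero_at_background_mean(self):
        cs = conditioned(np.arange(7.0), np.eye(7) * 2)
        cube = np.tile(np.arange(7.0), (3, 3, 1))
        assert np.all(detect.rx_map(cube, cs).scores == 0.0)

    def test_identity_covariance_unit_displacement(self):
        cs = conditioned(np.zeros(7), np.eye(7))
        x = np.zeros((1, 1, 7))
        x[0, 0, 2] = 1.0
        assert detect.rx_map(x, cs).scores[0, 0] == pytest.approx(1.0)

    def test_matches_explicit_inverse_oracle(self):
        """RX equals (x-mu)^T Sigma^-1 (x-mu) computed with an explicit
        matrix inverse, on 1000 random 7-dim voxels."""
        rng = np.random.default_rng(10)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        x = rng.normal(size=(1000, 7)) * 3
        cs = conditioned(mu, cov)
        ours = detect.rx_scores(x, cs)
        inv = np.linalg.inv(cov)
        oracle = np.einsum("ij,jk,ik->i", x - mu, inv, x - mu)
        np.testing.assert_allclose(ours, oracle, atol=1e-9, rtol=1e-9)

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(11)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        x = rng.normal(size=(50, 7))
        perm = rng.permutation(7)
        a = detect.rx_scores(x, conditioned(mu, cov))
        b = detect.rx_scores(
            x[:, perm], conditioned(mu[perm], cov[np.ix_(perm, perm)])
        )
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_gaussian_background_chi_square_moments(self, big_background):
        x, _, _ = big_background
        cube = x.reshape(-1, 1, 7)
        mask = np.ones((x.shape[0], 1), bool)
        cs = bg.condition_unprocessed(bg.compute_stats(cube, mask))
        scores = detect.rx_map(cube, cs, mask).masked_scores()
        assert scores.mean() == pytest.approx(7.0, rel=0.05)
        assert scores.var() == pytest.approx(14.0, rel=0.15)

    def test_delete_k_equals_subspace_whitened_oracle(self):
        """RX under delete-k stats equals the squared norm of the voxel
        whitened in the retained (C-k)-dimensional eigenspace."""
        rng = np.random.default_rng(12)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        x = rng.normal(size=(200, 7)) * 2
        for k in (1, 3, 4):
            cs = bg.filter_pcs(bg.BackgroundStats(mu, cov, 999), k)
            w, v = np.linalg.eigh(cov)
            keep = np.argsort(w)[k:]  # discard k smallest
            z = (x - mu) @ v[:, keep] / np.sqrt(w[keep])
            np.testing.assert_allclose(
                detect.rx_scores(x, cs), (z**2).sum(axis=1), atol=1e-9, rtol=1e-9
            )

    def test_dimension_mismatch_rejected(self):
        cs = conditioned(np.zeros(7), np.eye(7))
        with pytest.raises(ValueError, match="channels"):
            detect.rx_map(np.zeros((2, 2, 5)), cs)

    def test_no_data_value_outside_domain(self):
        cs = conditioned(np.zeros(7), np.eye(7))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        scores = detect.rx_map(np.ones((2, 2, 7)), cs, mask).scores
        assert scores[1, 1] == detect.NO_DATA and scores[0, 0] >= 0


class TestACE:
    def test_signature_voxel_scores_one(self):
        rng = np.random.default_rng(13)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        s = mu + rng.normal(size=7)
        cs = conditioned(mu, cov)
        score = detect.ace_scores(s[None], cs, detect.Signature(s))
        assert score[0] == pytest.approx(1.0, abs=1e-12)

    def test_whitened_orthogonal_scores_zero(self):
        cov = np.diag([1.0, 4.0, 9.0, 1, 1, 1, 1])
        mu = np.zeros(7)
        s = np.array([1.0, 0, 0, 0, 0, 0, 0])  # whitened: e1
        x = np.array([0.0, 2, 0, 0, 0, 0, 0])  # whitened: e2
        score = detect.ace_scores(x[None], conditioned(mu, cov), detect.Signature(s))
        assert score[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_whitened_cosine_oracle(self):
        """ACE equals cos^2 of the angle between explicitly whitened
        vectors, on 1000 random cases."""
        rng = np.random.default_rng(14)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        s = mu + rng.normal(size=7) * 2
        x = rng.normal(size=(1000, 7)) * 3
        cs = conditioned(mu, cov)
        ours = detect.ace_scores(x, cs, detect.Signature(s))
        w_inv_sqrt = np.linalg.cholesky(np.linalg.inv(cov)).T
        zx = (x - mu) @ w_inv_sqrt.T
        zs = w_inv_sqrt @ (s - mu)
        cos = (zx @ zs) / (np.linalg.norm(zx, axis=1) * np.linalg.norm(zs))
        np.testing.assert_allclose(ours, cos**2, atol=1e-9)

    def test_invariant_under_signature_scaling(self):
        rng = np.random.default_rng(15)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        s = mu + rng.normal(size=7)
        x = rng.normal(size=(100, 7))
        cs = conditioned(mu, cov)
        a = detect.ace_scores(x, cs, detect.Signature(s))
        b = detect.ace_scores(x, cs, detect.Signature(mu + 5.0 * (s - mu)))
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_scores_bounded_under_delete_pc_projection(self):
        rng = np.random.default_rng(16)
        cov = random_spd(rng, 7)
        mu = rng.normal(size=7)
        cs = bg.filter_pcs(bg.BackgroundStats(mu, cov, 999), 3)
        x = rng.normal(size=(500, 7)) * 4
        scores = detect.ace_scores(x, cs, detect.Signature(mu + rng.normal(size=7)))
        assert np.all((scores >= 0) & (scores <= 1))

    def test_degenerate_signature_rejected(self):
        cs = conditioned(np.zeros(7), np.eye(7))
        with pytest.raises(ValueError, match="degenerate"):
            detect.ace_scores(np.ones((1, 7)), cs, detect.Signature(np.zeros(7)))

    def test_voxel_at_mean_scores_zero(self):
        cs = conditioned(np.zeros(7), np.eye(7))
        s = detect.Signature(np.ones(7))
        assert detect.ace_scores(np.zeros((1, 7)), cs, s)[0] == 0.0


class TestSignature:
    def test_single_voxel_region(self, default_case):
        _, _, cube, masks = default_case
        idx = np.argwhere(masks["tumor"])[0]
        m = np.zeros_like(masks["tumor"])
        m[tuple(idx)] = True
        sig = detect.extract_signature(cube, m)
        np.testing.assert_array_equal(sig.s, cube.data[tuple(idx)])
        assert sig.n_voxels == 1

    def test_phantom_tumor_signature_recovered(self, default_case):
        spec, _, cube, masks = default_case
        sig = detect.extract_signature(cube, masks["tumor"])
        expected = spec.background_mean + spec.tumor_regions[0].signature
        se = np.sqrt(np.diag(spec.background_cov) / masks["tumor"].sum())
        assert np.all(np.abs(sig.s - expected) < 4 * se)

    def test_empty_region_rejected(self, default_case):
        _, _, cube, masks = default_case
        with pytest.raises(ValueError, match="empty"):
            detect.extract_signature(cube, np.zeros_like(masks["tumor"]))
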