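import numpy as np
import pytest

import songdkl as sk
from songdkl.divergence import dkl_from_models


def gaussian_model(mean, cov):
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    return sk.SongModel(k=1, weights=np.array([1.0]), means=mean[None, :],
                        covariances=cov[None])


def gaussian_kl_bits(mu0, cov0, mu1, cov1):
    """Closed-form KL( N(mu0,cov0) || N(mu1,cov1) ) in bits."""
    mu0, mu1 = np.atleast_1d(mu0).astype(float), np.atleast_1d(mu1).astype(float)
    cov0, cov1 = np.atleast_2d(cov0).astype(float), np.atleast_2d(cov1).astype(float)
    d = mu0.size
    inv1 = np.linalg.inv(cov1)
    diff = mu1 - mu0
    nats = 0.5 * (np.trace(inv1 @ cov0) + diff @ inv1 @ diff - d
                  + np.log(np.linalg.det(cov1) / np.linalg.det(cov0)))
    return nats / np.log(2)


class TestCrossEntropy:
    def test_standard_gaussian_entropy(self, rng):
        x = rng.normal(size=(10000, 1))
        model = gaussian_model([0.0], [[1.0]])
        h = sk.cross_entropy(x, model)
        expect = 0.5 * np.log2(2 * np.pi * np.e)  # 2.047 bits
        se = np.std(-model.log_density(x) / np.log(2), ddof=1) / 100
        assert abs(h - expect) < 3 * se

    def test_samples_at_mode(self):
        model = gaussian_model([0.0], [[1.0]])
        x = np.zeros((7, 1))
        h = sk.cross_entropy(x, model)
        assert np.isclose(h, 0.5 * np.log2(2 * np.pi))  # 1.3257 bits

    def test_flatter_model_costs_more(self, rng):
        x = rng.normal(size=(200, 1))
        hs = [sk.cross_entropy(x, gaussian_model([0.0], [[s ** 2]]))
              for s in (1.0, 3.0, 10.0, 30.0)]
        assert all(a < b for a, b in zip(hs, hs[1:]))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sk.cross_entropy(np.empty((0, 1)), gaussian_model([0.0], [[1.0]]))

    def test_density_floor_applied(self):
        model = gaussian_model([0.0], [[1.0]])
        h = sk.cross_entropy(np.array([[1e6]]), model)
        assert np.isfinite(h)


class TestDklEstimator:
    def test_identity_is_exactly_zero(self, rng):
        model = gaussian_model([0.0, 0.0], np.eye(2))
        x = rng.normal(size=(100, 2))
        res = dkl_from_models(x, model, model)
        assert res.dkl_bits == 0.0

    def test_unit_shift_gaussians(self, rng):
        """N(0,1) vs N(1,1): KL = 0.5 nats = 0.7213 bits."""
        p = gaussian_model([0.0], [[1.0]])
        q = gaussian_model([1.0], [[1.0]])
        x = rng.normal(size=(10000, 1))
        res = dkl_from_models(x, p, q)
        assert abs(res.dkl_bits - 0.5 / np.log(2)) < 3 * res.se_bits

    @pytest.mark.parametrize("dim", [1, 5])
    def test_matches_closed_form_across_seeds(self, dim):
        """Monte-Carlo estimate vs closed-form Gaussian KL in 1-D and 5-D."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            mu0 = np.zeros(dim)
            mu1 = rng.normal(0, 0.7, dim)
            cov0 = np.eye(dim)
            a = rng.normal(0, 0.2, (dim, dim))
            cov1 = np.eye(dim) + a @ a.T
            p, q = gaussian_model(mu0, cov0), gaussian_model(mu1, cov1)
            x = rng.multivariate_normal(mu0, cov0, size=3000)
            res = dkl_from_models(x, p, q)
            expect = gaussian_kl_bits(mu0, cov0, mu1, cov1)
            assert abs(res.dkl_bits - expect) < 3 * res.se_bits + 1e-9

    def test_result_invariant_consistency(self, rng):
        p = gaussian_model([0.0], [[1.0]])
        q = gaussian_model([2.0], [[1.0]])
        res = dkl_from_models(rng.normal(size=(500, 1)), p, q)
        assert np.isclose(res.dkl_bits, res.h_p_qhat - res.h_p_phat)

    def test_extra_comparison_mass_harmless_missing_mass_costly(self, rng):
        """Asymmetry at the model level: a comparison model with an extra,
        far-away component barely changes D_KL; a comparison model missing
        a reference mode raises it sharply."""
        ref = sk.SongModel(
            k=2, weights=np.array([0.5, 0.5]),
            means=np.array([[0.0], [6.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]))
        comp_extra = sk.SongModel(
            k=3, weights=np.array([0.45, 0.45, 0.1]),
            means=np.array([[0.0], [6.0], [30.0]]),
            covariances=np.array([[[1.0]], [[1.0]], [[1.0]]]))
        comp_missing = sk.SongModel(
            k=1, weights=np.array([1.0]),
            means=np.array([[0.0]]), covariances=np.array([[[1.0]]]))
        rng_local = np.random.default_rng(0)
        z = rng_local.integers(0, 2, 4000)
        x = (rng_local.normal(size=4000) + 6.0 * z)[:, None]
        d_extra = dkl_from_models(x, ref, comp_extra)
        d_missing = dkl_from_models(x, ref, comp_missing)
        assert abs(d_extra.dkl_bits) < 5 * d_extra.se_bits + 0.2
        assert d_missing.dkl_bits > d_extra.dkl_bits + 3 * d_missing.se_bits


class TestSongDkl:
    def test_fit_eval_split_disjoint_and_sized(self):
        cfg = sk.DklConfig(n_fit=30, n_eval=20)
        rng = np.random.default_rng(0)
        fit, ev = sk.divergence.split_fit_eval(100, cfg, rng)
        assert len(fit) == 30 and len(ev) == 20
        assert not set(fit) & set(ev)
        fit, ev = sk.divergence.split_fit_eval(40, cfg, rng)
        assert len(fit) == 20 and len(ev) == 20
        assert not set(fit) & set(ev)

    def test_song_dkl_with_prefitted_identical_models(self, rng):
        model = gaussian_model([0.0, 0.0], np.eye(2))
        x = rng.normal(size=(200, 2))
        res, _, _ = sk.song_dkl(x, x.copy(), sk.DklConfig(seed=0),
                                ref_model=model, comp_model=model)
        assert res.dkl_bits == 0.0

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="basis space"):
            sk.song_dkl(rng.normal(size=(50, 2)), rng.normal(size=(50, 3)))

    def test_split_half_nonnegative_within_noise(self, rng):
        """Split-half self-divergence of one Gaussian cloud sits at the
        noise floor: >= -3 SE."""
        x = rng.normal(size=(1200, 3))
        cfg = sk.DklConfig(k_grid=(1, 2), seed=0)
        res = sk.split_half_baseline(x, cfg)
        assert res.dkl_bits > -3 * res.se_bits

    def test_split_half_seed_stability(self, rng):
        x = rng.normal(size=(1200, 3))
        r1 = sk.split_half_baseline(x, sk.DklConfig(k_grid=(1, 2), seed=1))
        r2 = sk.split_half_baseline(x, sk.DklConfig(k_grid=(1, 2), seed=2))
        tol = 3 * np.hypot(r1.se_bits, r2.se_bits)
        assert abs(r1.dkl_bits - r2.dkl_bits) < tol
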