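import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

import songdkl as sk
from songdkl.song_model import _heldout_bic


def two_blob_data(rng, n=2000, dim=5, sep=10.0):
    """Two spherical unit-variance Gaussians separated by sep*sigma."""
    half = n // 2
    a = rng.normal(0.0, 1.0, size=(half, dim))
    b = rng.normal(0.0, 1.0, size=(n - half, dim)) + sep / np.sqrt(dim)
    return np.vstack([a, b])


class TestFitGmm:
    def test_two_cluster_parameter_recovery(self, rng):
        x = two_blob_data(rng)
        m = sk.fit_gmm(x, 2, seed=0)
        order = np.argsort(m.means[:, 0])
        mu_a, mu_b = m.means[order]
        assert np.linalg.norm(mu_a - 0.0) < 0.1 * np.sqrt(5)
        assert np.linalg.norm(mu_b - 10.0 / np.sqrt(5)) < 0.1 * np.sqrt(5)
        assert np.all(np.abs(m.weights - 0.5) < 0.05)

    def test_k1_closed_form(self, rng):
        x = rng.normal(size=(500, 3))
        m = sk.fit_gmm(x, 1, seed=0)
        assert np.allclose(m.means[0], x.mean(axis=0), atol=1e-6)
        assert np.allclose(m.covariances[0], np.cov(x.T, ddof=0), atol=1e-4)

    def test_deterministic_given_seed(self, rng):
        x = two_blob_data(rng, n=400)
        a = sk.fit_gmm(x, 2, seed=42)
        b = sk.fit_gmm(x, 2, seed=42)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.covariances, b.covariances)
        assert a.fit_loglik == b.fit_loglik

    def test_k_exceeding_rows(self, rng):
        with pytest.raises(ValueError, match="components"):
            sk.fit_gmm(rng.normal(size=(3, 2)), 5)

    def test_em_loglik_monotone(self, rng):
        """Stepping sklearn EM one iteration at a time from our K-means
        init: the training log-likelihood never decreases."""
        x = two_blob_data(rng, n=600, dim=3, sep=4.0)
        from songdkl.song_model import _kmeans_init, REG_COVAR
        w0, m0, p0 = _kmeans_init(x, 2, state=0)
        gm = GaussianMixture(n_components=2, covariance_type="full",
                             reg_covar=REG_COVAR, max_iter=1, tol=0.0,
                             warm_start=True, weights_init=w0, means_init=m0,
                             precisions_init=p0, random_state=0)
        prev = -np.inf
        import warnings
        for _ in range(25):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            ll = gm.score(x) * x.shape[0]
            assert ll >= prev - 1e-8 * max(1.0, abs(prev))
            prev = ll

    def test_density_matches_sklearn(self, rng):
        """Our Cholesky density evaluation agrees with sklearn's."""
        x = two_blob_data(rng, n=500, dim=4, sep=6.0)
        m = sk.fit_gmm(x, 2, seed=1)
        gm = GaussianMixture(n_components=2, covariance_type="full")
        gm.weights_, gm.means_ = m.weights, m.means
        gm.precisions_cholesky_ = np.array(
            [np.linalg.inv(np.linalg.cholesky(c)).T for c in m.covariances])
        pts = rng.normal(size=(50, 4))
        assert np.allclose(m.log_density(pts), gm.score_samples(pts),
                           rtol=1e-8, atol=1e-8)

    def test_density_integrates_to_one(self, rng):
        x = rng.normal(size=(400, 2))
        m = sk.fit_gmm(x, 1, seed=0)
        g = np.linspace(-8, 8, 301)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        dens = np.exp(m.log_density(pts))
        integral = dens.sum() * (g[1] - g[0]) ** 2
        assert abs(integral - 1.0) < 1e-3


class TestCvBic:
    def test_three_clusters_beat_one(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
        x = np.vstack([rng.normal(0, 1, (200, 2)) + c for c in centers])
        assert sk.cv_bic(x, 3, seed=0) < sk.cv_bic(x, 1, seed=0)

    def test_duplicated_data_same_choice(self, rng):
        centers = np.array([[0, 0], [8, 0], [0, 8]], dtype=float)
        x = np.vstack([rng.normal(0, 1, (150, 2)) + c for c in centers])
        grid = (2, 3, 4)
        _, r1 = sk.select_model(x, k_grid=grid, seed=0)
        _, r2 = sk.select_model(np.vstack([x, x]), k_grid=grid, seed=0)
        assert r1.chosen_k == r2.chosen_k == 3

    def test_single_cluster_picks_smallest_k(self, rng):
        x = rng.normal(0, 0.1, (300, 2))
        _, report = sk.select_model(x, k_grid=(1, 2, 3), seed=0)
        assert report.chosen_k == 1
        assert report.boundary_flag

    def test_insufficient_rows(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            sk.cv_bic(rng.normal(size=(5, 2)), 3, n_folds=3)


class TestSelectModel:
    def test_singleton_grid(self, rng):
        x = two_blob_data(rng, n=300, dim=2, sep=6.0)
        model, report = sk.select_model(x, k_grid=(4,), seed=0)
        assert report.chosen_k == 4
        assert report.boundary_flag
        assert model.k == 4

    def test_selected_restart_is_best(self, rng):
        """The returned fit's log-likelihood beats single-restart fits from
        the same seed stream."""
        x = two_blob_data(rng, n=400, dim=3, sep=3.0)
        best = sk.fit_gmm(x, 3, seed=5, n_restarts=5)
        singles = [sk.fit_gmm(x, 3, seed=5 + i, n_restarts=1)
                   for i in range(3)]
        assert best.fit_loglik >= max(s.fit_loglik for s in singles) - 1e-6

    def test_empty_grid(self, rng):
        with pytest.raises(ValueError, match="k_grid"):
            sk.select_model(rng.normal(size=(50, 2)), k_grid=())


def test_heldout_bic_definition(rng):
    """The fold score is -2*heldout loglik + n_params*ln(n_heldout)."""
    x = rng.normal(size=(100, 2))
    m = sk.fit_gmm(x, 2, seed=0)
    h = rng.normal(size=(40, 2))
    expect = -2.0 * m.log_density(h).sum() + m.n_parameters() * np.log(40)
    assert np.isclose(_heldout_bic(m, h), expect)


def test_model_serialization_roundtrip(tmp_path, rng):
    x = two_blob_data(rng, n=300, dim=3, sep=5.0)
    m = sk.fit_gmm(x, 2, seed=0)
    path = tmp_path / "model.json"
    m.save(path)
    m2 = sk.SongModel.load(path)
    assert m2.k == m.k
    assert np.allclose(m2.means, m.means)
    pts = rng.normal(size=(20, 3))
    assert np.allclose(m2.log_density(pts), m.log_density(pts))


def test_invalid_model_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        sk.SongModel(k=2, weights=np.array([0.7, 0.6]),
                     means=np.zeros((2, 2)),
                     covariances=np.array([np.eye(2), np.eye(2)]))
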