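"""Gaussian-mixture song models.

A repertoire projected into similarity-space is modeled as a K-component
full-covariance Gaussian mixture,

    p(x | theta) = sum_k pi_k N(x | mu_k, Sigma_k),

fit by EM initialized from K-means, restarted five times from independent
seeds with the highest-likelihood converged fit kept.  K is chosen by a
three-fold cross-validated BIC: for each candidate K the mixture is fit on
two folds and scored on the held-out fold with a BIC-style penalized score,
summed over folds; the K minimizing this score estimates the number of
distinct syllable types.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .similarity import SimilarityMatrix

log = logging.getLogger(__name__)

N_RESTARTS = 5          # independent EM runs per fit
KMEANS_RESTARTS = 10    # K-means starts inside each EM initialization
REG_COVAR = 1e-6
EM_TOL = 1e-4           # relative log-likelihood convergence tolerance
EM_MAX_ITER = 500

DEFAULT_K_GRID_AVIAN = tuple(range(2, 21))
DEFAULT_K_GRID_HUMAN = tuple(range(2, 36))


def _as_array(data: SimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, SimilarityMatrix):
        return data.values
    return np.asarray(data, dtype=np.float64)


@dataclass
class SongModel:
    """A fitted mixture representing one repertoire in similarity-space."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    fit_loglik: float = float("nan")
    seed: int | None = None
    converged: bool = True
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        if self.covariances.ndim == 2:  # single component convenience
            self.covariances = self.covariances[None]
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.k != self.means.shape[0]:
            raise ValueError("k does not match number of components")

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def n_parameters(self) -> int:
        d = self.dim
        return (self.k - 1) + self.k * d + self.k * d * (d + 1) // 2

    def _cholesky_factors(self) -> np.ndarray:
        if self._chol is None:
            chols = np.empty_like(self.covariances)
            for k in range(self.k):
                cov = self.covariances[k]
                try:
                    chols[k] = cholesky(cov, lower=True)
                except np.linalg.LinAlgError:
                    chols[k] = cholesky(
                        cov + REG_COVAR * np.eye(self.dim), lower=True)
            self._chol = chols
        return self._chol

    def log_density(self, x: np.ndarray, base: float = np.e) -> np.ndarray:
        """Mixture log-density at each row of ``x`` (natural log by default)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.dim:
            raise ValueError(
                f"points have dimension {x.shape[1]}, model is {self.dim}-D")
        n, d = x.shape
        log_probs = np.empty((n, self.k))
        chols = self._cholesky_factors()
        for k in range(self.k):
            L = chols[k]
            diff = x - self.means[k]
            z = solve_triangular(L, diff.T, lower=True).T
            maha = np.einsum("ij,ij->i", z, z)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            log_probs[:, k] = (np.log(self.weights[k])
                               - 0.5 * (d * np.log(2 * np.pi) + logdet + maha))
        out = logsumexp(log_probs, axis=1)
        if base != np.e:
            out = out / np.log(base)
        return out

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of each component for each row (rows sum to 1)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        chols = self._cholesky_factors()
        d = self.dim
        log_probs = np.empty((x.shape[0], self.k))
        for k in range(self.k):
            L = chols[k]
            z = solve_triangular(L, (x - self.means[k]).T, lower=True).T
            maha = np.einsum("ij,ij->i", z, z)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            log_probs[:, k] = (np.log(self.weights[k])
                               - 0.5 * (d * np.log(2 * np.pi) + logdet + maha))
        return np.exp(log_probs - logsumexp(log_probs, axis=1, keepdims=True))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"k": self.k, "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "covariances": self.covariances.tolist(),
                "fit_loglik": self.fit_loglik, "seed": self.seed,
                "converged": self.converged}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "SongModel":
        m = cls(k=d["k"], weights=np.array(d["weights"]),
                means=np.array(d["means"]),
                covariances=np.array(d["covariances"]),
                fit_loglik=d.get("fit_loglik", float("nan")),
                seed=d.get("seed"), converged=d.get("converged", True))
        m._cholesky_factors()  # validates positive-definiteness on load
        return m

    @classmethod
    def load(cls, path: str | Path) -> "SongModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ModelSelectionReport:
    k_grid: tuple[int, ...]
    cv_bic: tuple[float, ...]
    chosen_k: int
    boundary_flag: bool

    def __post_init__(self) -> None:
        best = self.k_grid[int(np.argmin(self.cv_bic))]
        if best != self.chosen_k:
            raise ValueError("chosen_k must attain the minimum cv_bic")


def _from_sklearn(gm: GaussianMixture, loglik: float, seed: int | None) -> SongModel:
    return SongModel(k=gm.n_components, weights=gm.weights_.copy(),
                     means=gm.means_.copy(), covariances=gm.covariances_.copy(),
                     fit_loglik=loglik, seed=seed,
                     converged=bool(gm.converged_))


def _kmeans_init(x: np.ndarray, k: int, state: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM starting point from a multi-restart K-means clustering.

    Weights, means and covariances are the empirical statistics of the
    K-means partition; sparse clusters fall back to the global covariance
    so every precision matrix is well-conditioned.
    """
    d = x.shape[1]
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=state)
    labels = km.fit_predict(x)
    global_cov = np.cov(x, rowvar=False, ddof=0) + REG_COVAR * np.eye(d)
    weights = np.empty(k)
    covs = np.empty((k, d, d))
    for j in range(k):
        members = x[labels == j]
        weights[j] = max(members.shape[0], 1) / x.shape[0]
        if members.shape[0] > d + 1:
            covs[j] = (np.cov(members, rowvar=False, ddof=0)
                       + REG_COVAR * np.eye(d))
        else:
            covs[j] = global_cov
    weights /= weights.sum()
    precisions = np.linalg.inv(covs)
    # symmetrize against round-off; sklearn checks symmetry strictly
    precisions = 0.5 * (precisions + precisions.transpose(0, 2, 1))
    return weights, km.cluster_centers_, precisions


def fit_gmm(data: SimilarityMatrix | np.ndarray, k: int,
            seed: int | None = None, n_restarts: int = N_RESTARTS,
            max_iter: int = EM_MAX_ITER, tol: float = EM_TOL) -> SongModel:
    """Fit a K-component full-covariance mixture by multi-restart EM.

    Each restart initializes EM from a K-means solution started from a
    seed-derived random state; the converged restart with the highest
    training log-likelihood wins.  If no restart converges the best
    non-converged fit is returned with ``converged=False`` and a warning.
    """
    x = _as_array(data)
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.shape[0] < k:
        raise ValueError(f"cannot fit {k} components to {x.shape[0]} rows")
    rng = np.random.default_rng(seed)
    best: tuple[float, GaussianMixture] | None = None
    best_any: tuple[float, GaussianMixture] | None = None
    for _ in range(n_restarts):
        state = int(rng.integers(0, 2**31 - 1))
        w0, m0, p0 = _kmeans_init(x, k, state)
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=REG_COVAR, tol=tol, max_iter=max_iter,
                             n_init=1, weights_init=w0, means_init=m0,
                             precisions_init=p0, random_state=state)
        gm.fit(x)
        ll = float(gm.score(x) * x.shape[0])
        if best_any is None or ll > best_any[0]:
            best_any = (ll, gm)
        if gm.converged_ and (best is None or ll > best[0]):
            best = (ll, gm)
    if best is None:
        log.warning("no EM restart converged for k=%d; returning best fit", k)
        best = best_any
    return _from_sklearn(best[1], best[0], seed)


def _heldout_bic(model: SongModel, heldout: np.ndarray) -> float:
    """BIC-style penalized score on held-out data:
    -2 * heldout log-likelihood + n_params * ln(n_heldout)."""
    ll = float(model.log_density(heldout).sum())
    return -2.0 * ll + model.n_parameters() * np.log(heldout.shape[0])


def cv_bic(data: SimilarityMatrix | np.ndarray, k: int, n_folds: int = 3,
           seed: int | None = None, n_restarts: int = N_RESTARTS) -> float:
    """Three-fold (by default) cross-validated BIC for a candidate K.

    Folds are a seeded partition; for each fold the mixture is fit on the
    remaining folds and the penalized score evaluated on the held-out
    fold.  The fold scores are summed.
    """
    x = _as_array(data)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if x.shape[0] < n_folds * k:
        raise ValueError(
            f"{x.shape[0]} rows insufficient for {n_folds}-fold CV at k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(x.shape[0])
    folds = np.array_split(perm, n_folds)
    total = 0.0
    for i, fold in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = fit_gmm(x[train_idx], k, seed=None if seed is None
                        else seed + 1000 * i + k, n_restarts=n_restarts)
        total += _heldout_bic(model, x[fold])
    return total


def select_model(data: SimilarityMatrix | np.ndarray,
                 k_grid: tuple[int, ...] = DEFAULT_K_GRID_AVIAN,
                 seed: int | None = None, n_folds: int = 3,
                 n_restarts: int = N_RESTARTS
                 ) -> tuple[SongModel, ModelSelectionReport]:
    """Choose K by cross-validated BIC over ``k_grid`` and refit on all data."""
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    x = _as_array(data)
    feasible = tuple(sorted(k for k in k_grid
                            if x.shape[0] >= n_folds * k))
    if not feasible:
        raise ValueError(
            f"no candidate in k_grid {tuple(sorted(k_grid))} is feasible "
            f"with {x.shape[0]} rows and {n_folds} folds")
    if len(feasible) < len(set(k_grid)):
        log.warning("restricting k_grid to %s for %d rows",
                    feasible, x.shape[0])
    k_grid = feasible
    scores = [cv_bic(x, k, n_folds=n_folds, seed=seed,
                     n_restarts=n_restarts) for k in k_grid]
    chosen = k_grid[int(np.argmin(scores))]
    report = ModelSelectionReport(
        k_grid=k_grid, cv_bic=tuple(scores), chosen_k=chosen,
        boundary_flag=(chosen == k_grid[0] or chosen == k_grid[-1]))
    if report.boundary_flag and len(k_grid) > 1:
        log.warning("chosen k=%d lies on the edge of the grid %s",
                    chosen, k_grid)
    model = fit_gmm(x, chosen, seed=seed, n_restarts=n_restarts)
    return model, report
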