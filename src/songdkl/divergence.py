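"""Monte-Carlo estimation of Song D_KL between repertoire mixture models.

There is no closed form for the KL divergence between two Gaussian
mixtures, so it is estimated as a difference of cross-entropies evaluated
on held-out reference samples:

    D_KL(P_hat || Q_hat)  =  H(P, Q_hat) - H(P, P_hat)
                          = -(1/N) sum_n log2 q_hat(p_n)
                           +(1/N) sum_n log2 p_hat(p_n)

where p_n are reference-song samples that were NOT used to fit the
reference model P_hat.  The result is in bits: the extra information
needed to encode the reference song with the comparison song's model.
Larger values mean more reference spectral content is missing from the
comparison.  The measure is asymmetric by design; reversing the roles
(reference = tutee) instead quantifies innovation — tutee content absent
from the tutor's song.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix
from .song_model import SongModel, ModelSelectionReport, select_model, \
    DEFAULT_K_GRID_AVIAN

log = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-300  # applied before the log; floored points are counted
LOG2 = np.log(2.0)


@dataclass(frozen=True)
class DklConfig:
    """Knobs of the estimator itself (model-fitting knobs live upstream)."""

    n_fit: int = 3000        # samples used to fit each model, when available
    n_eval: int = 3000       # held-out samples used to evaluate
    k_grid: tuple[int, ...] = DEFAULT_K_GRID_AVIAN
    n_folds: int = 3
    n_restarts: int = 5
    seed: int | None = None


@dataclass(frozen=True)
class SongDklResult:
    """A Song D_KL estimate and its ingredients."""

    dkl_bits: float
    h_p_phat: float          # cross-entropy of held-out refs under ref model
    h_p_qhat: float          # ... under comparison model
    n_eval: int
    n_fit: int
    se_bits: float           # Monte-Carlo standard error of dkl_bits
    ref_model: SongModel = field(repr=False)
    comp_model: SongModel = field(repr=False)
    seed: int | None = None
    n_floored: int = 0

    def __post_init__(self) -> None:
        if abs(self.dkl_bits - (self.h_p_qhat - self.h_p_phat)) > 1e-9:
            raise ValueError("dkl_bits must equal h_p_qhat - h_p_phat")
        if self.n_eval < 1:
            raise ValueError("n_eval must be >= 1")


def _rows(data: SimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, SimilarityMatrix):
        return data.values
    return np.atleast_2d(np.asarray(data, dtype=np.float64))


def cross_entropy(samples: SimilarityMatrix | np.ndarray,
                  model: SongModel) -> float:
    """H(P, model) in bits: -(1/N) sum log2 density(sample).

    Densities are floored at a tiny positive constant before the log so a
    single pathological point cannot produce -inf.
    """
    x = _rows(samples)
    if x.shape[0] == 0:
        raise ValueError("cross-entropy of an empty sample set is undefined")
    log2_dens, n_floored = _floored_log2_density(x, model)
    if n_floored:
        log.warning("%d of %d densities floored at %g",
                    n_floored, x.shape[0], DENSITY_FLOOR)
    return float(-log2_dens.mean())


def _floored_log2_density(x: np.ndarray, model: SongModel
                          ) -> tuple[np.ndarray, int]:
    ln_dens = model.log_density(x)
    floor_ln = np.log(DENSITY_FLOOR)
    n_floored = int((ln_dens < floor_ln).sum())
    return np.maximum(ln_dens, floor_ln) / LOG2, n_floored


def dkl_from_models(ref_heldout: SimilarityMatrix | np.ndarray,
                    ref_model: SongModel, comp_model: SongModel,
                    n_fit: int = 0, seed: int | None = None) -> SongDklResult:
    """Song D_KL given two already-fitted models and held-out reference rows."""
    x = _rows(ref_heldout)
    lp, fp = _floored_log2_density(x, ref_model)
    lq, fq = _floored_log2_density(x, comp_model)
    per_point = lp - lq                     # log2 p_hat - log2 q_hat
    dkl = float(per_point.mean())
    se = float(per_point.std(ddof=1) / np.sqrt(x.shape[0])) \
        if x.shape[0] > 1 else float("nan")
    return SongDklResult(
        dkl_bits=dkl, h_p_phat=float(-lp.mean()), h_p_qhat=float(-lq.mean()),
        n_eval=x.shape[0], n_fit=n_fit, se_bits=se,
        ref_model=ref_model, comp_model=comp_model, seed=seed,
        n_floored=fp + fq)


def split_fit_eval(n_rows: int, config: DklConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint fit/evaluation index sets for the reference repertoire.

    With at least ``n_fit + n_eval`` rows the requested sizes are used;
    otherwise the rows are split 50/50.
    """
    perm = rng.permutation(n_rows)
    if n_rows >= config.n_fit + config.n_eval:
        return perm[:config.n_fit], perm[config.n_fit:config.n_fit + config.n_eval]
    half = n_rows // 2
    log.warning("only %d reference rows; splitting 50/50 instead of %d/%d",
                n_rows, config.n_fit, config.n_eval)
    return perm[:half], perm[half:]


def song_dkl(ref: SimilarityMatrix | np.ndarray,
             comp: SimilarityMatrix | np.ndarray,
             config: DklConfig | None = None,
             ref_model: SongModel | None = None,
             comp_model: SongModel | None = None,
             ) -> tuple[SongDklResult, ModelSelectionReport | None, ModelSelectionReport | None]:
    """Full Song D_KL between two repertoires in one shared similarity-space.

    The reference rows are split into disjoint fit and evaluation sets;
    models are selected by cross-validated BIC (unless pre-fitted models
    are supplied) and the divergence estimated on the evaluation set.
    Returns the result plus the two model-selection reports (None where a
    pre-fitted model was supplied).
    """
    config = config or DklConfig()
    xr, xc = _rows(ref), _rows(comp)
    if xr.shape[1] != xc.shape[1]:
        raise ValueError("reference and comparison must share one basis space")
    rng = np.random.default_rng(config.seed)
    fit_idx, eval_idx = split_fit_eval(xr.shape[0], config, rng)
    ref_report = comp_report = None
    if ref_model is None:
        ref_model, ref_report = select_model(
            xr[fit_idx], k_grid=config.k_grid, seed=config.seed,
            n_folds=config.n_folds, n_restarts=config.n_restarts)
    if comp_model is None:
        comp_fit = xc if xc.shape[0] <= config.n_fit else \
            xc[rng.choice(xc.shape[0], size=config.n_fit, replace=False)]
        comp_model, comp_report = select_model(
            comp_fit, k_grid=config.k_grid, seed=config.seed,
            n_folds=config.n_folds, n_restarts=config.n_restarts)
    result = dkl_from_models(xr[eval_idx], ref_model, comp_model,
                             n_fit=len(fit_idx), seed=config.seed)
    return result, ref_report, comp_report


def innovation_dkl(tutee: SimilarityMatrix | np.ndarray,
                   tutor: SimilarityMatrix | np.ndarray,
                   config: DklConfig | None = None, **kw):
    """Innovation: Song D_KL with roles reversed (reference = tutee).

    Quantifies tutee song content absent from the tutor's song.
    """
    return song_dkl(tutee, tutor, config, **kw)


def split_half_baseline(data: SimilarityMatrix | np.ndarray,
                        config: DklConfig | None = None
                        ) -> SongDklResult:
    """Self-comparison noise floor: halve the repertoire at random and
    compute Song D_KL between the halves."""
    config = config or DklConfig()
    x = _rows(data)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 rows for a split-half baseline")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(x.shape[0])
    half = x.shape[0] // 2
    result, _, _ = song_dkl(x[perm[:half]], x[perm[half:]], config)
    return result
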