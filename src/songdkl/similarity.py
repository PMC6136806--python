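"""Basis-syllable similarity embedding.

Each syllable PSD is represented by its similarity to each of N basis
syllables drawn from the reference repertoire: an M x N matrix whose rows
are points in an N-dimensional "similarity-space".  Mixture models and
the divergence estimate all live in this space.  Similarities derive from
squared Euclidean distances between PSDs, normalized by the global
maximum distance so both repertoires of a comparison share one scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .spectral import PsdVector

log = logging.getLogger(__name__)

BOUNDED = "bounded"        # A = 1 - D / max(D), in [0, 1]
RECIPROCAL = "reciprocal"  # A = 1 / (D / max(D)); unbounded at D = 0


@dataclass(frozen=True)
class BasisSet:
    """N reference-syllable PSDs whose similarities define the embedding axes."""

    psds: list[PsdVector]
    selection: str = "random"
    seed: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.psds) < 2:
            raise ValueError("a basis needs at least 2 PSDs")
        dims = {pv.values.size for pv in self.psds}
        if len(dims) != 1:
            raise ValueError(f"basis PSDs have mixed dimensions: {sorted(dims)}")

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([pv.values for pv in self.psds])

    def __len__(self) -> int:
        return len(self.psds)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Rows = sample syllables in similarity-space; columns = basis syllables."""

    values: np.ndarray
    row_ids: list[str]
    basis: BasisSet | None = None
    form: str = BOUNDED

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix contains non-finite values")
        if self.form == BOUNDED and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("bounded similarities must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


def build_basis(psds: list[PsdVector], n_basis: int = 50,
                selection: str = "random", seed: int | None = None,
                source: str = "") -> BasisSet:
    """Draw a basis of ``n_basis`` PSDs, either the first N or a seeded
    random draw without replacement."""
    if len(psds) < n_basis:
        raise ValueError(
            f"need at least {n_basis} PSDs to build a basis, have {len(psds)}")
    if selection == "first":
        chosen = list(psds[:n_basis])
    elif selection == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(psds), size=n_basis, replace=False)
        chosen = [psds[i] for i in idx]
    else:
        raise ValueError(f"unknown basis selection {selection!r}")
    return BasisSet(psds=chosen, selection=selection, seed=seed, source=source)


def _to_matrix(samples: list[PsdVector] | np.ndarray) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        return np.asarray(samples, dtype=np.float64)
    return np.vstack([pv.values for pv in samples])


def _apply_form(d: np.ndarray, d_max: float, form: str) -> np.ndarray:
    if d_max <= 0:
        raise ValueError("all PSDs identical (max distance 0): degenerate data")
    if form == BOUNDED:
        return 1.0 - d / d_max
    if form == RECIPROCAL:
        with np.errstate(divide="ignore"):
            a = d_max / np.where(d > 0, d, np.inf)
        finite_max = a[np.isfinite(a)].max() if np.isfinite(a).any() else 1.0
        return np.where(d > 0, a, finite_max)
    raise ValueError(f"unknown similarity form {form!r}")


def similarity_matrix(samples: list[PsdVector] | np.ndarray, basis: BasisSet,
                      form: str = BOUNDED,
                      row_ids: list[str] | None = None) -> SimilarityMatrix:
    """Project sample PSDs into similarity-space relative to ``basis``.

    max(D) is taken over this matrix alone; to place two repertoires on a
    shared scale use :func:`project_pair`.
    """
    x = _to_matrix(samples)
    b = basis.matrix
    if x.shape[1] != b.shape[1]:
        raise ValueError(
            f"sample dimension {x.shape[1]} != basis dimension {b.shape[1]}")
    d = cdist(x, b, metric="sqeuclidean")
    a = _apply_form(d, float(d.max()), form)
    if row_ids is None:
        if isinstance(samples, np.ndarray):
            row_ids = [str(i) for i in range(x.shape[0])]
        else:
            row_ids = [pv.source_segment or str(i)
                       for i, pv in enumerate(samples)]
    return SimilarityMatrix(values=a, row_ids=row_ids, basis=basis, form=form)


def project_pair(ref: list[PsdVector] | np.ndarray,
                 comp: list[PsdVector] | np.ndarray, basis: BasisSet,
                 form: str = BOUNDED) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Project reference and comparison repertoires with one basis and one
    max(D) normalization taken over their union, so both live on one scale."""
    xr, xc = _to_matrix(ref), _to_matrix(comp)
    b = basis.matrix
    for name, x in (("reference", xr), ("comparison", xc)):
        if x.shape[1] != b.shape[1]:
            raise ValueError(
                f"{name} dimension {x.shape[1]} != basis dimension {b.shape[1]}")
    dr = cdist(xr, b, metric="sqeuclidean")
    dc = cdist(xc, b, metric="sqeuclidean")
    d_max = float(max(dr.max(), dc.max()))
    ar = _apply_form(dr, d_max, form)
    ac = _apply_form(dc, d_max, form)
    mk = lambda a, src: SimilarityMatrix(
        values=a, row_ids=[str(i) for i in range(a.shape[0])],
        basis=basis, form=form)
    return mk(ar, "ref"), mk(ac, "comp")


def write_similarity_matrix(path, m: SimilarityMatrix) -> None:
    """Persist as CSV (rows = samples, columns = basis ids) with a sidecar
    JSON recording the form, seed and basis provenance."""
    import json
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    cols = ([pv.source_segment or str(j)
             for j, pv in enumerate(m.basis.psds)]
            if m.basis is not None else
            [str(j) for j in range(m.n_basis)])
    pd.DataFrame(m.values, index=pd.Index(m.row_ids, name="segment_id"),
                 columns=cols).to_csv(path)
    meta = {"form": m.form,
            "basis_seed": m.basis.seed if m.basis else None,
            "basis_selection": m.basis.selection if m.basis else None,
            "basis_source": m.basis.source if m.basis else None,
            "n_basis": m.n_basis}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_similarity_matrix(path) -> SimilarityMatrix:
    import json
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    df = pd.read_csv(path, index_col="segment_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    form = BOUNDED
    if sidecar.exists():
        form = json.loads(sidecar.read_text()).get("form", BOUNDED)
    return SimilarityMatrix(values=df.to_numpy(dtype=float),
                            row_ids=[str(i) for i in df.index],
                            basis=None, form=form)


def sample_rows(m: np.ndarray, n: int, seed: int | None = None) -> np.ndarray:
    """Uniform draw of ``n`` rows without replacement; all rows (with a
    warning) when fewer exist."""
    if m.shape[0] <= n:
        if m.shape[0] < n:
            log.warning("requested %d rows but only %d available; using all",
                        n, m.shape[0])
        return m
    rng = np.random.default_rng(seed)
    idx = rng.choice(m.shape[0], size=n, replace=False)
    return m[idx]
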