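"""End-to-end orchestration: WAV directories in, results out.

Each ``run_*`` function chains the front end (high-pass filter,
segmentation, PSD extraction), the similarity embedding, and the
model-based stage it is named for.  All stochastic steps draw from
explicit seeds in :class:`RunConfig`, so a run is exactly reproducible
from its persisted config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import FilterSpec, highpass, read_wav
from .classification import LabeledSyllable, classify, write_label_table
from .divergence import DklConfig, SongDklResult, innovation_dkl, song_dkl
from .segmentation import Segment, SegmentationParams, segment_recording
from .similarity import BOUNDED, build_basis, project_pair, similarity_matrix
from .song_model import DEFAULT_K_GRID_AVIAN, ModelSelectionReport, SongModel, \
    select_model
from .spectral import PsdParams, PsdVector, syllable_psd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters; defaults are the method's standard values
    (N=50 basis syllables, M=3000 sample syllables, 3-fold CV, avian
    segmentation and K grid)."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    psd: PsdParams = field(default_factory=PsdParams)
    n_basis: int = 50
    n_samples: int = 3000
    similarity_form: str = BOUNDED
    k_grid: tuple[int, ...] = DEFAULT_K_GRID_AVIAN
    n_folds: int = 3
    n_restarts: int = 5
    seed: int = 0

    def dkl_config(self) -> DklConfig:
        return DklConfig(n_fit=self.n_samples, n_eval=self.n_samples,
                         k_grid=self.k_grid, n_folds=self.n_folds,
                         n_restarts=self.n_restarts, seed=self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_grid"] = list(self.k_grid)
        d["provenance"] = {"tool": "songdkl", "version": __version__}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.pop("provenance", None)
        return cls(filter=FilterSpec(**d.pop("filter", {})),
                   segmentation=SegmentationParams(**d.pop("segmentation", {})),
                   psd=PsdParams(**d.pop("psd", {})),
                   k_grid=tuple(d.pop("k_grid", DEFAULT_K_GRID_AVIAN)),
                   **d)


def _wav_paths(source: str | Path | list) -> list[Path]:
    if isinstance(source, (list, tuple)):
        return [Path(p) for p in source]
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("*.wav"))
        if not paths:
            raise FileNotFoundError(f"no WAV files in directory {source}")
        return paths
    return [source]


def wavs_to_psds(source: str | Path | list, config: RunConfig | None = None
                 ) -> tuple[list[PsdVector], list[Segment]]:
    """Front end: read, filter, segment and spectrally summarize a WAV set."""
    config = config or RunConfig()
    psds: list[PsdVector] = []
    segments: list[Segment] = []
    for path in _wav_paths(source):
        w = highpass(read_wav(path), config.filter)
        segs = segment_recording(w, config.segmentation, source=path.name)
        log.info("%s: %d syllables", path.name, len(segs))
        for i, s in enumerate(segs):
            s = dataclasses.replace(s, source=f"{path.name}:{i}")
            segments.append(s)
            psds.append(dataclasses.replace(
                _psd_one(s, config, w.rate), source_segment=s.source))
    if not psds:
        raise ValueError(f"no syllables segmented from {source}")
    return psds, segments


def _psd_one(seg: Segment, config: RunConfig, rate: float) -> PsdVector:
    return syllable_psd(seg, config.psd, rate=rate)


def song_to_similarity(ref_psds: list[PsdVector], comp_psds: list[PsdVector],
                       config: RunConfig):
    """Reference-basis projection of both repertoires on one scale."""
    basis = build_basis(ref_psds, n_basis=config.n_basis, selection="random",
                        seed=config.seed, source="reference")
    return project_pair(ref_psds, comp_psds, basis, form=config.similarity_form)


def run_numsyls(source: str | Path | list, config: RunConfig | None = None,
                out_dir: str | Path | None = None
                ) -> ModelSelectionReport:
    """Estimate the number of syllable types in a repertoire."""
    config = config or RunConfig()
    psds, _ = wavs_to_psds(source, config)
    basis = build_basis(psds, n_basis=min(config.n_basis, len(psds)),
                        selection="random", seed=config.seed)
    sim = similarity_matrix(psds, basis, form=config.similarity_form)
    rows = sim.values
    if rows.shape[0] > config.n_samples:
        rng = np.random.default_rng(config.seed)
        rows = rows[rng.choice(rows.shape[0], config.n_samples, replace=False)]
    grid = tuple(k for k in config.k_grid if k * config.n_folds <= rows.shape[0])
    _, report = select_model(rows, k_grid=grid, seed=config.seed,
                             n_folds=config.n_folds,
                             n_restarts=config.n_restarts)
    if out_dir is not None:
        _dump_json(Path(out_dir) / "numsyls.json",
                   {"k_grid": list(report.k_grid),
                    "cv_bic": list(report.cv_bic),
                    "chosen_k": report.chosen_k,
                    "boundary_flag": report.boundary_flag,
                    "config_hash": config.config_hash()})
    return report


def run_songdkl(ref: str | Path | list, comp: str | Path | list,
                config: RunConfig | None = None,
                out_dir: str | Path | None = None,
                reverse: bool = False) -> SongDklResult:
    """Full Song D_KL between a reference and a comparison WAV set.

    With ``reverse=True`` the roles are swapped after the front end, i.e.
    the innovation measure with the basis still drawn from the (original)
    reference song."""
    config = config or RunConfig()
    ref_psds, _ = wavs_to_psds(ref, config)
    comp_psds, _ = wavs_to_psds(comp, config)
    sim_ref, sim_comp = song_to_similarity(ref_psds, comp_psds, config)
    dkl_cfg = config.dkl_config()
    if reverse:
        result, _, _ = innovation_dkl(sim_comp.values, sim_ref.values, dkl_cfg)
    else:
        result, _, _ = song_dkl(sim_ref.values, sim_comp.values, dkl_cfg)
    if out_dir is not None:
        _dump_json(Path(out_dir) / ("innovation.json" if reverse
                                    else "songdkl.json"),
                   result_record(result, config))
    return result


def run_classify(source: str | Path | list, config: RunConfig | None = None,
                 model: SongModel | None = None,
                 out_path: str | Path | None = None
                 ) -> tuple[list[LabeledSyllable], SongModel]:
    """Segment a repertoire and label each syllable by mixture component."""
    config = config or RunConfig()
    psds, segments = wavs_to_psds(source, config)
    basis = build_basis(psds, n_basis=min(config.n_basis, len(psds)),
                        selection="random", seed=config.seed)
    sim = similarity_matrix(psds, basis, form=config.similarity_form)
    if model is None:
        rows = sim.values
        if rows.shape[0] > config.n_samples:
            rng = np.random.default_rng(config.seed)
            rows = rows[rng.choice(rows.shape[0], config.n_samples,
                                   replace=False)]
        grid = tuple(k for k in config.k_grid
                     if k * config.n_folds <= rows.shape[0])
        model, _ = select_model(rows, k_grid=grid, seed=config.seed,
                                n_folds=config.n_folds,
                                n_restarts=config.n_restarts)
    labels = classify(model, sim)
    if out_path is not None:
        seg_df = pd.DataFrame({
            "segment_id": [s.source for s in segments],
            "onset_s": [s.onset_s for s in segments],
            "offset_s": [s.offset_s for s in segments]})
        write_label_table(out_path, labels, seg_df)
    return labels, model


def run_split_half(source: str | Path | list, config: RunConfig | None = None
                   ) -> SongDklResult:
    """Split-half self-divergence: the noise-floor baseline for a repertoire."""
    config = config or RunConfig()
    psds, _ = wavs_to_psds(source, config)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(psds))
    half = len(psds) // 2
    ref = [psds[i] for i in perm[:half]]
    comp = [psds[i] for i in perm[half:]]
    sim_ref, sim_comp = song_to_similarity(ref, comp, config)
    result, _, _ = song_dkl(sim_ref.values, sim_comp.values,
                            config.dkl_config())
    return result


def result_record(result: SongDklResult, config: RunConfig) -> dict:
    return {"dkl_bits": result.dkl_bits, "h_p_phat": result.h_p_phat,
            "h_p_qhat": result.h_p_qhat, "se_bits": result.se_bits,
            "n_eval": result.n_eval, "n_fit": result.n_fit,
            "ref_k": result.ref_model.k, "comp_k": result.comp_model.k,
            "n_floored": result.n_floored,
            "config": config.to_dict(),
            "config_hash": config.config_hash()}


def _dump_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2))


def run_batch(manifest: str | Path, config: RunConfig | None = None,
              out_path: str | Path | None = None) -> pd.DataFrame:
    """Cohort mode: manifest CSV with columns bird_id, role, path.

    Every bird with role ``comparison`` is scored against every bird with
    role ``reference``; one row per pair."""
    config = config or RunConfig()
    df = pd.read_csv(manifest)
    missing = {"bird_id", "role", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    refs = df[df["role"] == "reference"]
    comps = df[df["role"] == "comparison"]
    rows = []
    for r in refs.itertuples():
        for c in comps.itertuples():
            res = run_songdkl(r.path, c.path, config)
            rows.append({"reference": r.bird_id, "comparison": c.bird_id,
                         "dkl_bits": res.dkl_bits, "se_bits": res.se_bits,
                         "n_eval": res.n_eval})
    out = pd.DataFrame(rows)
    if out_path is not None:
        out.to_csv(out_path, index=False)
    return out
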