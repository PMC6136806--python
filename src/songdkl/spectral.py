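"""Welch power-spectral-density features for segmented syllables.

Each syllable is reduced to its time-averaged power spectrum: 4096-point
FFT windows advanced so consecutive windows share 256 samples, the final
window zero-padded to full length, periodograms averaged, and the
one-sided spectrum band-restricted (600 Hz to Nyquist by default).  The
resulting vector — optionally unit-sum normalized so it reflects spectral
shape rather than recording gain — is the sole representation of a
syllable from here on; all temporal structure within the syllable is
deliberately discarded (unless multi-block PSDs are requested).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import welch

from .segmentation import Segment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsdParams:
    """Spectral-feature configuration.

    ``overlap`` is the number of samples shared by consecutive FFT windows
    (hop = n_fft - overlap).  ``band_hi_hz=None`` means Nyquist.  With the
    defaults at 32 kHz the band vector has 1971 bins.  ``n_blocks > 1``
    splits each syllable into equal-duration pieces and concatenates their
    PSDs, restoring coarse spectro-temporal structure.
    """

    n_fft: int = 4096
    overlap: int = 256
    n_freqs: int = 2048
    band_lo_hz: float = 600.0
    band_hi_hz: float | None = None
    n_blocks: int = 1
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_fft <= 0 or (self.n_fft & (self.n_fft - 1)) != 0:
            raise ValueError("n_fft must be a positive power of two")
        if not 0 <= self.overlap < self.n_fft:
            raise ValueError("overlap must satisfy 0 <= overlap < n_fft")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    def band_indices(self, rate: float) -> np.ndarray:
        """Indices of the retained one-sided bins for a given sample rate."""
        hi = rate / 2.0 if self.band_hi_hz is None else self.band_hi_hz
        if not self.band_lo_hz < hi <= rate / 2.0 + 1e-9:
            raise ValueError(
                f"band [{self.band_lo_hz}, {hi}] Hz invalid for rate {rate}")
        freqs = np.arange(self.n_freqs) * rate / self.n_fft
        return np.flatnonzero((freqs >= self.band_lo_hz) & (freqs <= hi))


@dataclass(frozen=True)
class PsdVector:
    """Band-restricted PSD of one syllable (blocks concatenated in time order)."""

    values: np.ndarray
    freqs_hz: np.ndarray
    n_blocks: int = 1
    source_segment: str = ""


def _welch_psd(samples: np.ndarray, rate: float, p: PsdParams) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch periodogram average with zero-padded final window."""
    hop = p.n_fft - p.overlap
    n = samples.size
    if n <= p.n_fft:
        n_windows = 1
    else:
        n_windows = 1 + int(np.ceil((n - p.n_fft) / hop))
    padded_len = p.n_fft + (n_windows - 1) * hop
    padded = np.zeros(padded_len)
    padded[:n] = samples
    freqs, psd = welch(padded, fs=rate, window="boxcar", nperseg=p.n_fft,
                       noverlap=p.overlap, detrend=False, scaling="density")
    return freqs[: p.n_freqs], psd[: p.n_freqs]


def syllable_psd(seg: Segment, p: PsdParams | None = None,
                 rate: float | None = None) -> PsdVector:
    """Time-averaged, band-restricted PSD of one segment.

    ``rate`` defaults to the rate implied by the segment's duration and
    sample count.
    """
    p = p or PsdParams()
    samples = np.asarray(seg.samples, dtype=np.float64)
    if samples.size == 0:
        raise ValueError("cannot compute PSD of an empty segment")
    if rate is None:
        rate = samples.size / seg.duration_s
    if p.n_blocks > 1:
        return multi_block_psd(seg, p, rate=rate)
    freqs, psd = _welch_psd(samples, rate, p)
    band = p.band_indices(rate)
    values = psd[band]
    if p.normalize:
        total = values.sum()
        if total > 0:
            values = values / total
        else:
            warnings.warn("all-zero segment: skipping PSD normalization")
    return PsdVector(values=values, freqs_hz=freqs[band], n_blocks=1,
                     source_segment=seg.source)


def multi_block_psd(seg: Segment, p: PsdParams, rate: float | None = None) -> PsdVector:
    """Split a segment into ``n_blocks`` equal-duration pieces; concatenate PSDs."""
    if p.n_blocks < 2:
        return syllable_psd(seg, replace(p, n_blocks=1), rate=rate)
    samples = np.asarray(seg.samples, dtype=np.float64)
    if samples.size < p.n_blocks:
        raise ValueError(
            f"segment of {samples.size} samples too short for {p.n_blocks} blocks")
    if rate is None:
        rate = samples.size / seg.duration_s
    block_p = replace(p, n_blocks=1)
    edges = np.linspace(0, samples.size, p.n_blocks + 1).round().astype(int)
    dur = seg.duration_s / p.n_blocks
    parts, freqs = [], None
    for i in range(p.n_blocks):
        sub = Segment(onset_s=0.0, offset_s=dur,
                      samples=samples[edges[i]:edges[i + 1]],
                      source=seg.source)
        pv = syllable_psd(sub, block_p, rate=rate)
        parts.append(pv.values)
        freqs = pv.freqs_hz
    return PsdVector(values=np.concatenate(parts),
                     freqs_hz=np.tile(freqs, p.n_blocks),
                     n_blocks=p.n_blocks, source_segment=seg.source)


def psds_from_segments(segments: list[Segment], p: PsdParams | None = None,
                       rate: float | None = None) -> list[PsdVector]:
    p = p or PsdParams()
    return [syllable_psd(s, p, rate=rate) for s in segments]


def write_psd_table(path: str | Path, psds: list[PsdVector],
                    params: PsdParams) -> None:
    """One row per segment; PsdParams stored in a sidecar JSON for self-description."""
    path = Path(path)
    mat = np.vstack([pv.values for pv in psds])
    ids = [pv.source_segment or str(i) for i, pv in enumerate(psds)]
    df = pd.DataFrame(mat, index=pd.Index(ids, name="segment_id"))
    df.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(params), indent=2))


def read_psd_table(path: str | Path) -> tuple[np.ndarray, list[str], PsdParams | None]:
    path = Path(path)
    df = pd.read_csv(path, index_col="segment_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    params = None
    if sidecar.exists():
        params = PsdParams(**json.loads(sidecar.read_text()))
    return df.to_numpy(dtype=float), [str(i) for i in df.index], params
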