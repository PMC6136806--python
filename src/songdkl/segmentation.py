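"""Syllable segmentation by amplitude-envelope thresholding.

A rectified, smoothed amplitude envelope is thresholded with an
automatically chosen (Otsu) threshold; supra-threshold runs become
candidate vocalizations, which are then merged across short gaps, filtered
by minimum duration, and padded.  Rule order is fixed: merge, then
minimum-duration filter, then pad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .audio import Waveform

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Envelope:
    """Smoothed rectified amplitude, index-aligned with its source waveform."""

    values: np.ndarray
    rate: float


@dataclass(frozen=True)
class SegmentationParams:
    """Defaults follow avian song analysis; use min_dur_ms=50 for speech."""

    smooth_ms: float = 8.0
    merge_gap_ms: float = 5.0
    min_dur_ms: float = 10.0
    pad_ms: float = 3.0
    n_otsu_bins: int = 256

    def __post_init__(self) -> None:
        for name in ("smooth_ms", "merge_gap_ms", "min_dur_ms", "pad_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Segment:
    """One detected vocalization, with its excerpt of the filtered waveform."""

    onset_s: float
    offset_s: float
    samples: np.ndarray = field(repr=False)
    source: str = ""

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def amplitude_envelope(w: Waveform, smooth_ms: float = 8.0) -> Envelope:
    """Rectify and smooth with a unit-area square window of ``smooth_ms``.

    The convolution is same-length and centered, so envelope index i refers
    to waveform sample i.
    """
    if smooth_ms <= 0:
        raise ValueError("smooth_ms must be positive")
    n_win = max(1, int(round(smooth_ms * w.rate / 1000.0)))
    if n_win > w.samples.size:
        raise ValueError(
            f"smoothing window ({n_win} samples) longer than signal "
            f"({w.samples.size} samples)")
    window = np.full(n_win, 1.0 / n_win)
    values = fftconvolve(np.abs(w.samples), window, mode="same")
    # fftconvolve round-off can give tiny negatives on silent stretches
    np.maximum(values, 0.0, out=values)
    return Envelope(values=values, rate=w.rate)


def otsu_threshold(e: Envelope | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold over a histogram of envelope values.

    Candidate thresholds are interior bin edges of an ``n_bins`` histogram
    spanning [min, max]; the returned edge maximizes the between-class
    variance (equivalently minimizes within-class variance) of the split.
    """
    values = e.values if isinstance(e, Envelope) else np.asarray(e, float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        raise ValueError("constant envelope: no threshold separates classes")
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1].astype(float)          # mass below edge k+1
    w1 = counts.sum() - w0
    mass = np.cumsum(counts * centers)[:-1]
    mu0 = np.divide(mass, w0, out=np.zeros_like(mass), where=w0 > 0)
    mu1 = np.divide(mass[-1] + counts[-1] * centers[-1] - mass, w1,
                    out=np.zeros_like(mass), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # argmax takes the first maximizer; edges[1:-1] are the interior edges
    return float(edges[1:-1][int(np.argmax(between))])


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def merge_runs(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    """Merge consecutive runs separated by ``max_gap`` samples or fewer."""
    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def segment(w: Waveform, e: Envelope, threshold: float,
            params: SegmentationParams | None = None,
            source: str = "") -> list[Segment]:
    """Threshold the envelope and return padded vocalization segments.

    Rules, in order: (1) maximal runs with envelope > threshold; (2) merge
    runs separated by <= merge_gap_ms; (3) drop runs shorter than
    min_dur_ms; (4) pad by pad_ms each side, clipping at recording edges
    and at the midpoint of any gap that padding would overlap; (5) extract
    samples from the (filtered) waveform.
    """
    params = params or SegmentationParams()
    rate = w.rate
    ms = rate / 1000.0
    runs = _runs_above(e.values > threshold)
    runs = merge_runs(runs, int(round(params.merge_gap_ms * ms)))
    min_len = int(round(params.min_dur_ms * ms))
    runs = [(a, b) for a, b in runs if b - a >= min_len]
    pad = int(round(params.pad_ms * ms))
    out: list[Segment] = []
    n = w.samples.size
    for i, (a, b) in enumerate(runs):
        lo = a - pad
        hi = b + pad
        if i > 0:
            lo = max(lo, (runs[i - 1][1] + a) // 2)
        if i + 1 < len(runs):
            hi = min(hi, (b + runs[i + 1][0]) // 2)
        lo = max(lo, 0)
        hi = min(hi, n)
        out.append(Segment(onset_s=lo / rate, offset_s=hi / rate,
                           samples=w.samples[lo:hi].copy(), source=source))
    return out


def segment_recording(w: Waveform, params: SegmentationParams | None = None,
                      source: str = "") -> list[Segment]:
    """Envelope, per-recording Otsu threshold, and segmentation in one call."""
    params = params or SegmentationParams()
    env = amplitude_envelope(w, params.smooth_ms)
    thr = otsu_threshold(env, params.n_otsu_bins)
    return segment(w, env, thr, params, source=source)


def write_segment_table(path: str | Path, segments: list[Segment]) -> None:
    """Persist segments as CSV: source, onset_s, offset_s (6 decimals)."""
    df = pd.DataFrame({"source": [s.source for s in segments],
                       "onset_s": [round(s.onset_s, 6) for s in segments],
                       "offset_s": [round(s.offset_s, 6) for s in segments]})
    df.to_csv(path, index=False, float_format="%.6f")


def read_segment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"source", "onset_s", "offset_s"} - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    return df


def extract_segments(w: Waveform, table: pd.DataFrame,
                     source: str | None = None) -> list[Segment]:
    """Rebuild Segment objects from a table row set against a waveform."""
    rows = table if source is None else table[table["source"] == source]
    out = []
    for row in rows.itertuples():
        a = int(round(row.onset_s * w.rate))
        b = int(round(row.offset_s * w.rate))
        out.append(Segment(onset_s=row.onset_s, offset_s=row.offset_s,
                           samples=w.samples[a:b].copy(), source=row.source))
    return out
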