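"""WAV ingestion and the fixed high-pass pre-filter.

Every recording entering the pipeline passes through :func:`read_wav` and
:func:`highpass` before segmentation, so that amplitude thresholds and
spectral features are comparable across recorders, bit depths and gain
settings.  Low-frequency content (cage noise, wing flaps, mains hum) is
removed with an elliptic IIR high-pass before any envelope is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import ellip, lfilter


@dataclass(frozen=True)
class Waveform:
    """Mono audio: float samples in [-1, 1] plus the sample rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", s)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if s.ndim != 1 or s.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FilterSpec:
    """Elliptic IIR high-pass design.

    The cutoff may be given in Hz (``cutoff_hz``, default 500) or as a
    normalized passband-edge frequency in radians/sample
    (``passband_edge_rad``), which takes precedence when set.  Order and
    ripple are design choices exposed here because only the family and
    cutoff are fixed by the method; the divergence estimate downstream is
    insensitive to them.
    """

    cutoff_hz: float = 500.0
    passband_edge_rad: float | None = None
    order: int = 4
    passband_ripple_db: float = 0.1
    stopband_atten_db: float = 40.0

    def edge_hz(self, rate: float) -> float:
        """Resolve the passband edge to Hz for a given sample rate."""
        if self.passband_edge_rad is not None:
            if not 0.0 < self.passband_edge_rad < np.pi:
                raise ValueError("passband_edge_rad must lie in (0, pi)")
            return self.passband_edge_rad * rate / (2.0 * np.pi)
        return self.cutoff_hz


# integer PCM full-scale magnitudes for float conversion
_PCM_SCALE = {np.dtype(np.int16): 32768.0, np.dtype(np.int32): 2147483648.0,
              np.dtype(np.uint8): 128.0}


def read_wav(path: str | Path) -> Waveform:
    """Read a mono RIFF PCM WAV file, scaling samples to [-1, 1].

    Stereo files are rejected rather than downmixed: channel mixing changes
    amplitude statistics and therefore segmentation thresholds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype.kind == "f":
        samples = data.astype(np.float64)
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    return Waveform(samples=samples, rate=float(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a Waveform as 16-bit PCM mono WAV (values clipped to [-1, 1])."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(Path(path)), int(round(w.rate)), pcm)


def highpass(w: Waveform, spec: FilterSpec | None = None) -> Waveform:
    """Apply the elliptic high-pass filter, forward-only (causal).

    Returns a waveform of identical length and rate.
    """
    spec = spec or FilterSpec()
    edge = spec.edge_hz(w.rate)
    nyq = w.rate / 2.0
    if not 0.0 < edge < nyq:
        raise ValueError(
            f"high-pass edge {edge:g} Hz outside (0, Nyquist={nyq:g} Hz)")
    b, a = ellip(spec.order, spec.passband_ripple_db, spec.stopband_atten_db,
                 edge / nyq, btype="highpass")
    return Waveform(samples=lfilter(b, a, w.samples), rate=w.rate)
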