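"""Synthetic songs with known ground truth.

Emulates the structure of adult passerine song for pipeline validation:
a repertoire of 5-10 categorically distinct syllable types (harmonic
stacks, band-limited noise bursts, frequency sweeps), 30-200 ms each,
produced in sequence with silent gaps, with per-rendition jitter in
fundamental frequency, duration and amplitude.  Tutor/tutee pairs with
controllable copy quality are produced by re-rendering a repertoire with
extra spectral jitter, omitted types, or innovated (novel) types.

Everything is deterministic given the SongSpec seed, and every rendered
syllable's exact sample boundaries, type and provenance are returned, so
segmentation, classification and divergence results can be scored against
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from .audio import Waveform

RAMP_MS = 5.0  # raised-cosine onset/offset, avoids segmentation edge artifacts


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable type.

    ``f0_hz`` is the fundamental (harmonic stack), band low edge (noise
    burst) or start frequency (sweep); ``f1_hz`` the band high edge or
    sweep end frequency.
    """

    kind: str  # harmonic_stack | noise_band | sweep
    f0_hz: float
    f1_hz: float | None = None
    n_harmonics: int = 8
    duration_ms: float = 80.0
    amplitude: float = 0.25  # RMS-equivalent sine level; keeps peaks < 1
    # gentle downward glide on harmonic stacks: spreads each harmonic over
    # a band ~glide_frac wide, as in natural song, so that per-rendition
    # f0 jitter moves spectral peaks by less than their own width
    glide_frac: float = 0.06

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic_stack", "noise_band", "sweep"):
            raise ValueError(f"unknown syllable kind {self.kind!r}")
        if self.duration_ms < 10:
            raise ValueError("syllable duration must be >= 10 ms")
        if self.kind in ("noise_band", "sweep") and self.f1_hz is None:
            raise ValueError(f"{self.kind} requires f1_hz")


@dataclass(frozen=True)
class JitterSpec:
    """Per-rendition variability: multiplicative log-normal on f0 and
    duration, relative Gaussian on amplitude, plus an additive white-noise
    floor over the whole recording."""

    f0_frac: float = 0.005   # ~0.5% pitch CV, typical of crystallized song
    dur_frac: float = 0.05
    amp_frac: float = 0.1
    noise_floor: float = 0.002

    def __post_init__(self) -> None:
        for name in ("f0_frac", "dur_frac", "amp_frac", "noise_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SongSpec:
    repertoire: tuple[SyllableSpec, ...]
    sequence: tuple[int, ...] | None = None   # one motif; default = all types in order
    gap_ms: tuple[float, float] = (20.0, 40.0)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    n_renditions: int = 50                     # motif repetitions
    rate: float = 32000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_renditions < 1:
            raise ValueError("n_renditions must be >= 1")
        for s in self.repertoire:
            top = s.f1_hz or s.f0_hz * (s.n_harmonics if s.kind ==
                                        "harmonic_stack" else 1)
            if s.f0_hz >= self.rate / 2:
                raise ValueError(
                    f"syllable f0 {s.f0_hz} Hz at or above Nyquist")

    @property
    def motif(self) -> tuple[int, ...]:
        return self.sequence or tuple(range(len(self.repertoire)))


@dataclass(frozen=True)
class TuteeSpec:
    """A learner's rendition of a tutor repertoire with imperfections."""

    base: SongSpec
    spectral_jitter_extra: float = 0.0
    omit_types: tuple[int, ...] = ()
    innovate: tuple[SyllableSpec, ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        if len(set(self.omit_types)) == len(self.base.repertoire) \
                and not self.innovate:
            raise ValueError("cannot omit every type and innovate none")


def _ramp(n: int, rate: float) -> np.ndarray:
    n_ramp = min(int(round(RAMP_MS * rate / 1000.0)), n // 2)
    env = np.ones(n)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def render_syllable(spec: SyllableSpec, rate: float,
                    rng: np.random.Generator,
                    f0_scale: float = 1.0, dur_scale: float = 1.0,
                    amp_scale: float = 1.0) -> np.ndarray:
    """One rendition of a syllable type, with jitter scales applied."""
    n = max(int(round(spec.duration_ms * dur_scale * rate / 1000.0)), 16)
    t = np.arange(n) / rate
    nyq = rate / 2.0
    f0 = min(spec.f0_hz * f0_scale, nyq * 0.95)
    if spec.kind == "harmonic_stack":
        g = spec.glide_frac
        inst_f0 = f0 * (1.0 + g / 2.0 - g * np.arange(n) / n)
        base_phase = 2 * np.pi * np.cumsum(inst_f0) / rate
        y = np.zeros(n)
        for h in range(1, spec.n_harmonics + 1):
            if h * f0 * (1 + g) >= nyq:
                break
            y += np.sin(h * base_phase) / h
    elif spec.kind == "noise_band":
        f1 = min(spec.f1_hz * f0_scale, nyq * 0.99)
        lo, hi = sorted((f0 / nyq, f1 / nyq))
        b, a = butter(4, [max(lo, 1e-4), min(hi, 0.999)], btype="bandpass")
        y = lfilter(b, a, rng.standard_normal(n))
    else:  # sweep
        f1 = min(spec.f1_hz * f0_scale, nyq * 0.95)
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / (n / rate) * t ** 2)
        y = np.sin(phase)
    # equalize loudness across kinds: amplitude sets the RMS-equivalent
    # sine level, so envelope thresholding treats all kinds alike
    rms = max(float(np.sqrt(np.mean(y ** 2))), 1e-12)
    y = y * (spec.amplitude / np.sqrt(2.0)) / rms
    return amp_scale * y * _ramp(n, rate)


def _render(repertoire: tuple[SyllableSpec, ...], motif: tuple[int, ...],
            provenance: dict[int, str], spec: SongSpec,
            rng: np.random.Generator) -> tuple[Waveform, pd.DataFrame]:
    jit = spec.jitter
    pieces: list[np.ndarray] = []
    rows = []
    cursor = 0
    lead = int(round(spec.gap_ms[1] * spec.rate / 1000.0))
    pieces.append(np.zeros(lead))
    cursor += lead
    counter = 0
    for _ in range(spec.n_renditions):
        for t_idx in motif:
            syl = repertoire[t_idx]
            f0s = float(np.exp(rng.normal(0.0, jit.f0_frac))) if jit.f0_frac else 1.0
            durs = float(np.exp(rng.normal(0.0, jit.dur_frac))) if jit.dur_frac else 1.0
            amps = float(max(1.0 + rng.normal(0.0, jit.amp_frac), 0.1)) \
                if jit.amp_frac else 1.0
            y = render_syllable(syl, spec.rate, rng, f0s, durs, amps)
            rows.append({"segment_id": f"syl{counter:05d}",
                         "onset_s": cursor / spec.rate,
                         "offset_s": (cursor + y.size) / spec.rate,
                         "type": t_idx,
                         "provenance": provenance.get(t_idx, "copied")})
            pieces.append(y)
            cursor += y.size
            gap = rng.uniform(*spec.gap_ms)
            n_gap = int(round(gap * spec.rate / 1000.0))
            pieces.append(np.zeros(n_gap))
            cursor += n_gap
            counter += 1
    samples = np.concatenate(pieces)
    if jit.noise_floor > 0:
        samples = samples + jit.noise_floor * rng.standard_normal(samples.size)
    truth = pd.DataFrame(rows)
    truth["source"] = "synthetic"
    return Waveform(samples=samples, rate=spec.rate), truth


def render_song(spec: SongSpec) -> tuple[Waveform, pd.DataFrame]:
    """Render a song; returns audio plus a ground-truth table with exact
    sample-accurate onset_s/offset_s, type index and provenance columns."""
    rng = np.random.default_rng(spec.seed)
    return _render(spec.repertoire, spec.motif, {}, spec, rng)


def render_tutee(tutee: TuteeSpec) -> tuple[Waveform, pd.DataFrame]:
    """Render a tutee song: the tutor repertoire minus omitted types, plus
    innovated types, with extra spectral (f0) jitter."""
    base = tutee.base
    keep = [i for i in range(len(base.repertoire)) if i not in tutee.omit_types]
    repertoire = tuple(base.repertoire[i] for i in keep) + tuple(tutee.innovate)
    provenance = {i: "copied" for i in range(len(keep))}
    provenance.update({len(keep) + j: "innovated"
                       for j in range(len(tutee.innovate))})
    jit = base.jitter
    jit = replace(jit, f0_frac=jit.f0_frac + tutee.spectral_jitter_extra)
    song = replace(base, repertoire=repertoire, sequence=None,
                   jitter=jit, seed=tutee.seed)
    rng = np.random.default_rng(tutee.seed)
    wav, truth = _render(repertoire, song.motif, provenance, song, rng)
    # report the tutor's type indices for copied syllables
    truth["type"] = [keep[t] if t < len(keep) else len(base.repertoire) + (t - len(keep))
                     for t in truth["type"]]
    return wav, truth


def default_repertoire(n_types: int = 6, seed: int = 0,
                       rate: float = 32000.0) -> tuple[SyllableSpec, ...]:
    """A repertoire of distinct types spanning the three syllable kinds.

    Harmonic stacks at geometrically spaced fundamentals, one band-noise
    burst and one sweep (for n_types >= 5), with durations spread over
    40-160 ms.
    """
    if not 2 <= n_types <= 12:
        raise ValueError("n_types must lie in 2..12")
    rng = np.random.default_rng(seed)
    durations = rng.uniform(40.0, 160.0, size=n_types)
    specs: list[SyllableSpec] = []
    # harmonic stacks at geometrically spaced fundamentals; the noise burst
    # occupies a high band above the stacks' energy and the sweep a narrow
    # low band, so every type has a distinct spectral footprint
    f0s = 750.0 * (1.35 ** np.arange(n_types))
    for i in range(n_types):
        if n_types >= 5 and i == n_types - 2:
            # broadband high noise: per-bin power low, so rendition-to-
            # rendition periodogram noise stays small next to inter-type
            # distances
            lo = float(rng.uniform(5000, 6500))
            specs.append(SyllableSpec(kind="noise_band", f0_hz=lo,
                                      f1_hz=min(lo * 2.4, rate * 0.47),
                                      duration_ms=durations[i]))
        elif n_types >= 5 and i == n_types - 1:
            # narrow sweep: compact spectral support gives it a strong
            # footprint, clearly apart from the diffuse noise burst
            start = float(rng.uniform(900, 1400))
            specs.append(SyllableSpec(kind="sweep", f0_hz=start,
                                      f1_hz=start * 1.3, duration_ms=durations[i]))
        else:
            specs.append(SyllableSpec(kind="harmonic_stack",
                                      f0_hz=float(min(f0s[i], rate * 0.1)),
                                      n_harmonics=int(rng.integers(4, 8)),
                                      duration_ms=durations[i]))
    return tuple(specs)


def render_psd_repertoire(n_types: int = 3, n_renditions: int = 1000,
                          seed: int = 0, n_bins: int = 1971,
                          rate: float = 32000.0, band_lo_hz: float = 600.0,
                          f0_jitter: float = 0.005,
                          spectral_noise: float = 0.3,
                          omit_types: tuple[int, ...] = (),
                          template_seed: int | None = None,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic repertoire generated directly at the PSD level.

    Emulates the statistics of Welch spectra of harmonic syllables without
    rendering audio: each type is a template of Gaussian harmonic bumps,
    each rendition shifts the harmonics by a log-normal f0 jitter,
    multiplies every bin by independent noise (the chi-squared-like
    variability of short-window periodograms) and renormalizes to unit
    sum.  Orders of magnitude faster than the audio path, so estimator
    properties can be studied at realistic sample sizes.  Returns
    (psd matrix, type labels); ``template_seed`` fixes the repertoire
    while ``seed`` varies renditions.
    """
    t_rng = np.random.default_rng(seed if template_seed is None
                                  else template_seed)
    rng = np.random.default_rng(seed)
    freqs = band_lo_hz + np.arange(n_bins) * rate / 4096.0
    # geometric f0 spacing with mild scatter keeps the types distinct
    f0s = (750.0 * 1.45 ** np.arange(n_types)
           * np.exp(t_rng.normal(0.0, 0.04, size=n_types)))
    widths = t_rng.uniform(40.0, 120.0, size=n_types)
    n_harm = t_rng.integers(3, 7, size=n_types)
    keep = [t for t in range(n_types) if t not in omit_types]
    if not keep:
        raise ValueError("cannot omit every type")
    labels = np.array([keep[i % len(keep)] for i in range(n_renditions)])
    psds = np.empty((n_renditions, n_bins))
    for i, t in enumerate(labels):
        f0 = f0s[t] * np.exp(rng.normal(0.0, f0_jitter))
        spec = np.zeros(n_bins)
        for h in range(1, n_harm[t] + 1):
            if h * f0 < rate / 2:
                spec += np.exp(-0.5 * ((freqs - h * f0) / widths[t]) ** 2) / h
        spec *= rng.gamma(1.0 / spectral_noise ** 2, spectral_noise ** 2,
                          size=n_bins)
        spec += 1e-6
        psds[i] = spec / spec.sum()
    return psds, labels


def overlapping_repertoire(n_types: int = 6, seed: int = 0
                           ) -> tuple[SyllableSpec, ...]:
    """Types with deliberately similar spectra (close fundamentals) so that
    single-PSD features partially confuse them; used to probe the benefit
    of multi-block spectro-temporal features."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_types):
        f0 = 1200.0 * (1.07 ** i)
        if i % 2 == 0:
            specs.append(SyllableSpec(kind="harmonic_stack", f0_hz=f0,
                                      n_harmonics=6,
                                      duration_ms=float(rng.uniform(60, 120))))
        else:
            # sweep through nearly the same band as the neighboring stack
            specs.append(SyllableSpec(kind="sweep", f0_hz=f0 * 0.8,
                                      f1_hz=f0 * 1.6,
                                      duration_ms=float(rng.uniform(60, 120))))
    return tuple(specs)
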