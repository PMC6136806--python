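"""Front end: from a recording to syllable spectral features.

Renders a small synthetic song (3 syllable types, 20 renditions each),
high-pass filters it, segments it into syllables by Otsu-thresholded
amplitude envelope, and summarizes each syllable as a band-restricted
Welch power spectrum.
"""

import numpy as np

import songdkl as sk

spec = sk.SongSpec(repertoire=sk.default_repertoire(3, seed=0),
                   n_renditions=20, seed=0)
wav, truth = sk.render_song(spec)
print(f"rendered {len(truth)} syllables in {wav.duration_s:.1f} s of audio")

filtered = sk.highpass(wav)                      # 500 Hz elliptic high-pass
segments = sk.segment_recording(filtered)        # envelope + Otsu threshold
print(f"segmentation found {len(segments)} syllables "
      f"(ground truth: {len(truth)})")

psds = [sk.syllable_psd(s) for s in segments]
durations = 1000 * np.array([s.duration_s for s in segments])
print(f"PSD dimensionality: {psds[0].values.size} bins "
      f"({psds[0].freqs_hz[0]:.0f}-{psds[0].freqs_hz[-1]:.0f} Hz)")
print(f"syllable durations: {durations.min():.0f}-{durations.max():.0f} ms")
# Each syllable is now a unit-sum spectrum: the input to similarity-space.
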