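import numpy as np
import pytest

import songdkl as sk


@pytest.fixture(scope="session")
def six_type_song():
    """A rendered 6-type song with truth labels, shared across tests."""
    rep = sk.default_repertoire(6, seed=1)
    spec = sk.SongSpec(repertoire=rep, n_renditions=60, seed=1)
    wav, truth = sk.render_song(spec)
    return spec, wav, truth


@pytest.fixture(scope="session")
def six_type_psds(six_type_song):
    """Front-end output for the shared song: PSDs aligned with truth types."""
    spec, wav, truth = six_type_song
    segs = sk.segment_recording(sk.highpass(wav))
    assert len(segs) == len(truth)
    psds = [sk.syllable_psd(s) for s in segs]
    return psds, truth["type"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def tone(freq_hz: float, dur_s: float, rate: float = 32000.0,
         amp: float = 1.0) -> sk.Waveform:
    t = np.arange(int(round(dur_s * rate))) / rate
    return sk.Waveform(samples=amp * np.sin(2 * np.pi * freq_hz * t),
                       rate=rate)
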