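import numpy as np
import pytest

from songbert.spectro import AudioClip, spectrogram
from songbert.synthetic import make_grammar, synthesize_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """A small 3-type corpus with spectrograms, shared by read-only tests."""
    grammar = make_grammar(3, seed=7)
    songs = synthesize_corpus(grammar, 4, 3.0, seed=7)
    specs = [spectrogram(AudioClip(s.waveform)).values for s in songs]
    return grammar, songs, specs
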