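"""Audio -> model-ready spectrograms.

The representation is fixed by the method: 44.1 kHz mono audio is high-pass
filtered (5th-order elliptic, 0.2 dB ripple, 40 dB stopband, 500 Hz cutoff,
applied causally), short-time Fourier transformed with a 1,024-point Hann
window and a 119-sample hop (2.7 ms per time bin), truncated to frequency
bins [20, 216) — exactly 196 rows, roughly 0.86-9.3 kHz — log-compressed
(log of the magnitude, floored by a tiny epsilon) and Z-scored over the
whole frequency-time image, which also removes any global recording gain.

Framing convention: frames are centered at sample k*hop for
k = 0..floor(N/hop) with 512-sample reflection padding at both ends, so an
N-sample clip yields exactly 1 + floor(N/119) time bins. The synthetic-song
generator labels frames with the same convention, keeping waveforms and
frame labels aligned end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import ellip, get_window, sosfilt

SAMPLE_RATE = 44_100
N_FFT = 1_024
HOP = 119
FREQ_LO, FREQ_HI = 20, 216          # half-open bin range -> 196 rows
N_ROWS = FREQ_HI - FREQ_LO
HOP_S = HOP / SAMPLE_RATE           # 2.698... ms per time bin

_HPF_SOS = ellip(5, 0.2, 40, 500, btype="highpass", fs=SAMPLE_RATE,
                 output="sos")
_LOG_EPS = 1e-8


@dataclass
class AudioClip:
    """Mono audio at the fixed 44.1 kHz rate."""

    samples: np.ndarray
    rate: int = SAMPLE_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate != SAMPLE_RATE:
            raise ValueError(
                f"audio must be sampled at {SAMPLE_RATE} Hz, got {self.rate}; "
                "resampling is out of scope")
        if self.samples.ndim != 1:
            raise ValueError("audio must be mono (1-D)")


@dataclass
class Spectrogram:
    """196 x T normalized spectrogram with provenance."""

    values: np.ndarray                      # (196, T)
    hop_s: float = HOP_S
    source_id: str = ""
    offset: int = 0                         # sample offset into the source

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != N_ROWS:
            raise ValueError(f"expected {N_ROWS} rows, got {self.values.shape[0]}")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def n_frames_for(n_samples: int) -> int:
    """Number of time bins produced for an n-sample clip."""
    return 1 + n_samples // HOP


def highpass(audio: AudioClip) -> AudioClip:
    """Causal 5th-order elliptic high-pass at 500 Hz."""
    return AudioClip(sosfilt(_HPF_SOS, audio.samples), audio.rate)


def stft_spectrogram(audio: AudioClip) -> np.ndarray:
    """Full-band magnitude STFT, shape (513, 1 + floor(N/119)).

    Hann window of length 1,024, FFT size 1,024, hop 119 samples; frames
    centered via reflection padding.
    """
    x = audio.samples
    if len(x) < N_FFT:
        raise ValueError(f"need at least {N_FFT} samples, got {len(x)}")
    pad = N_FFT // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    n_frames = n_frames_for(len(x))
    frames = sliding_window_view(xp, N_FFT)[::HOP][:n_frames]
    win = get_window("hann", N_FFT, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * win, axis=1))
    return spec.T


def truncate_and_normalize(full: np.ndarray, *, source_id: str = "",
                           offset: int = 0) -> Spectrogram:
    """Keep bins [20, 216), log-compress, Z-score over the whole image."""
    full = np.asarray(full, dtype=np.float64)
    if full.shape[0] < FREQ_HI:
        raise ValueError(f"need at least {FREQ_HI} frequency rows")
    cut = np.log(full[FREQ_LO:FREQ_HI] + _LOG_EPS)
    sd = cut.std()
    if sd < 1e-12:
        raise ValueError("constant spectrogram: Z-score undefined")
    values = (cut - cut.mean()) / sd
    return Spectrogram(values, source_id=source_id, offset=offset)


def spectrogram(audio: AudioClip, *, source_id: str = "",
                offset: int = 0, apply_highpass: bool = True) -> Spectrogram:
    """Full preprocessing chain: high-pass -> STFT -> truncate+normalize."""
    if apply_highpass:
        audio = highpass(audio)
    return truncate_and_normalize(stft_spectrogram(audio),
                                  source_id=source_id, offset=offset)


def restrict_to_intervals(audio: AudioClip,
                          intervals: np.ndarray) -> list[AudioClip]:
    """Cut out half-open [start_s, end_s) song intervals.

    Stands in for a song detector: the pipeline consumes pre-marked song
    intervals instead of detecting them.
    """
    out = []
    for start_s, end_s in np.atleast_2d(np.asarray(intervals, dtype=float)):
        a = int(round(start_s * SAMPLE_RATE))
        b = int(round(end_s * SAMPLE_RATE))
        if b <= a:
            raise ValueError("interval end must exceed start")
        out.append(AudioClip(audio.samples[a:b], audio.rate))
    return out


def read_wav(path) -> AudioClip:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("stereo audio is out of scope")
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return AudioClip(np.asarray(data, dtype=np.float64), rate)


def write_wav(path, audio: AudioClip) -> None:
    scaled = np.clip(audio.samples, -1.0, 1.0)
    wavfile.write(path, audio.rate, (scaled * 32767).astype(np.int16))


def save_spectrogram(path, spec: Spectrogram) -> None:
    np.savez(path, values=spec.values, hop_s=spec.hop_s,
             source_id=spec.source_id, offset=spec.offset)


def load_spectrogram(path) -> Spectrogram:
    with np.load(path, allow_pickle=False) as z:
        return Spectrogram(z["values"], hop_s=float(z["hop_s"]),
                           source_id=str(z["source_id"]), offset=int(z["offset"]))
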