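"""Synthetic canary-like song with exact frame-level ground truth.

Canary song is a sequence of *phrases*: runs of one syllable type repeated
with brief (~5-15 ms) intra-phrase gaps, with longer silences between
phrases. The generator emulates that structure — harmonic syllables with
constant / upsweep / downsweep / trill pitch trajectories, uniform draws for
durations and gaps, first-order Markov phrase transitions — and emits, next
to each waveform, an integer label per 2.7 ms spectrogram time bin using the
same framing convention as :mod:`songbert.spectro`, so every downstream
stage can be tested without external recordings.

Label convention: 0 is silence; template ids are 1..K. Every frame's label
is the label of the sample at the frame center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectro import SAMPLE_RATE, HOP, n_frames_for

SILENCE = 0

_TRAJECTORIES = ("constant", "upsweep", "downsweep", "trill")


@dataclass(frozen=True)
class SyllableTemplate:
    """One syllable type: a harmonic tone with a pitch trajectory."""

    template_id: int
    duration_ms_range: tuple[float, float]
    f0_trajectory: str                       # constant/upsweep/downsweep/trill
    f0_start: float                          # Hz, in [1000, 8000]
    f0_end: float
    n_harmonics: int = 1
    amplitude: float = 1.0
    trill_rate_hz: float = 30.0
    trill_depth_hz: float = 300.0

    def __post_init__(self):
        lo, hi = self.duration_ms_range
        if not (20.0 <= lo <= hi <= 400.0):
            raise ValueError("syllable durations must lie in [20, 400] ms")
        if self.f0_trajectory not in _TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.f0_trajectory!r}")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")


@dataclass(frozen=True)
class PhraseGrammar:
    """Markov grammar over syllable templates."""

    templates: tuple[SyllableTemplate, ...]
    transition_matrix: np.ndarray            # row-stochastic, K x K
    repeats_range: tuple[int, int] = (3, 8)
    intra_gap_ms_range: tuple[float, float] = (5.0, 15.0)
    inter_gap_ms_range: tuple[float, float] = (150.0, 400.0)
    grammar_id: str = ""

    def __post_init__(self):
        tm = np.asarray(self.transition_matrix, dtype=np.float64)
        object.__setattr__(self, "transition_matrix", tm)
        k = len(self.templates)
        if tm.shape != (k, k):
            raise ValueError("transition matrix shape must match template count")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.intra_gap_ms_range[0] < 3.0:
            raise ValueError("intra-phrase gaps must be >= 3 ms (> one time bin)")

    @property
    def template_ids(self) -> list[int]:
        return [t.template_id for t in self.templates]


@dataclass
class LabeledSong:
    """Waveform plus frame-aligned ground-truth labels."""

    waveform: np.ndarray                     # float64 samples at 44.1 kHz
    frame_labels: np.ndarray                 # int per 2.7 ms bin, 0 = silence
    grammar_id: str = ""
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return len(self.frame_labels)


def make_grammar(n_syllable_types: int, seed: int, *,
                 repeats_range: tuple[int, int] = (3, 8),
                 intra_gap_ms_range: tuple[float, float] = (5.0, 15.0),
                 inter_gap_ms_range: tuple[float, float] = (150.0, 400.0),
                 ) -> PhraseGrammar:
    """Draw a random grammar with acoustically separated syllable types.

    Fundamental frequencies are spread evenly across 1.5-7 kHz with a small
    seeded jitter, and trajectories cycle through the four shapes, so the
    rendered templates occupy distinct spectral bands.
    """
    if n_syllable_types < 1:
        raise ValueError("n_syllable_types must be >= 1")
    rng = np.random.default_rng(seed)
    k = n_syllable_types
    if k == 1:
        bases = np.array([3000.0])
    else:
        bases = np.linspace(1500.0, 7000.0, k)
    jitter = (bases[1] - bases[0]) * 0.1 if k > 1 else 200.0
    bases = bases + rng.uniform(-jitter, jitter, k)
    templates = []
    for i in range(k):
        traj = _TRAJECTORIES[int(rng.integers(len(_TRAJECTORIES)))]
        f0 = float(bases[i])
        sweep = min(400.0, 0.15 * f0) * (1 if rng.random() < 0.5 else -1)
        if traj == "upsweep":
            f_start, f_end = f0 - abs(sweep) / 2, f0 + abs(sweep) / 2
        elif traj == "downsweep":
            f_start, f_end = f0 + abs(sweep) / 2, f0 - abs(sweep) / 2
        else:
            f_start = f_end = f0
        lo = float(rng.uniform(50.0, 100.0))
        hi = lo + float(rng.uniform(20.0, 80.0))
        templates.append(SyllableTemplate(
            template_id=i + 1,
            duration_ms_range=(lo, hi),
            f0_trajectory=traj,
            f0_start=f_start, f0_end=f_end,
            n_harmonics=int(rng.integers(1, 3)),
            amplitude=float(rng.uniform(0.6, 1.0)),
            trill_rate_hz=float(rng.uniform(20.0, 40.0)),
            trill_depth_hz=float(rng.uniform(200.0, 400.0)),
        ))
    # Markov chain biased toward moving on (small self-transition mass),
    # strictly positive so the chain is ergodic.
    if k == 1:
        tm = np.array([[1.0]])
    else:
        tm = rng.uniform(0.5, 1.0, (k, k))
        np.fill_diagonal(tm, rng.uniform(0.05, 0.15, k))
        tm /= tm.sum(axis=1, keepdims=True)
    return PhraseGrammar(
        templates=tuple(templates), transition_matrix=tm,
        repeats_range=repeats_range,
        intra_gap_ms_range=intra_gap_ms_range,
        inter_gap_ms_range=inter_gap_ms_range,
        grammar_id=f"grammar-k{k}-s{seed}",
    )


def seasonal_variant(grammar: PhraseGrammar, seed: int,
                     turnover: float = 0.5) -> PhraseGrammar:
    """Re-draw a fraction of templates to emulate seasonal repertoire turnover.

    Kept template ids are unchanged; replaced ids get fresh acoustics (new
    frequency band, trajectory, durations) under the same id, so the two
    grammars describe "the same bird" with a partially rewritten repertoire.
    """
    rng = np.random.default_rng(seed)
    k = len(grammar.templates)
    n_replace = int(round(turnover * k))
    replaced = rng.choice(k, size=n_replace, replace=False)
    fresh = make_grammar(k, seed=int(rng.integers(2**31)))
    templates = list(grammar.templates)
    for idx in replaced:
        templates[idx] = replace(fresh.templates[idx],
                                 template_id=grammar.templates[idx].template_id)
    return replace(grammar, templates=tuple(templates),
                   grammar_id=grammar.grammar_id + f"-seasonal{seed}")


def render_syllable(template: SyllableTemplate, duration_ms: float,
                    rate: int = SAMPLE_RATE) -> np.ndarray:
    """Render one syllable: harmonic stack with a 5 ms raised-cosine ramp."""
    n = max(1, int(round(duration_ms * 1e-3 * rate)))
    t = np.arange(n) / rate
    if template.f0_trajectory == "trill":
        f = template.f0_start + template.trill_depth_hz * np.sin(
            2 * np.pi * template.trill_rate_hz * t)
    else:
        f = np.linspace(template.f0_start, template.f0_end, n)
    phase = 2 * np.pi * np.cumsum(f) / rate
    y = np.zeros(n)
    nyquist = rate / 2
    for h in range(1, template.n_harmonics + 1):
        if f.max() * h >= nyquist:        # clip harmonics above Nyquist
            break
        y += (0.3 ** (h - 1)) * np.sin(h * phase)
    ramp = min(int(0.005 * rate), n // 2)
    env = np.ones(n)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return template.amplitude * env * y


def synthesize_song(grammar: PhraseGrammar, target_duration_s: float,
                    seed: int, snr_db: float = 30.0) -> LabeledSong:
    """Generate one song of roughly the target duration.

    Phrases are drawn from the Markov chain (initial phrase uniform),
    each phrase repeats its syllable a uniform number of times with uniform
    intra-phrase gaps; phrases are separated by longer uniform silences.
    White noise is added at the given SNR (relative to signal power).
    """
    if target_duration_s <= 0:
        raise ValueError("target_duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_target = int(round(target_duration_s * SAMPLE_RATE))
    wave_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    k = len(grammar.templates)
    state = int(rng.integers(k))
    total = 0

    def push(x: np.ndarray, label: int) -> None:
        nonlocal total
        wave_parts.append(x)
        label_parts.append(np.full(len(x), label, dtype=np.int64))
        total += len(x)

    first = True
    while total < n_target:
        gap_ms = rng.uniform(*grammar.inter_gap_ms_range)
        push(np.zeros(int(round(gap_ms * 1e-3 * SAMPLE_RATE))), SILENCE)
        if total >= n_target:
            break
        if not first:
            state = int(rng.choice(k, p=grammar.transition_matrix[state]))
        first = False
        template = grammar.templates[state]
        repeats = int(rng.integers(grammar.repeats_range[0],
                                   grammar.repeats_range[1] + 1))
        for r in range(repeats):
            if r > 0:
                intra_ms = rng.uniform(*grammar.intra_gap_ms_range)
                push(np.zeros(int(round(intra_ms * 1e-3 * SAMPLE_RATE))),
                     SILENCE)
            dur_ms = rng.uniform(*template.duration_ms_range)
            push(render_syllable(template, dur_ms), template.template_id)
    waveform = np.concatenate(wave_parts)[:n_target]
    sample_labels = np.concatenate(label_parts)[:n_target]
    sig_power = np.mean(waveform**2)
    if sig_power > 0 and np.isfinite(snr_db):
        noise_sd = np.sqrt(sig_power / 10 ** (snr_db / 10))
        waveform = waveform + rng.normal(0.0, noise_sd, len(waveform))
    peak = np.abs(waveform).max()
    if peak > 0:
        waveform = 0.9 * waveform / peak
    centers = np.minimum(np.arange(n_frames_for(len(waveform))) * HOP,
                         len(waveform) - 1)
    frame_labels = sample_labels[centers]
    return LabeledSong(waveform=waveform, frame_labels=frame_labels,
                       grammar_id=grammar.grammar_id, seed=seed)


def synthesize_corpus(grammar: PhraseGrammar, n_songs: int,
                      song_duration_s: float, seed: int,
                      snr_db: float = 30.0) -> list[LabeledSong]:
    """Generate independent songs with counter-derived per-song seeds."""
    if n_songs < 1:
        raise ValueError("n_songs must be >= 1")
    songs = []
    for i in range(n_songs):
        song_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                        % (2**31))
        songs.append(synthesize_song(grammar, song_duration_s, song_seed,
                                     snr_db=snr_db))
    return songs


def write_labels(path, frame_labels: np.ndarray) -> None:
    """Label sidecar: two-column delimited text (frame index, label)."""
    idx = np.arange(len(frame_labels))
    np.savetxt(path, np.column_stack([idx, frame_labels]), fmt="%d",
               delimiter="\t", header="frame\tlabel", comments="")


def read_labels(path) -> np.ndarray:
    data = np.loadtxt(path, dtype=np.int64, delimiter="\t", skiprows=1,
                      ndmin=2)
    return data[:, 1]
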