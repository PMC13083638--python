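"""Training-window construction: segment sampling, frequency-shift
augmentation, and the masked-prediction occlusion.

The occlusion covers 25% of the window's time bins by default, built as a
union of contiguous segments whose lengths are uniform on {0..250} and whose
positions are uniform (segments may overhang the window edges and are
clipped, which makes the per-position masking probability independent of
position). Segments accumulate until coverage reaches the target, and the
final segment is trimmed (from a randomly chosen end, keeping the marginal
position-independent) so coverage is *exact*. Masked
columns span all frequency rows and are replaced with zeros.

The frequency shift (uniform on +/-50 bins, zero-filling vacated rows) is
applied before masking so input and target share the same shifted frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectro import N_ROWS, Spectrogram

CONTEXT = 1_000
MASK_RATIO = 0.25
MAX_MASK_LEN = 250
MAX_SHIFT = 50


@dataclass
class TrainingWindow:
    """Masked input, unmasked target, and the mask that relates them."""

    input: np.ndarray                 # (n_freq, context), masked
    target: np.ndarray                # (n_freq, context), unmasked
    mask: np.ndarray                  # (context,) bool over time bins
    shift_bins: int = 0


def sample_window(spec: Spectrogram | np.ndarray, rng: np.random.Generator,
                  context: int = CONTEXT) -> np.ndarray:
    """Random context-length slice; zero-pad along time when too short."""
    values = spec.values if isinstance(spec, Spectrogram) else np.asarray(spec)
    T = values.shape[1]
    if T >= context:
        start = int(rng.integers(0, T - context + 1))
        return values[:, start:start + context].copy()
    out = np.zeros((values.shape[0], context))
    out[:, :T] = values
    return out


def frequency_shift(window: np.ndarray, shift_bins: int | None = None,
                    rng: np.random.Generator | None = None,
                    max_shift: int = MAX_SHIFT) -> tuple[np.ndarray, int]:
    """Translate rows by `shift_bins` (positive = toward higher bins),
    zero-filling vacated rows. Sampled uniformly on [-max_shift, max_shift]
    when not supplied."""
    if shift_bins is None:
        if rng is None:
            raise ValueError("supply shift_bins or rng")
        shift_bins = int(rng.integers(-max_shift, max_shift + 1))
    if abs(shift_bins) > max_shift:
        raise ValueError(f"|shift_bins| must be <= {max_shift}")
    out = np.zeros_like(window)
    if shift_bins >= 0:
        if shift_bins < window.shape[0]:
            out[shift_bins:] = window[:window.shape[0] - shift_bins]
    else:
        out[:shift_bins] = window[-shift_bins:]
    return out, shift_bins


def generate_mask(length: int = CONTEXT, ratio: float = MASK_RATIO,
                  max_mask_len: int = MAX_MASK_LEN,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Boolean time-bin mask with exactly round(ratio * length) bins set."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if max_mask_len > length:
        raise ValueError("max_mask_len must be <= length")
    target = int(round(ratio * length))
    mask = np.zeros(length, dtype=bool)
    if target == 0:
        return mask
    if max_mask_len < 1:
        raise ValueError("max_mask_len must be >= 1 for a non-zero ratio")
    if rng is None:
        rng = np.random.default_rng()
    covered = 0
    while covered < target:
        seg_len = int(rng.integers(0, max_mask_len + 1))
        if seg_len == 0:
            continue
        # position uniform with edge clipping: start in [-(len-1), length-1]
        start = int(rng.integers(-(seg_len - 1), length))
        a, b = max(0, start), min(length, start + seg_len)
        if b <= a:
            continue
        newly = np.flatnonzero(~mask[a:b]) + a
        mask[a:b] = True
        covered += len(newly)
        if covered > target:
            # trim the final segment to hit the target exactly; the trimmed
            # end is chosen at random so the per-position masking
            # probability stays position-independent
            excess = covered - target
            if rng.integers(2):
                mask[newly[-excess:]] = False
            else:
                mask[newly[:excess]] = False
            covered = target
    return mask


def apply_mask(target: np.ndarray, mask: np.ndarray,
               shift_bins: int = 0) -> TrainingWindow:
    """Zero the masked columns of a copy of `target`."""
    target = np.asarray(target)
    mask = np.asarray(mask, dtype=bool)
    if target.ndim != 2 or mask.ndim != 1 or target.shape[1] != mask.shape[0]:
        raise ValueError("target must be (n_freq, T) with mask of length T")
    masked = target.copy()
    masked[:, mask] = 0.0
    return TrainingWindow(input=masked, target=target.copy(), mask=mask.copy(),
                          shift_bins=shift_bins)


def make_training_window(spec: Spectrogram | np.ndarray,
                         rng: np.random.Generator,
                         mask: np.ndarray | None = None,
                         context: int = CONTEXT,
                         max_shift: int = MAX_SHIFT) -> TrainingWindow:
    """Sample -> shift -> mask, the full augmentation chain for one window."""
    window = sample_window(spec, rng, context=context)
    shifted, shift = frequency_shift(window, rng=rng, max_shift=max_shift)
    if mask is None:
        mask = generate_mask(length=context, rng=rng)
    return apply_mask(shifted, mask, shift_bins=shift)
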