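"""Self-supervised pretraining.

Each optimization step: draw a batch of random windows from training songs,
apply per-window frequency shifts, occlude one shared mask across the batch,
run the network, and minimize MSE computed exclusively over the masked
cells with Adam (lr 3e-4, batch 42 in the reference configuration).

Validation runs every 500 steps on a fixed, pre-drawn set of held-out
windows with fixed masks, so successive checks are comparable. The check
value is smoothed by averaging all validation records within the trailing
1,000 optimization steps; training stops after eight consecutive checks
without improvement of the smoothed loss, or at ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _nn as nn
from ._nn import Tensor
from .masking import (MAX_MASK_LEN, apply_mask, frequency_shift,
                      generate_mask, sample_window)
from .model import ModelConfig, SongBertNetwork
from .spectro import Spectrogram
from .synthetic import LabeledSong


@dataclass
class OptimConfig:
    learning_rate: float = 3e-4
    batch_size: int = 42
    val_interval: int = 500
    val_smoothing_span: int = 1_000
    patience: int = 8
    max_steps: int = 26_500          # reference budget; desk runs use far less
    n_val_windows: int = 16
    max_shift: int = 50

    def __post_init__(self):
        if self.learning_rate < 0:          # 0 disables the optimizer
            raise ValueError("learning_rate must be non-negative")
        for name in ("batch_size", "val_interval", "val_smoothing_span",
                     "patience", "max_steps", "n_val_windows"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainState:
    step: int = 0
    smoothed_val: float = np.inf
    best_smoothed_val: float = np.inf
    patience_counter: int = 0
    history: list[tuple[int, float, float]] = field(default_factory=list)
    train_losses: list[tuple[int, float]] = field(default_factory=list)


def make_split(corpus: list, train_fraction: float = 0.8,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Song-level split: whole songs go to exactly one side."""
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 songs to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def masked_mse_np(pred: np.ndarray, target: np.ndarray,
                  mask: np.ndarray) -> float:
    """Mean squared error over masked cells only (NumPy, no tape)."""
    mask = np.asarray(mask, dtype=bool)
    if pred.shape != target.shape or pred.shape[-1] != mask.shape[-1]:
        raise ValueError("shape mismatch")
    if not mask.any():
        raise ValueError("empty mask: masked loss undefined")
    d = pred[..., mask] - target[..., mask]
    return float(np.mean(d * d))


def masked_mse(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Differentiable masked MSE: mean over the masked columns' cells."""
    mask = np.asarray(mask, dtype=bool)
    n_masked = int(mask.sum())
    if n_masked == 0:
        raise ValueError("empty mask: masked loss undefined")
    diff = pred - Tensor(np.asarray(target))
    w = mask.astype(np.float64)          # broadcast over frequency rows
    total = ((diff * diff) * Tensor(w)).sum()
    denom = float(np.prod(pred.shape)) / pred.shape[-1] * n_masked
    return total * (1.0 / denom)


def _as_spectrogram_values(song) -> np.ndarray:
    from .spectro import AudioClip, spectrogram
    if isinstance(song, Spectrogram):
        return song.values
    if isinstance(song, np.ndarray):
        return song
    if isinstance(song, LabeledSong):
        return spectrogram(AudioClip(song.waveform)).values
    raise TypeError(f"cannot interpret {type(song)} as a spectrogram")


def _draw_batch(specs: list[np.ndarray], net: SongBertNetwork,
                optim: OptimConfig, rng: np.random.Generator,
                mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One optimization batch: (inputs, targets), shared mask."""
    context = net.config.context
    inputs, targets = [], []
    for _ in range(optim.batch_size):
        spec = specs[int(rng.integers(len(specs)))]
        window = sample_window(spec, rng, context=context)
        shifted, _ = frequency_shift(window, rng=rng,
                                     max_shift=optim.max_shift)
        tw = apply_mask(shifted, mask)
        inputs.append(tw.input)
        targets.append(tw.target)
    return np.stack(inputs), np.stack(targets)


def train(corpus: list, model_config: ModelConfig = ModelConfig(),
          optim_config: OptimConfig = OptimConfig(), seed: int = 0,
          train_fraction: float = 0.8,
          ) -> tuple[SongBertNetwork, TrainState]:
    """Pretrain a network on a corpus of songs or spectrograms.

    Returns the trained network and the training trace.
    """
    if len(corpus) == 0:
        raise ValueError("corpus must be non-empty")
    rng = np.random.default_rng(seed)
    net = SongBertNetwork(model_config, seed=int(rng.integers(2**31)))
    specs = [_as_spectrogram_values(s) for s in corpus]
    if len(specs) >= 2:
        train_ids, val_ids = make_split(specs, train_fraction,
                                        seed=int(rng.integers(2**31)))
    else:
        train_ids = val_ids = np.array([0])
    train_specs = [specs[i] for i in train_ids]
    val_specs = [specs[i] for i in val_ids]

    # fixed validation windows + masks so checks are comparable
    val_rng = np.random.default_rng(int(rng.integers(2**31)))
    val_set = []
    for _ in range(optim_config.n_val_windows):
        spec = val_specs[int(val_rng.integers(len(val_specs)))]
        window = sample_window(spec, val_rng, context=model_config.context)
        mask = generate_mask(length=model_config.context,
                             max_mask_len=min(MAX_MASK_LEN,
                                              model_config.context),
                             rng=val_rng)
        val_set.append((window, mask))

    opt = nn.Adam(net.parameters(), lr=optim_config.learning_rate)
    state = TrainState()

    def validation_loss() -> float:
        losses = []
        for window, mask in val_set:
            tw = apply_mask(window, mask)
            pred, _ = net.forward(tw.input[None])
            losses.append(masked_mse_np(pred.data[0], tw.target, mask))
        return float(np.mean(losses))

    while state.step < optim_config.max_steps:
        state.step += 1
        step_mask = generate_mask(length=model_config.context,
                                  max_mask_len=min(MAX_MASK_LEN,
                                                   model_config.context),
                                  rng=rng)
        inputs, targets = _draw_batch(train_specs, net, optim_config, rng,
                                      step_mask)
        pred, _ = net.forward(inputs)
        loss = masked_mse(pred, targets, step_mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.train_losses.append((state.step, float(loss.data)))

        if state.step % optim_config.val_interval == 0:
            raw = validation_loss()
            state.history.append((state.step, raw, np.nan))
            span_lo = state.step - optim_config.val_smoothing_span
            recent = [r for s, r, _ in state.history if s > span_lo]
            smoothed = float(np.mean(recent))
            state.history[-1] = (state.step, raw, smoothed)
            state.smoothed_val = smoothed
            if smoothed < state.best_smoothed_val:
                state.best_smoothed_val = smoothed
                state.patience_counter = 0
            else:
                state.patience_counter += 1
                if state.patience_counter >= optim_config.patience:
                    break
    return net, state


def run_early_stopping(val_losses: list[float], patience: int = 8,
                       val_interval: int = 500,
                       smoothing_span: int = 1_000) -> int:
    """Number of validation checks consumed on a given raw-loss sequence.

    Pure re-implementation of the trainer's stopping rule, usable to verify
    the patience contract on rigged sequences without training a network.
    """
    best = np.inf
    counter = 0
    records: list[tuple[int, float]] = []
    for i, raw in enumerate(val_losses):
        step = (i + 1) * val_interval
        records.append((step, raw))
        recent = [r for s, r in records if s > step - smoothing_span]
        smoothed = float(np.mean(recent))
        if smoothed < best:
            best = smoothed
            counter = 0
        else:
            counter += 1
            if counter >= patience:
                return i + 1
    return len(val_losses)


class SongBert(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper: fit = masked pretraining, transform =
    frame latents.

    Parameters mirror :class:`ModelConfig` and :class:`OptimConfig`; fitted
    attributes carry the trained network and training trace.
    """

    def __init__(self, n_freq=196, conv_channels=(32, 64, 64, 64),
                 d_model=196, n_heads=4, ffn_dim=768, n_blocks=4,
                 context=1000, relpos_clip=512, learning_rate=3e-4,
                 batch_size=42, val_interval=500, max_steps=26_500,
                 patience=8, latent_block=3, seed=0):
        self.n_freq = n_freq
        self.conv_channels = conv_channels
        self.d_model = d_model
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.n_blocks = n_blocks
        self.context = context
        self.relpos_clip = relpos_clip
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.val_interval = val_interval
        self.max_steps = max_steps
        self.patience = patience
        self.latent_block = latent_block
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_freq=self.n_freq, conv_channels=tuple(self.conv_channels),
            d_model=self.d_model, n_heads=self.n_heads, ffn_dim=self.ffn_dim,
            n_blocks=self.n_blocks, context=self.context,
            relpos_clip=self.relpos_clip)

    def fit(self, X, y=None):
        """Pretrain on a list of songs / spectrograms."""
        optim = OptimConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            val_interval=self.val_interval, max_steps=self.max_steps,
            patience=self.patience)
        self.network_, self.train_state_ = train(
            list(X), self._model_config(), optim, seed=self.seed)
        return self

    def transform(self, X):
        """Per-song frame latents: list of (T, d_model) arrays."""
        from .embed import latents_for_song
        if not hasattr(self, "network_"):
            raise RuntimeError("fit the model first")
        return [latents_for_song(self.network_, _as_spectrogram_values(s),
                                 block=self.latent_block) for s in X]
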