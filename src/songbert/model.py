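"""The masked-spectrogram transformer network.

Architecture, front to back:

1. CNN front-end: four (conv 5x5, pad 2 -> GELU -> max-pool (2,1)) stages.
   Pooling halves the frequency axis each time (196 -> 98 -> 49 -> 24 -> 12,
   floor division) and never touches the time axis, so every layer of the
   network keeps one state per 2.7 ms time bin.
2. Linear projection of the flattened per-bin CNN features (channels x
   remaining frequency positions, 64 x 12 = 768 in the reference
   configuration) into the d_model = 196 embedding space.
3. Four pre-layer-norm transformer encoder blocks: multi-head self-attention
   (4 heads of dimension 49) with learned relative positional biases, residual;
   then a 196 -> 768 -> 196 GELU feed-forward, residual.
4. Final layer norm and a linear deprojection back to 196 frequency bins,
   giving the reconstruction the masked-prediction loss is computed on.

Relative positions use Shaw-style learned relative-key embeddings: one table
per block of shape (2*clip+1, head_dim), shared across heads, with the
relative distance j - i clipped to +/-clip (512 by default). The attention
logit is (q_i . k_j + q_i . r_{j-i}) / sqrt(head_dim).

The reference configuration totals 2,476,660 trainable scalars (~2.5 M).

Every intermediate hidden state is exposed by a tap name; the frame latents
used downstream are the post-attention-residual, pre-feed-forward state of
block 3 (1-indexed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn as nn
from ._nn import Parameter, Tensor


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network. Defaults are the reference model."""

    n_freq: int = 196
    conv_channels: tuple[int, ...] = (32, 64, 64, 64)
    conv_kernel: int = 5
    d_model: int = 196
    n_heads: int = 4
    ffn_dim: int = 768
    n_blocks: int = 4
    context: int = 1000
    relpos_clip: int = 512

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("n_heads must divide d_model")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def freq_trajectory(self) -> list[int]:
        """Frequency extent after each pooling stage (floor halving)."""
        traj = [self.n_freq]
        for _ in self.conv_channels:
            traj.append(traj[-1] // 2)
        return traj

    @property
    def feature_dim(self) -> int:
        """Per-time-bin feature width leaving the CNN front-end."""
        return self.conv_channels[-1] * self.freq_trajectory[-1]


#: Desk-scale configuration: small enough to pretrain on one CPU in minutes
#: while exercising every architectural element.
DESK_CONFIG = ModelConfig(
    conv_channels=(4, 8, 8, 8), d_model=64, n_heads=4,
    ffn_dim=128, n_blocks=2, context=250, relpos_clip=256,
)


class SongBertNetwork:
    """The network with explicit parameter registry and named latent taps.

    Parameters are float64 NumPy arrays on a small reverse-mode autodiff
    tape; the forward pass is deterministic for fixed weights and input.
    """

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.params: dict[str, Parameter] = {}
        self._dist_cache: dict[int, np.ndarray] = {}
        self._init(seed)

    # -- parameters -----------------------------------------------------------

    def _add(self, name: str, value: np.ndarray) -> Parameter:
        p = Parameter(value)
        self.params[name] = p
        return p

    def _init(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        cfg = self.config
        k = cfg.conv_kernel
        cin = 1
        for i, cout in enumerate(cfg.conv_channels):
            fan_in = cin * k * k
            self._add(f"conv{i}.w",
                      rng.normal(0.0, math.sqrt(2.0 / fan_in), (cout, cin, k, k)))
            self._add(f"conv{i}.b", np.zeros(cout))
            cin = cout

        def linear(name: str, m: int, n: int) -> None:
            bound = math.sqrt(6.0 / (m + n))
            self._add(f"{name}.w", rng.uniform(-bound, bound, (m, n)))
            self._add(f"{name}.b", np.zeros(n))

        linear("proj", cfg.feature_dim, cfg.d_model)
        for b in range(cfg.n_blocks):
            self._add(f"block{b}.ln1.g", np.ones(cfg.d_model))
            self._add(f"block{b}.ln1.b", np.zeros(cfg.d_model))
            linear(f"block{b}.qkv", cfg.d_model, 3 * cfg.d_model)
            linear(f"block{b}.attn_out", cfg.d_model, cfg.d_model)
            self._add(f"block{b}.relpos",
                      rng.normal(0.0, 0.02, (2 * cfg.relpos_clip + 1, cfg.head_dim)))
            self._add(f"block{b}.ln2.g", np.ones(cfg.d_model))
            self._add(f"block{b}.ln2.b", np.zeros(cfg.d_model))
            linear(f"block{b}.ffn1", cfg.d_model, cfg.ffn_dim)
            linear(f"block{b}.ffn2", cfg.ffn_dim, cfg.d_model)
        self._add("final_ln.g", np.ones(cfg.d_model))
        self._add("final_ln.b", np.zeros(cfg.d_model))
        linear("deproj", cfg.d_model, cfg.n_freq)

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def copy_weights_from(self, other: "SongBertNetwork") -> None:
        for name, p in self.params.items():
            p.data = other.params[name].data.copy()

    # -- forward --------------------------------------------------------------

    def _relative_distance(self, T: int) -> np.ndarray:
        if T not in self._dist_cache:
            i = np.arange(T)
            d = np.clip(i[None, :] - i[:, None],
                        -self.config.relpos_clip, self.config.relpos_clip)
            self._dist_cache[T] = d + self.config.relpos_clip
        return self._dist_cache[T]

    def cnn_frontend(self, x: Tensor) -> Tensor:
        """(B, n_freq, T) spectrogram windows -> (B, T, feature_dim)."""
        if x.shape[1] != self.config.n_freq:
            raise ValueError(
                f"expected {self.config.n_freq} frequency rows, got {x.shape[1]}")
        B, F, T = x.shape
        h = x.reshape(B, 1, F, T)
        for i in range(len(self.config.conv_channels)):
            h = nn.conv2d(h, self.params[f"conv{i}.w"],
                          self.params[f"conv{i}.b"],
                          padding=self.config.conv_kernel // 2)
            h = nn.gelu(h)
            h = nn.maxpool_freq2(h)
        # (B, C, F', T) -> (B, T, C*F')
        h = h.transpose(0, 3, 1, 2).reshape(B, T, self.config.feature_dim)
        return h

    def _attention(self, h: Tensor, b: int) -> Tensor:
        cfg = self.config
        B, T, _ = h.shape
        a = nn.layer_norm(h, self.params[f"block{b}.ln1.g"],
                          self.params[f"block{b}.ln1.b"])
        qkv = a @ self.params[f"block{b}.qkv.w"] + self.params[f"block{b}.qkv.b"]
        qkv = qkv.reshape(B, T, 3, cfg.n_heads, cfg.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)          # (3, B, H, T, dh)
        q, k, v = _split3(qkv)
        scale = 1.0 / math.sqrt(cfg.head_dim)
        logits = (q @ k.swapaxes(-1, -2)) * scale   # (B, H, T, T)
        rel = nn.embedding(self.params[f"block{b}.relpos"],
                           self._relative_distance(T))          # (T, T, dh)
        qT = q.transpose(2, 0, 1, 3)                # (T, B, H, dh)
        relT = rel.swapaxes(1, 2)                   # (T, dh, T)
        bias = (qT @ relT.reshape(T, 1, cfg.head_dim, T))       # (T, B, H, T)
        logits = logits + bias.transpose(1, 2, 0, 3) * scale
        att = nn.softmax(logits, axis=-1)
        o = att @ v                                  # (B, H, T, dh)
        o = o.transpose(0, 2, 1, 3).reshape(B, T, cfg.d_model)
        return o @ self.params[f"block{b}.attn_out.w"] \
            + self.params[f"block{b}.attn_out.b"]

    def forward(self, x: Tensor | np.ndarray,
                collect_taps: bool = False
                ) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the network.

        Parameters
        ----------
        x : (B, n_freq, T) or (n_freq, T) array or Tensor.
        collect_taps : record every intermediate hidden state.

        Returns
        -------
        reconstruction : Tensor of the input's shape.
        taps : mapping tap name -> Tensor. Always includes
            ``block{i}.attn`` (post-attention residual, pre-FFN) and
            ``block{i}.ffn`` (post-FFN residual) for each 1-indexed block,
            plus ``cnn``, ``proj``, ``final_ln`` when `collect_taps`.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        squeeze = x.ndim == 2
        if squeeze:
            x = x.reshape(1, *x.shape)
        taps: dict[str, Tensor] = {}
        feats = self.cnn_frontend(x)
        if collect_taps:
            taps["cnn"] = feats
        h = feats @ self.params["proj.w"] + self.params["proj.b"]
        if collect_taps:
            taps["proj"] = h
        for b in range(self.config.n_blocks):
            h = h + self._attention(h, b)
            taps[f"block{b + 1}.attn"] = h
            a = nn.layer_norm(h, self.params[f"block{b}.ln2.g"],
                              self.params[f"block{b}.ln2.b"])
            f = nn.gelu(a @ self.params[f"block{b}.ffn1.w"]
                        + self.params[f"block{b}.ffn1.b"])
            f = f @ self.params[f"block{b}.ffn2.w"] + self.params[f"block{b}.ffn2.b"]
            h = h + f
            taps[f"block{b + 1}.ffn"] = h
        h = nn.layer_norm(h, self.params["final_ln.g"], self.params["final_ln.b"])
        if collect_taps:
            taps["final_ln"] = h
        recon = h @ self.params["deproj.w"] + self.params["deproj.b"]
        recon = recon.swapaxes(1, 2)                # (B, n_freq, T)
        if squeeze:
            recon = recon.reshape(recon.shape[1], recon.shape[2])
        return recon, taps

    def extract_latent(self, window: np.ndarray, block: int = 3,
                       tap: str | None = None) -> np.ndarray:
        """Frame latents, (T, d_model), frame-aligned with the input.

        By default the post-attention (pre-FFN) state of a 1-indexed block;
        any named tap (e.g. ``"final_ln"`` or ``"block2.ffn"``) can be
        requested instead.
        """
        if tap is None:
            if not 1 <= block <= self.config.n_blocks:
                raise ValueError(
                    f"block must be in [1, {self.config.n_blocks}], got {block}")
            tap = f"block{block}.attn"
        window = np.asarray(window)
        squeeze = window.ndim == 2
        _, taps = self.forward(window, collect_taps=True)
        if tap not in taps:
            raise ValueError(f"unknown tap {tap!r}; have {sorted(taps)}")
        out = taps[tap].data
        return out[0] if squeeze else out

    # -- persistence ----------------------------------------------------------

    def save(self, path, step: int = 0) -> None:
        cfg = asdict(self.config)
        cfg["conv_channels"] = list(cfg["conv_channels"])
        arrays = {f"param/{k}": p.data for k, p in self.params.items()}
        np.savez(path, __config__=json.dumps(cfg), __step__=step, **arrays)

    @classmethod
    def load(cls, path) -> tuple["SongBertNetwork", int]:
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            cfg["conv_channels"] = tuple(cfg["conv_channels"])
            net = cls(ModelConfig(**cfg), seed=0)
            for k in net.params:
                net.params[k].data = z[f"param/{k}"]
            step = int(z["__step__"])
        return net, step


def _split3(qkv: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Split the leading axis-3 of a (3, ...) tensor into three tensors."""
    outs = []
    for j in range(3):
        def backward(g, j=j):
            if qkv.grad is None:
                qkv.grad = np.zeros_like(qkv.data)
            qkv.grad[j] += g
        outs.append(qkv._make(qkv.data[j], (qkv,), backward))
    return tuple(outs)


def count_parameters(config: ModelConfig = ModelConfig()) -> int:
    """Exact number of trainable scalars of a configuration."""
    return SongBertNetwork(config, seed=0).n_parameters()
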