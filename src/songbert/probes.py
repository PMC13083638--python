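"""Linear-probe evaluation of frame representations.

Four conditions measure how linearly decodable phrase identity is from a
per-frame feature vector:

- ``pretrained``: block-3 post-attention latents of the pretrained network;
- ``untrained``: the same tap of a randomly initialized network (same
  architecture, fresh seeded weights) — the inductive-bias baseline;
- ``spectrogram``: the raw 196-dim spectrogram column, no temporal context;
- ``finetune``: the final deprojection output, with the whole backbone
  trained jointly with the head.

The probe itself is always a single linear map from the feature dimension
to the phrase classes, trained with cross-entropy and Adam (lr 1e-2 for
frozen-feature conditions, 3e-4 for finetuning), batch 42, validation every
25 batches with a 1,000-step moving average and patience 6, capped at 5,000
batches. No masking or frequency shifting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn as nn
from ._nn import Parameter, Tensor
from .embed import latents_for_song
from .model import ModelConfig, SongBertNetwork

CONDITIONS = ("pretrained", "untrained", "spectrogram", "finetune")


@dataclass
class ProbeConfig:
    condition: str = "pretrained"
    latent_block: int = 3
    learning_rate: float | None = None       # default per condition
    batch_size: int = 42
    eval_interval: int = 25                  # batches per validation check
    patience: int = 6
    max_batches: int = 5_000
    smoothing_span: int = 1_000
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.learning_rate is None:
            self.learning_rate = 3e-4 if self.condition == "finetune" else 1e-2


def features_for_condition(condition: str, net: SongBertNetwork | None,
                           values: np.ndarray, latent_block: int = 3
                           ) -> np.ndarray:
    """Frame features (T, D) of one song under a probe condition."""
    if condition == "spectrogram":
        return np.asarray(values).T
    if net is None:
        raise ValueError(f"condition {condition!r} needs a network")
    if condition in ("pretrained", "untrained"):
        return latents_for_song(net, values, block=latent_block)
    if condition == "finetune":
        recon, _ = net.forward(values)
        return recon.data.T
    raise ValueError(f"unknown condition {condition!r}")


class PhraseProbe(BaseEstimator, ClassifierMixin):
    """A single linear layer from frame features to phrase classes.

    Follows the probe training protocol (Adam, batch 42, early stopping on
    a smoothed validation loss). Classes absent from the training labels
    are excluded from the output space and flagged in ``missing_classes_``.
    """

    def __init__(self, learning_rate=1e-2, batch_size=42, eval_interval=25,
                 patience=6, max_batches=5_000, smoothing_span=1_000,
                 val_fraction=0.2, seed=0):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.eval_interval = eval_interval
        self.patience = patience
        self.max_batches = max_batches
        self.smoothing_span = smoothing_span
        self.val_fraction = val_fraction
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.missing_classes_ = set()
        yi = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.seed)
        n = len(X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        k = len(self.classes_)
        d = X.shape[1]
        W = Parameter(rng.normal(0.0, 0.01, (d, k)))
        b = Parameter(np.zeros(k))
        opt = nn.Adam([W, b], lr=self.learning_rate)
        best = np.inf
        counter = 0
        records: list[tuple[int, float]] = []
        self.history_ = []
        for step in range(1, self.max_batches + 1):
            idx = train_idx[rng.integers(0, len(train_idx), self.batch_size)]
            logits = Tensor(X[idx]) @ W + b
            loss = nn.cross_entropy(logits, yi[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            if step % self.eval_interval == 0:
                vlogits = X[val_idx] @ W.data + b.data
                vlogits -= vlogits.max(axis=1, keepdims=True)
                logp = vlogits - np.log(
                    np.exp(vlogits).sum(axis=1, keepdims=True))
                vloss = float(-logp[np.arange(len(val_idx)),
                                    yi[val_idx]].mean())
                records.append((step, vloss))
                recent = [r for s, r in records
                          if s > step - self.smoothing_span]
                smoothed = float(np.mean(recent))
                self.history_.append((step, vloss, smoothed))
                if smoothed < best:
                    best = smoothed
                    counter = 0
                else:
                    counter += 1
                    if counter >= self.patience:
                        break
        self.coef_ = W.data
        self.intercept_ = b.data
        self.n_steps_ = step
        return self

    def decision_function(self, X):
        return np.asarray(X) @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]


def probe_fer(probe: PhraseProbe, X: np.ndarray, y: np.ndarray
              ) -> dict[str, float]:
    """Frame error rate of a trained probe on held-out frames.

    Returns the overall FER (percent of mismatched frames), per-class FERs,
    and their standard deviation (population sd over classes).
    """
    pred = probe.predict(X)
    y = np.asarray(y)
    fer = 100.0 * float(np.mean(pred != y))
    per_class = {}
    for c in np.unique(y):
        sel = y == c
        per_class[int(c)] = 100.0 * float(np.mean(pred[sel] != y[sel]))
    sd = float(np.std(list(per_class.values()))) if per_class else 0.0
    return {"fer": fer, "per_class_fer": per_class, "per_class_sd": sd}


def _collect(condition: str, net: SongBertNetwork | None, songs_values,
             labels, latent_block: int) -> tuple[np.ndarray, np.ndarray]:
    Xs, ys = [], []
    for values, lab in zip(songs_values, labels):
        feats = features_for_condition(condition, net, values, latent_block)
        T = min(len(feats), len(lab))
        Xs.append(feats[:T])
        ys.append(np.asarray(lab)[:T])
    return np.concatenate(Xs), np.concatenate(ys)


def train_probe(condition: str, net: SongBertNetwork | None,
                train_values, train_labels, config: ProbeConfig | None = None,
                seed: int = 0) -> PhraseProbe:
    """Train a probe for one condition on frame-aligned phrase labels.

    For the frozen conditions features are computed once and only the head
    trains. The ``finetune`` condition trains the whole backbone jointly
    with the head (see :func:`finetune`).
    """
    config = config or ProbeConfig(condition=condition)
    if condition == "finetune":
        raise ValueError("use finetune() for the joint-training condition")
    X, y = _collect(condition, net, train_values, train_labels,
                    config.latent_block)
    probe = PhraseProbe(learning_rate=config.learning_rate,
                        batch_size=config.batch_size,
                        eval_interval=config.eval_interval,
                        patience=config.patience,
                        max_batches=config.max_batches,
                        smoothing_span=config.smoothing_span,
                        val_fraction=config.val_fraction, seed=seed)
    return probe.fit(X, y)


def finetune(net: SongBertNetwork, train_values, train_labels,
             config: ProbeConfig | None = None, seed: int = 0,
             context: int | None = None) -> tuple[SongBertNetwork, PhraseProbe]:
    """Joint supervised training of backbone + linear head.

    The head sits on the final deprojection output; all network weights
    train at lr 3e-4. Windows of the model's context length are drawn from
    the training songs; no masking or shifting is applied.
    """
    config = config or ProbeConfig(condition="finetune")
    rng = np.random.default_rng(seed)
    context = context or net.config.context
    classes = np.unique(np.concatenate([np.asarray(l) for l in train_labels]))
    k = len(classes)
    W = Parameter(rng.normal(0.0, 0.01, (net.config.n_freq, k)))
    b = Parameter(np.zeros(k))
    params = net.parameters() + [W, b]
    opt = nn.Adam(params, lr=config.learning_rate)
    probe = PhraseProbe(seed=seed)
    probe.classes_ = classes
    probe.missing_classes_ = set()
    best = np.inf
    counter = 0
    records: list[tuple[int, float]] = []
    n_songs = len(train_values)
    for step in range(1, config.max_batches + 1):
        sid = int(rng.integers(n_songs))
        values = np.asarray(train_values[sid])
        labels = np.asarray(train_labels[sid])
        T = values.shape[1]
        if T > context:
            start = int(rng.integers(0, T - context + 1))
            values = values[:, start:start + context]
            labels = labels[start:start + context]
        recon, _ = net.forward(values)
        feats = recon.swapaxes(0, 1)                     # (T, n_freq)
        logits = feats @ W + b
        yi = np.searchsorted(classes, labels[:feats.shape[0]])
        loss = nn.cross_entropy(logits, yi)
        opt.zero_grad()
        loss.backward()
        opt.step()
        if step % config.eval_interval == 0:
            records.append((step, float(loss.data)))
            recent = [r for s, r in records
                      if s > step - config.smoothing_span]
            smoothed = float(np.mean(recent))
            if smoothed < best:
                best = smoothed
                counter = 0
            else:
                counter += 1
                if counter >= config.patience:
                    break
    probe.coef_ = W.data
    probe.intercept_ = b.data
    probe.n_steps_ = step
    return net, probe


def evaluate_conditions(net: SongBertNetwork, untrained_seed: int,
                        train_values, train_labels,
                        test_values, test_labels,
                        conditions=("pretrained", "untrained", "spectrogram"),
                        latent_block: int = 3, seed: int = 0
                        ) -> dict[str, dict[str, float]]:
    """Train and evaluate probes for several conditions on one dataset."""
    results = {}
    untrained = SongBertNetwork(net.config, seed=untrained_seed)
    for condition in conditions:
        use_net = {"pretrained": net, "untrained": untrained,
                   "spectrogram": None, "finetune": net}[condition]
        cfg = ProbeConfig(condition=condition, latent_block=latent_block)
        probe = train_probe(condition, use_net, train_values, train_labels,
                            cfg, seed=seed)
        X, y = _collect(condition, use_net, test_values, test_labels,
                        latent_block)
        results[condition] = probe_fer(probe, X, y)
    return results
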