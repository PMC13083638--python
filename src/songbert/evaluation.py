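"""Comparing machine labels to ground truth.

Covers: syllable-to-phrase conversion (inter-syllabic silences absorbed into
the nearer phrase), V-measure (harmonic mean of homogeneity and
completeness), one-to-one Hungarian mapping of predicted clusters to
ground-truth labels on the column-normalized co-occurrence matrix, total and
matched-only frame error rates, phrase syntax statistics (mean run duration
and Shannon transition entropy in bits), a frequency-weighted Pearson
correlation, and the smoothing-window sweep that ties them together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import homogeneity_completeness_v_measure

from .embed import NOISE, _per_song, reassign_noise, smooth_labels
from .synthetic import SILENCE


@dataclass
class CooccurrenceMatrix:
    M: np.ndarray                       # (G, P) frame counts
    truth_labels: np.ndarray
    pred_labels: np.ndarray


@dataclass
class ClusterMapping:
    pairs: dict[int, int]               # truth label -> predicted label
    unmatched_predicted: set[int]
    unmatched_truth: set[int]

    @property
    def pred_to_truth(self) -> dict[int, int]:
        return {p: t for t, p in self.pairs.items()}


@dataclass
class PhraseStats:
    mean_duration: dict[int, float]     # label -> mean run length (bins)
    entropy: dict[int, float]           # label -> transition entropy (bits)
    occurrences: dict[int, int]         # label -> number of runs
    terminal_only: set[int] = field(default_factory=set)  # no outgoing runs


def syllables_to_phrases(labels: np.ndarray,
                         boundaries: np.ndarray | None = None,
                         silence: int = SILENCE) -> np.ndarray:
    """Absorb silent bins into the nearer adjacent syllable label.

    Equidistant silences take the label earlier in the song; leading or
    trailing silence takes the single adjacent label. An all-silence song is
    returned unchanged with a warning.
    """
    labels = np.asarray(labels).copy()
    for a, b in _per_song(labels, boundaries):
        seg = labels[a:b]
        if np.all(seg == silence):
            warnings.warn("all-silence sequence left unchanged")
            continue
        # identical nearest-fill as noise reassignment, silence as sentinel
        labels[a:b] = reassign_noise(seg, noise=silence)
    return labels


def v_measure(gt: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    """(v, homogeneity, completeness) of predicted labels vs ground truth."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.shape != pred.shape:
        raise ValueError("label sequences must have equal length")
    h, c, v = homogeneity_completeness_v_measure(gt, pred)
    return float(v), float(h), float(c)


def cooccurrence(gt: np.ndarray, pred: np.ndarray) -> CooccurrenceMatrix:
    gt, pred = np.asarray(gt), np.asarray(pred)
    truth_labels = np.unique(gt)
    pred_labels = np.unique(pred)
    gi = np.searchsorted(truth_labels, gt)
    pi = np.searchsorted(pred_labels, pred)
    M = np.zeros((len(truth_labels), len(pred_labels)), dtype=np.int64)
    np.add.at(M, (gi, pi), 1)
    return CooccurrenceMatrix(M, truth_labels, pred_labels)


def map_labels(gt: np.ndarray, pred: np.ndarray
               ) -> tuple[CooccurrenceMatrix, ClusterMapping]:
    """Hungarian one-to-one assignment on the column-normalized matrix.

    Columns (predicted clusters) are normalized to proportions so clusters
    of different sizes compete fairly; the assignment maximizes the summed
    normalized co-occurrence. Labels left without a partner are unmatched.
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    if gt.size == 0 or gt.shape != pred.shape:
        raise ValueError("need equal-length, non-empty label sequences")
    co = cooccurrence(gt, pred)
    col_tot = co.M.sum(axis=0, keepdims=True)
    norm = co.M / np.maximum(col_tot, 1)
    rows, cols = linear_sum_assignment(norm, maximize=True)
    pairs = {int(co.truth_labels[r]): int(co.pred_labels[c])
             for r, c in zip(rows, cols)}
    mapping = ClusterMapping(
        pairs=pairs,
        unmatched_predicted=set(co.pred_labels) - set(pairs.values()),
        unmatched_truth=set(co.truth_labels) - set(pairs.keys()))
    return co, mapping


def frame_error_rates(gt: np.ndarray, pred: np.ndarray,
                      mapping: ClusterMapping) -> dict[str, float]:
    """Total and matched-only frame error rates, in percent.

    Total counts every frame in an unmatched predicted cluster as an error;
    matched-only restricts the denominator to frames whose predicted
    cluster has a mapping.
    """
    gt, pred = np.asarray(gt), np.asarray(pred)
    p2t = mapping.pred_to_truth
    mapped = np.isin(pred, list(p2t.keys()))
    translated = np.where(
        mapped,
        np.vectorize(lambda p: p2t.get(int(p), NOISE))(pred)
        if len(pred) else pred,
        NOISE)
    mismatch = translated != gt
    total_errors = int(np.sum(mismatch | ~mapped))
    total_fer = 100.0 * total_errors / len(gt)
    n_matched = int(mapped.sum())
    matched_fer = (100.0 * int(np.sum(mismatch & mapped)) / n_matched
                   if n_matched else 0.0)
    return {"total_fer": total_fer, "matched_fer": matched_fer}


def _runs(seg: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encoding: list of (label, length)."""
    if len(seg) == 0:
        return []
    change = np.flatnonzero(np.diff(seg)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(seg)]])
    return [(int(seg[s]), int(e - s)) for s, e in zip(starts, ends)]


def phrase_statistics(labels: np.ndarray,
                      boundaries: np.ndarray | None = None) -> PhraseStats:
    """Per-label mean run duration (bins), transition entropy (bits), and
    run counts. Transitions are counted between consecutive runs within one
    song only; a label that only ever ends songs gets entropy 0 and a flag.
    """
    durations: dict[int, list[int]] = {}
    transitions: dict[int, dict[int, int]] = {}
    occurrences: dict[int, int] = {}
    for a, b in _per_song(np.asarray(labels), boundaries):
        runs = _runs(np.asarray(labels)[a:b])
        for i, (lab, length) in enumerate(runs):
            durations.setdefault(lab, []).append(length)
            occurrences[lab] = occurrences.get(lab, 0) + 1
            if i + 1 < len(runs):
                nxt = runs[i + 1][0]
                transitions.setdefault(lab, {})
                transitions[lab][nxt] = transitions[lab].get(nxt, 0) + 1
    entropy = {}
    terminal_only = set()
    for lab in durations:
        counts = np.array(list(transitions.get(lab, {}).values()), dtype=float)
        if counts.size == 0:
            entropy[lab] = 0.0
            terminal_only.add(lab)
        else:
            p = counts / counts.sum()
            entropy[lab] = float(-(p * np.log2(p)).sum())
    return PhraseStats(
        mean_duration={k: float(np.mean(v)) for k, v in durations.items()},
        entropy=entropy, occurrences=occurrences,
        terminal_only=terminal_only)


def weighted_pearson(x: np.ndarray, y: np.ndarray,
                     w: np.ndarray) -> float:
    """Pearson correlation under weighted means/variances/covariance."""
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    if not (len(x) == len(y) == len(w)) or len(x) < 2:
        raise ValueError("need equal-length inputs of length >= 2")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero weighted variance: correlation undefined")
    return float(cov / np.sqrt(vx * vy))


def phrase_metric_correlations(gt: np.ndarray, pred: np.ndarray,
                               mapping: ClusterMapping,
                               boundaries: np.ndarray | None = None
                               ) -> dict[str, float]:
    """Weighted correlations of per-phrase duration and entropy between
    ground truth and mapped predictions; weights are ground-truth run counts
    of each matched phrase."""
    gt_stats = phrase_statistics(gt, boundaries)
    pred_stats = phrase_statistics(pred, boundaries)
    rows = [(t, p) for t, p in mapping.pairs.items()
            if t in gt_stats.mean_duration and p in pred_stats.mean_duration]
    out = {"duration_r": np.nan, "entropy_r": np.nan}
    if len(rows) >= 2:
        w = np.array([gt_stats.occurrences[t] for t, _ in rows], dtype=float)
        dx = np.array([gt_stats.mean_duration[t] for t, _ in rows])
        dy = np.array([pred_stats.mean_duration[p] for _, p in rows])
        ex = np.array([gt_stats.entropy[t] for t, _ in rows])
        ey = np.array([pred_stats.entropy[p] for _, p in rows])
        for key, xs, ys in (("duration_r", dx, dy), ("entropy_r", ex, ey)):
            try:
                out[key] = weighted_pearson(xs, ys, w)
            except ValueError:
                out[key] = np.nan
    return out


def evaluate_labels(gt_phrases: np.ndarray, pred: np.ndarray,
                    boundaries: np.ndarray | None = None) -> dict[str, float]:
    """All metrics for one ground-truth/prediction pair."""
    v, h, c = v_measure(gt_phrases, pred)
    _, mapping = map_labels(gt_phrases, pred)
    fers = frame_error_rates(gt_phrases, pred, mapping)
    corr = phrase_metric_correlations(gt_phrases, pred, mapping, boundaries)
    return {"v_measure": v, "homogeneity": h, "completeness": c,
            **fers, **corr,
            "n_unmatched_pred": float(len(mapping.unmatched_predicted))}


def smoothing_sweep(gt_phrases: np.ndarray, pred_raw: np.ndarray,
                    boundaries: np.ndarray | None = None,
                    windows: np.ndarray | None = None) -> pd.DataFrame:
    """Metrics as a function of the smoothing window (default 0..500 by 25).

    For each window: reassign noise, smooth, map clusters, compute
    V-measure, both frame error rates, and the duration/entropy
    correlations. Window 0 reports metrics on unsmoothed labels.
    """
    if windows is None:
        windows = np.arange(0, 501, 25)
    cleaned = reassign_noise(pred_raw, boundaries)
    rows = []
    for w in windows:
        labels = smooth_labels(cleaned, int(w), boundaries)
        rows.append({"window": int(w),
                     **evaluate_labels(gt_phrases, labels, boundaries)})
    return pd.DataFrame(rows)
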