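"""From a trained network to frame-level cluster labels.

Pipeline: collect one latent vector per 2.7 ms time bin (block-3
post-attention tap), reduce to 2-D with UMAP (cosine distance, 200
neighbors, min-dist 0.1, seed 42 at full scale), cluster with HDBSCAN
(min_cluster_size 5,000, min_samples 1 at full scale), then clean the label
sequence per song: noise bins (-1) take the nearest non-noise label in time
(tie -> left), and a window-majority temporal smoothing suppresses brief
spurious labels. Both label-sequence operations never cross song
boundaries, and smoothing is a single non-recursive pass computed from the
original labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import SongBertNetwork

NOISE = -1


@dataclass
class EmbeddingFold:
    """Latents (and, once reduced, 2-D coordinates) with per-row provenance."""

    latents: np.ndarray                       # (N, d_model)
    song_ids: np.ndarray                      # (N,) int
    frame_ids: np.ndarray                     # (N,) int
    coords2d: np.ndarray | None = None        # (N, 2)
    fold_id: int = 0

    def __post_init__(self):
        if not (len(self.latents) == len(self.song_ids) == len(self.frame_ids)):
            raise ValueError("provenance must match latent rows")

    @property
    def song_boundaries(self) -> np.ndarray:
        """Start indices of each song's run of rows (rows are song-ordered)."""
        change = np.flatnonzero(np.diff(self.song_ids)) + 1
        return np.concatenate([[0], change, [len(self.song_ids)]])


def latents_for_song(net: SongBertNetwork, values: np.ndarray,
                     block: int = 3, tap: str | None = None) -> np.ndarray:
    """One latent per frame of a whole song, tiling context-length windows.

    The song is cut into consecutive windows of the model's context length;
    the last window is zero-padded and only its valid frames kept.
    """
    context = net.config.context
    T = values.shape[1]
    out = np.empty((T, net.config.d_model))
    for start in range(0, T, context):
        chunk = values[:, start:start + context]
        valid = chunk.shape[1]
        if valid < context:
            padded = np.zeros((values.shape[0], context))
            padded[:, :valid] = chunk
            chunk = padded
        lat = net.extract_latent(chunk, block=block, tap=tap)
        out[start:start + valid] = lat[:valid]
    return out


def collect_latents(net: SongBertNetwork, songs: list, cap: int = 1_000_000,
                    block: int = 3, tap: str | None = None,
                    fold_id: int = 0) -> EmbeddingFold:
    """Latents for a list of songs/spectrograms, truncated at `cap` rows."""
    from .trainer import _as_spectrogram_values
    lat_parts, song_parts, frame_parts = [], [], []
    total = 0
    for sid, song in enumerate(songs):
        if total >= cap:
            break
        values = _as_spectrogram_values(song)
        lat = latents_for_song(net, values, block=block, tap=tap)
        take = min(len(lat), cap - total)
        lat_parts.append(lat[:take])
        song_parts.append(np.full(take, sid))
        frame_parts.append(np.arange(take))
        total += take
    return EmbeddingFold(
        latents=np.concatenate(lat_parts),
        song_ids=np.concatenate(song_parts),
        frame_ids=np.concatenate(frame_parts),
        fold_id=fold_id)


def reduce_umap(latents: np.ndarray, n_neighbors: int = 200,
                min_dist: float = 0.1, metric: str = "cosine",
                seed: int = 42, n_components: int = 2) -> np.ndarray:
    """2-D UMAP with the reference defaults; scale n_neighbors down for
    small inputs."""
    latents = np.asarray(latents)
    if len(latents) <= n_neighbors:
        raise ValueError("need more points than n_neighbors")
    import umap

    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        metric=metric, n_components=n_components,
                        random_state=seed)
    return np.asarray(reducer.fit_transform(latents), dtype=np.float64)


def cluster_hdbscan(coords: np.ndarray, min_cluster_size: int = 5_000,
                    min_samples: int = 1) -> np.ndarray:
    """Density clustering; -1 marks noise. Parameters scale down for tests."""
    from sklearn.cluster import HDBSCAN

    clusterer = HDBSCAN(min_cluster_size=min_cluster_size,
                        min_samples=min_samples)
    return clusterer.fit_predict(np.asarray(coords)).astype(np.int64)


def _per_song(labels: np.ndarray, boundaries: np.ndarray | None):
    labels = np.asarray(labels)
    if boundaries is None:
        boundaries = np.array([0, len(labels)])
    boundaries = np.asarray(boundaries)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        yield int(a), int(b)


def reassign_noise(labels: np.ndarray,
                   boundaries: np.ndarray | None = None,
                   noise: int = NOISE) -> np.ndarray:
    """Replace noise bins with the nearest non-noise label in the same song.

    Distance is in time bins; ties default to the left neighbor; a song with
    no valid label anywhere is returned unchanged.
    """
    labels = np.asarray(labels).copy()
    for a, b in _per_song(labels, boundaries):
        seg = labels[a:b]
        valid = np.flatnonzero(seg != noise)
        if len(valid) == 0 or len(valid) == len(seg):
            continue
        idx = np.arange(len(seg))
        # nearest valid on the left (or -1) and right (or len)
        left = valid[np.searchsorted(valid, idx, side="right") - 1]
        has_left = np.searchsorted(valid, idx, side="right") > 0
        ri = np.searchsorted(valid, idx, side="left")
        has_right = ri < len(valid)
        right = valid[np.minimum(ri, len(valid) - 1)]
        dl = np.where(has_left, idx - left, np.iinfo(np.int64).max)
        dr = np.where(has_right, right - idx, np.iinfo(np.int64).max)
        use_left = dl <= dr                      # tie -> left
        fill = np.where(use_left, seg[np.where(has_left, left, 0)],
                        seg[np.where(has_right, right, 0)])
        noisy = seg == noise
        seg[noisy] = fill[noisy]
        labels[a:b] = seg
    return labels


def smooth_labels(labels: np.ndarray, w: int,
                  boundaries: np.ndarray | None = None) -> np.ndarray:
    """Window-majority smoothing of a frame-label sequence.

    For each position i the label becomes the most frequent label in the
    length-w window centered at i (for even w the window is left-heavy:
    [i - w//2, i + (w+1)//2)), truncated at the song edges. Ties go to the
    label that appears first in the window. All outputs are computed from
    the original labels (single non-recursive pass). w of 0 or 1 is the
    identity.
    """
    if w < 0:
        raise ValueError("window must be non-negative")
    labels = np.asarray(labels).copy()
    if w <= 1:
        return labels
    out = labels.copy()
    half_lo, half_hi = w // 2, (w + 1) // 2
    for a, b in _per_song(labels, boundaries):
        seg = labels[a:b]
        n = len(seg)
        for i in range(n):
            lo, hi = max(0, i - half_lo), min(n, i + half_hi)
            window = seg[lo:hi]
            vals, first_pos, counts = np.unique(window, return_index=True,
                                                return_counts=True)
            best = counts.max()
            cands = counts == best
            # tie -> earliest first occurrence within the window
            out[a + i] = vals[cands][np.argmin(first_pos[cands])]
    return out


class FrameClusterer:
    """Scikit-learn style front door for the latent-clustering stage.

    fit_predict(fold) runs UMAP, HDBSCAN, noise reassignment and smoothing
    and returns one integer label per frame. Fitted attributes expose the
    2-D coordinates and the raw (pre-cleanup) cluster labels.
    """

    def __init__(self, n_neighbors=200, min_dist=0.1, umap_seed=42,
                 min_cluster_size=5_000, min_samples=1, smoothing_window=0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.umap_seed = umap_seed
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.smoothing_window = smoothing_window

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "n_neighbors", "min_dist", "umap_seed", "min_cluster_size",
            "min_samples", "smoothing_window")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_predict(self, fold: EmbeddingFold) -> np.ndarray:
        self.coords2d_ = reduce_umap(
            fold.latents, n_neighbors=self.n_neighbors,
            min_dist=self.min_dist, seed=self.umap_seed)
        fold.coords2d = self.coords2d_
        self.raw_labels_ = cluster_hdbscan(
            self.coords2d_, min_cluster_size=self.min_cluster_size,
            min_samples=self.min_samples)
        bounds = fold.song_boundaries
        labels = reassign_noise(self.raw_labels_, bounds)
        if self.smoothing_window > 1:
            labels = smooth_labels(labels, self.smoothing_window, bounds)
        self.labels_ = labels
        return labels
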