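"""Repertoire-overlap analysis between recording epochs.

Frame embeddings from different temporal groups (two per season) are binned
into 300 x 300 2-D histograms over one shared extent (the pooled bounding
box padded by 1%, upper edges closed), normalized to probability
distributions, and compared with the Bhattacharyya coefficient
BC(P, Q) = sum(sqrt(P * Q)): 1 for identical distributions, 0 for disjoint
support. Stable repertoires give high within-season BC; seasonal turnover
depresses the between-season BC.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np


@dataclass
class EmbeddingHistogram:
    P: np.ndarray                       # (bins, bins), sums to 1
    extent: tuple[float, float, float, float]   # xmin, xmax, ymin, ymax
    group_id: str = ""


def shared_extent(groups: list[np.ndarray],
                  pad: float = 0.01) -> tuple[float, float, float, float]:
    """Bounding box of the pooled coordinates, padded on each side."""
    allpts = np.concatenate([np.asarray(g) for g in groups])
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    dx = (xmax - xmin) or 1.0
    dy = (ymax - ymin) or 1.0
    return (xmin - pad * dx, xmax + pad * dx,
            ymin - pad * dy, ymax + pad * dy)


def histogram2d(coords: np.ndarray,
                extent: tuple[float, float, float, float],
                bins: int = 300, group_id: str = "") -> EmbeddingHistogram:
    """Normalized 2-D histogram on a fixed extent (upper edges closed)."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty coordinate set")
    H, _, _ = np.histogram2d(coords[:, 0], coords[:, 1], bins=bins,
                             range=[extent[:2], extent[2:]])
    total = H.sum()
    if total == 0:
        raise ValueError("no points fall inside the extent")
    return EmbeddingHistogram(H / total, extent, group_id)


def bhattacharyya(P: EmbeddingHistogram | np.ndarray,
                  Q: EmbeddingHistogram | np.ndarray) -> float:
    """Overlap of two discrete probability distributions, in [0, 1]."""
    p = P.P if isinstance(P, EmbeddingHistogram) else np.asarray(P, dtype=float)
    q = Q.P if isinstance(Q, EmbeddingHistogram) else np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share a shape")
    for name, a in (("P", p), ("Q", q)):
        if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} must be a normalized distribution")
    return float(np.sqrt(p * q).sum())


def season_comparison(groups: dict[str, np.ndarray],
                      seasons: dict[str, str],
                      bins: int = 300) -> dict:
    """Within- vs between-season overlap of 2+2 temporal groups.

    `groups` maps group id -> (N, 2) embedding coordinates; `seasons` maps
    group id -> season label. With two groups per season this averages the
    2 same-season pairs and the 4 cross-season pairs.
    """
    season_counts: dict[str, int] = {}
    for g in groups:
        season_counts[seasons[g]] = season_counts.get(seasons[g], 0) + 1
    if any(c < 2 for c in season_counts.values()) or len(season_counts) < 2:
        raise ValueError("need at least two groups per season, two seasons")
    extent = shared_extent(list(groups.values()))
    hists = {g: histogram2d(c, extent, bins=bins, group_id=g)
             for g, c in groups.items()}
    pairwise = {}
    within, between = [], []
    for a, b in combinations(sorted(groups), 2):
        bc = bhattacharyya(hists[a], hists[b])
        pairwise[(a, b)] = bc
        (within if seasons[a] == seasons[b] else between).append(bc)
    return {"within_season": float(np.mean(within)),
            "between_season": float(np.mean(between)),
            "pairwise": pairwise, "extent": extent}
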