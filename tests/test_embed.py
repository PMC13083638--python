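"""Latent collection, dimensionality reduction, clustering, label cleanup."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from songbert.embed import (
    NOISE,
    EmbeddingFold,
    FrameClusterer,
    cluster_hdbscan,
    collect_latents,
    reassign_noise,
    reduce_umap,
    smooth_labels,
)
from songbert.model import ModelConfig, SongBertNetwork

TINY = ModelConfig(conv_channels=(2, 4, 4, 4), d_model=16, n_heads=2,
                   ffn_dim=32, n_blocks=2, context=64, relpos_clip=64)


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_reassign(seq, noise=NOISE):
    seq = list(seq)
    out = list(seq)
    for i, lab in enumerate(seq):
        if lab != noise:
            continue
        best = None           # (distance, side_preference)
        for j, other in enumerate(seq):
            if other == noise:
                continue
            d = abs(j - i)
            side = 0 if j < i else 1          # tie -> left
            if best is None or (d, side) < best[:2]:
                best = (d, side, other)
        if best is not None:
            out[i] = best[2]
    return np.array(out)


def brute_smooth(seq, w):
    seq = list(seq)
    n = len(seq)
    if w <= 1:
        return np.array(seq)
    out = []
    for i in range(n):
        lo, hi = max(0, i - w // 2), min(n, i + (w + 1) // 2)
        window = seq[lo:hi]
        counts = {}
        for lab in window:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        # tie: first occurrence in the window wins
        for lab in window:
            if counts[lab] == best:
                out.append(lab)
                break
    return np.array(out)


class TestReassignNoise:
    @pytest.mark.parametrize("seq,expected", [
        ([-1, 2, 2], [2, 2, 2]),
        ([1, -1, 3], [1, 1, 3]),          # equidistant -> left
        ([-1, -1, -1], [-1, -1, -1]),     # nothing to copy from
        ([5], [5]),
        ([1, -1, -1, -1, 2], [1, 1, 1, 2, 2]),
    ])
    def test_examples(self, seq, expected):
        np.testing.assert_array_equal(reassign_noise(np.array(seq)), expected)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            seq = rng.integers(-1, 4, n)
            np.testing.assert_array_equal(reassign_noise(seq),
                                          brute_reassign(seq))

    def test_respects_song_boundaries(self):
        seq = np.array([1, 1, -1, -1, 2, 2])
        bounds = np.array([0, 3, 6])
        out = reassign_noise(seq, bounds)
        # the noise at index 2 may only look inside song 1 -> becomes 1
        np.testing.assert_array_equal(out, [1, 1, 1, 2, 2, 2])


class TestSmoothLabels:
    def test_identity_for_tiny_windows(self, rng):
        seq = rng.integers(0, 4, 30)
        for w in (0, 1):
            np.testing.assert_array_equal(smooth_labels(seq, w), seq)

    def test_constant_sequence_unchanged(self):
        seq = np.full(20, 3)
        np.testing.assert_array_equal(smooth_labels(seq, 5), seq)

    def test_majority_flips_isolated_label(self):
        np.testing.assert_array_equal(
            smooth_labels(np.array([1, 1, 2, 1, 1]), 5), [1, 1, 1, 1, 1])

    def test_tie_goes_to_first_in_window(self):
        # window at the center position holds {2, 2, 3, 3}; 2 appears first
        seq = np.array([2, 2, 3, 3])
        out = smooth_labels(seq, 4)
        assert out[2] == 2

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(np.array([1, 2]), -1)

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            w = int(rng.integers(0, 10))
            seq = rng.integers(0, 4, n)
            np.testing.assert_array_equal(smooth_labels(seq, w),
                                          brute_smooth(seq, w))

    def test_single_pass_uses_original_labels(self):
        # a recursive pass would propagate the flip rightward
        seq = np.array([2, 2, 2, 1, 1, 1, 1])
        out = smooth_labels(seq, 3)
        np.testing.assert_array_equal(out, brute_smooth(seq, 3))


class TestCollectLatents:
    def test_cap_and_provenance(self, small_corpus):
        _, _, specs = small_corpus
        net = SongBertNetwork(
            ModelConfig(conv_channels=(2, 4, 4, 4), d_model=16, n_heads=2,
                        ffn_dim=32, n_blocks=2, context=250, relpos_clip=128),
            seed=0)
        fold = collect_latents(net, specs[:2], cap=100, block=2)
        assert len(fold.latents) == 100
        prov = set(zip(fold.song_ids.tolist(), fold.frame_ids.tolist()))
        assert len(prov) == 100

    def test_uncapped_row_count_equals_frame_census(self, small_corpus):
        _, songs, specs = small_corpus
        net = SongBertNetwork(
            ModelConfig(conv_channels=(2, 4, 4, 4), d_model=16, n_heads=2,
                        ffn_dim=32, n_blocks=2, context=250, relpos_clip=128),
            seed=0)
        fold = collect_latents(net, specs, cap=10**9, block=1)
        assert len(fold.latents) == sum(s.shape[1] for s in specs)
        assert fold.latents.shape[1] == 16


class TestReduceUmap:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 16))
        a = reduce_umap(x, n_neighbors=10, seed=42)
        b = reduce_umap(x, n_neighbors=10, seed=42)
        assert a.shape == (300, 2)
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            reduce_umap(np.zeros((5, 16)), n_neighbors=10)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((1000, 196)) + 0.0
        b = rng.standard_normal((1000, 196)) + 12.0
        coords = reduce_umap(np.vstack([a, b]), n_neighbors=15, seed=42)
        ident = np.repeat([0, 1], 1000)
        assert silhouette_score(coords, ident) > 0.5


class TestClusterHdbscan:
    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((6000, 2))
        b = rng.standard_normal((6000, 2)) + 30.0
        labels = cluster_hdbscan(np.vstack([a, b]), min_cluster_size=5000)
        found = set(labels.tolist()) - {NOISE}
        assert len(found) == 2

    def test_too_small_structure_is_all_noise(self):
        rng = np.random.default_rng(5)
        labels = cluster_hdbscan(rng.uniform(0, 1, (500, 2)),
                                 min_cluster_size=5000)
        assert set(labels.tolist()) == {NOISE}

    def test_label_domain(self):
        rng = np.random.default_rng(6)
        labels = cluster_hdbscan(rng.standard_normal((200, 2)),
                                 min_cluster_size=20)
        assert all(l >= -1 for l in labels)


def test_frame_clusterer_params_roundtrip():
    fc = FrameClusterer(min_cluster_size=50)
    params = fc.get_params()
    assert params["min_cluster_size"] == 50
    fc.set_params(smoothing_window=7)
    assert fc.smoothing_window == 7
    with pytest.raises(ValueError):
        fc.set_params(bogus=1)
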