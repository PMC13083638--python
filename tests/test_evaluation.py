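"""Metrics: phrase conversion, V-measure, Hungarian mapping, FER,
phrase syntax statistics, weighted correlation, smoothing sweep."""

import itertools

import numpy as np
import pytest

from songbert.evaluation import (
    cooccurrence,
    evaluate_labels,
    frame_error_rates,
    map_labels,
    phrase_statistics,
    smoothing_sweep,
    syllables_to_phrases,
    v_measure,
    weighted_pearson,
)


class TestSyllablesToPhrases:
    @pytest.mark.parametrize("seq,expected", [
        ([1, 0, 1], [1, 1, 1]),
        ([1, 0, 2], [1, 1, 2]),            # equidistant -> earlier label
        ([0, 0, 1, 0], [1, 1, 1, 1]),      # boundary silence -> adjacent
        ([2, 2, 0, 0, 0, 3], [2, 2, 2, 2, 3, 3]),
    ])
    def test_examples(self, seq, expected):
        np.testing.assert_array_equal(
            syllables_to_phrases(np.array(seq)), expected)

    def test_all_silence_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = syllables_to_phrases(np.zeros(5, dtype=int))
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_boundaries_respected(self):
        seq = np.array([1, 0, 0, 2])
        out = syllables_to_phrases(seq, boundaries=np.array([0, 2, 4]))
        np.testing.assert_array_equal(out, [1, 1, 2, 2])


class TestVMeasure:
    def test_perfect_up_to_relabeling(self):
        gt = np.array([0, 0, 1, 1, 2])
        pred = np.array([7, 7, 3, 3, 9])
        v, h, c = v_measure(gt, pred)
        assert v == h == c == 1.0

    def test_single_cluster_has_zero_homogeneity(self):
        v, h, c = v_measure(np.array([0, 0, 1, 1]), np.array([0, 0, 0, 0]))
        assert h == 0.0 and v == 0.0

    def test_oversplit_closed_form(self):
        v, h, c = v_measure(np.array([0, 0, 1, 1]), np.array([0, 1, 2, 3]))
        assert h == pytest.approx(1.0)
        assert c == pytest.approx(0.5)
        assert v == pytest.approx(2 / 3)

    def test_permutation_invariance(self, rng):
        gt = rng.integers(0, 3, 60)
        pred = rng.integers(0, 4, 60)
        v1, _, _ = v_measure(gt, pred)
        v2, _, _ = v_measure((gt + 5) % 7, pred)
        perm = {0: 3, 1: 0, 2: 2, 3: 1}
        v3, _, _ = v_measure(gt, np.vectorize(perm.get)(pred))
        assert v1 == pytest.approx(v2) == pytest.approx(v3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            v_measure(np.zeros(3), np.zeros(4))


def brute_assignment_score(M):
    """Best one-to-one assignment score by exhaustive permutation search."""
    G, P = M.shape
    best = -np.inf
    if G <= P:
        for perm in itertools.permutations(range(P), G):
            best = max(best, sum(M[i, j] for i, j in enumerate(perm)))
    else:
        for perm in itertools.permutations(range(G), P):
            best = max(best, sum(M[i, j] for j, i in enumerate(perm)))
    return best


class TestMapLabels:
    def test_diagonal_identity(self):
        gt = np.array([0, 0, 1, 1, 2, 2])
        _, mapping = map_labels(gt, gt)
        assert mapping.pairs == {0: 0, 1: 1, 2: 2}
        assert not mapping.unmatched_predicted
        assert not mapping.unmatched_truth

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            G = int(rng.integers(1, 7))
            P = int(rng.integers(1, 7))
            n = int(rng.integers(20, 60))
            gt = rng.integers(0, G, n)
            pred = rng.integers(0, P, n)
            co, mapping = map_labels(gt, pred)
            norm = co.M / np.maximum(co.M.sum(axis=0, keepdims=True), 1)
            achieved = sum(
                norm[np.searchsorted(co.truth_labels, t),
                     np.searchsorted(co.pred_labels, p)]
                for t, p in mapping.pairs.items())
            assert achieved == pytest.approx(brute_assignment_score(norm))

    def test_surplus_predicted_clusters_left_unmatched(self):
        gt = np.array([0] * 4 + [1] * 4)
        pred = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        _, mapping = map_labels(gt, pred)
        assert len(mapping.pairs) == 2
        assert len(mapping.unmatched_predicted) == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            map_labels(np.array([]), np.array([]))


class TestFrameErrorRates:
    def test_perfect_prediction(self):
        gt = np.array([0, 0, 1, 1])
        _, mapping = map_labels(gt, gt)
        fer = frame_error_rates(gt, gt, mapping)
        assert fer == {"total_fer": 0.0, "matched_fer": 0.0}

    def test_hand_counted_case(self):
        gt = np.array([10, 10, 11, 12, 12])
        pred = np.array([0, 0, 2, 1, 1])
        _, mapping = map_labels(gt, pred)
        # cluster 2 covers only the single gt-11 frame; after 10->0, 12->1
        # it may claim 11. Build the specified mapping by hand instead.
        from songbert.evaluation import ClusterMapping
        mapping = ClusterMapping(pairs={10: 0, 12: 1},
                                 unmatched_predicted={2},
                                 unmatched_truth={11})
        fer = frame_error_rates(gt, pred, mapping)
        assert fer["total_fer"] == pytest.approx(20.0)
        assert fer["matched_fer"] == pytest.approx(0.0)

    def test_error_partition_invariant(self, rng):
        for _ in range(50):
            gt = rng.integers(0, 3, 40)
            pred = rng.integers(0, 5, 40)
            _, mapping = map_labels(gt, pred)
            fer = frame_error_rates(gt, pred, mapping)
            mapped = np.isin(pred, list(mapping.pred_to_truth))
            n_unmatched = int((~mapped).sum())
            p2t = mapping.pred_to_truth
            matched_errors = sum(
                1 for g, p in zip(gt, pred)
                if p in p2t and p2t[p] != g)
            assert fer["total_fer"] == pytest.approx(
                100.0 * (matched_errors + n_unmatched) / 40)
            assert fer["total_fer"] >= 100.0 * matched_errors / 40 - 1e-9


class TestPhraseStatistics:
    def test_hand_worked_runs(self):
        stats = phrase_statistics(np.array([1, 1, 1, 2, 2, 1, 1]))
        assert stats.mean_duration[1] == pytest.approx(2.5)
        assert stats.mean_duration[2] == pytest.approx(2.0)
        assert stats.entropy[1] == 0.0
        assert stats.entropy[2] == 0.0
        assert stats.occurrences == {1: 2, 2: 1}
        assert 1 in stats.terminal_only or stats.entropy[1] == 0.0

    def test_balanced_successors_give_one_bit(self):
        seq = np.array([1, 2, 1, 3, 1, 2, 1, 3])
        stats = phrase_statistics(seq)
        assert stats.entropy[1] == pytest.approx(1.0)

    def test_deterministic_chain_zero_entropy(self):
        seq = np.array([1, 2, 1, 2, 1, 2])
        stats = phrase_statistics(seq)
        assert all(e == 0.0 for e in stats.entropy.values())

    def test_transitions_do_not_cross_songs(self):
        seq = np.array([1, 1, 2, 2, 1, 1, 3, 3])
        bounds = np.array([0, 4, 8])
        stats = phrase_statistics(seq, bounds)
        # within songs: 1->2 (song 1), 1->3 (song 2); never 2->1
        assert stats.entropy[2] == 0.0
        assert 2 in stats.terminal_only


class TestWeightedPearson:
    def test_perfect_line(self, rng):
        x = rng.standard_normal(10)
        w = rng.uniform(0.5, 2.0, 10)
        assert weighted_pearson(x, 2 * x + 1, w) == pytest.approx(1.0)

    def test_uniform_weights_reduce_to_plain(self, rng):
        x, y = rng.standard_normal((2, 20))
        plain = np.corrcoef(x, y)[0, 1]
        assert weighted_pearson(x, y, np.ones(20)) == pytest.approx(
            plain, abs=1e-12)

    def test_integer_weights_equal_replication(self, rng):
        x, y = rng.standard_normal((2, 8))
        w = rng.integers(1, 5, 8)
        xr = np.repeat(x, w)
        yr = np.repeat(y, w)
        assert weighted_pearson(x, y, w) == pytest.approx(
            np.corrcoef(xr, yr)[0, 1], abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weighted_pearson([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            weighted_pearson([1.0, 2.0], [0.0, 1.0], [1.0, -1.0])


class TestSmoothingSweep:
    def test_window_zero_equals_unsmoothed_metrics(self, rng):
        gt = np.repeat(rng.integers(1, 4, 20), 10)
        pred = gt.copy()
        pred[::17] = -1
        table = smoothing_sweep(gt, pred, windows=np.array([0]))
        from songbert.embed import reassign_noise
        direct = evaluate_labels(gt, reassign_noise(pred))
        assert table.loc[0, "v_measure"] == pytest.approx(direct["v_measure"])
        assert table.loc[0, "total_fer"] == pytest.approx(direct["total_fer"])

    def test_default_sweep_has_21_rows(self, rng):
        gt = np.repeat([1, 2, 3], 30)
        table = smoothing_sweep(gt, gt.copy(), windows=None)
        assert len(table) == 21
        np.testing.assert_array_equal(table["window"], np.arange(0, 501, 25))

    def test_smoothing_removes_planted_spurious_labels(self):
        """Brief 1-3-bin label glitches raise FER at window 0; a ~200-bin
        window recovers the clean sequence."""
        rng = np.random.default_rng(7)
        gt = np.repeat(rng.integers(1, 4, 12), 500)   # ~1.3 s phrases
        pred = gt.copy()
        for _ in range(60):
            i = int(rng.integers(0, len(pred) - 3))
            pred[i:i + int(rng.integers(1, 4))] = int(rng.integers(4, 7))
        table = smoothing_sweep(gt, pred, windows=np.array([0, 200]))
        fer0 = table.set_index("window").loc[0, "total_fer"]
        fer200 = table.set_index("window").loc[200, "total_fer"]
        assert fer0 > 0.0
        assert fer200 < fer0
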