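from math import comb

import numpy as np
import pytest

from predann.evaluation import (
    WindowPredictions,
    accuracy_report,
    aggregate_majority,
    aggregate_max,
    aggregate_mean,
    chance_level,
    mcnemar_test,
    sliding_window_scores,
)
from predann.synthetic import worked_example_scores


def uniform_predict(windows):
    n = windows.shape[0]
    return np.full((n, 4), 0.25)


class TestSlidingWindows:
    @pytest.mark.parametrize("seconds,expected", [(5, 3), (7, 5), (3, 1)])
    def test_window_counts_at_one_second_stride(self, seconds, expected):
        excerpt = np.zeros((2, seconds * 125))
        wp = sliding_window_scores(uniform_predict, excerpt, 125.0, 0)
        assert wp.n_windows == expected

    def test_single_window_aggregators_coincide(self):
        excerpt = np.zeros((2, 3 * 125))
        wp = sliding_window_scores(uniform_predict, excerpt, 125.0, 0)
        assert (
            aggregate_mean(wp).predicted_class
            == aggregate_max(wp).predicted_class
            == aggregate_majority(wp).predicted_class
        )

    def test_excerpt_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_scores(uniform_predict, np.zeros((2, 100)), 125.0, 0)


class TestAggregationWorkedExample:
    def test_per_window_argmaxes(self):
        wp = worked_example_scores()
        np.testing.assert_array_equal(np.argmax(wp.scores, axis=1), [8, 0, 7])

    def test_majority_tie_broken_by_earliest_window(self):
        assert aggregate_majority(worked_example_scores()).predicted_class == 8

    def test_max_recovers_true_label(self):
        res = aggregate_max(worked_example_scores())
        assert res.predicted_class == 7
        assert res.per_class_evidence[7] == 9.93e-1

    def test_mean_prefers_class_eight(self):
        res = aggregate_mean(worked_example_scores())
        assert res.predicted_class == 8
        assert res.per_class_evidence.sum() == pytest.approx(1.0, abs=0.005)


class TestAggregationGeneral:
    def test_strict_majority(self):
        scores = np.zeros((3, 5))
        scores[0, 3] = scores[1, 3] = scores[2, 1] = 1.0
        scores += 1e-9
        scores /= scores.sum(axis=1, keepdims=True)
        assert aggregate_majority(WindowPredictions(scores, 3)).predicted_class == 3

    def test_single_window_majority_is_argmax(self, rng):
        row = rng.dirichlet(np.ones(6))[None, :]
        wp = WindowPredictions(row, 0)
        assert aggregate_majority(wp).predicted_class == int(np.argmax(row))

    def test_max_equals_global_argmax_brute_force(self, rng):
        for _ in range(25):
            scores = rng.dirichlet(np.ones(7), size=4)
            wp = WindowPredictions(scores, 0)
            best, best_class = -1.0, -1
            for i in range(scores.shape[0]):
                for j in range(scores.shape[1]):
                    if scores[i, j] > best:
                        best, best_class = scores[i, j], j
            assert aggregate_max(wp).predicted_class == best_class

    def test_mean_invariant_to_window_order(self, rng):
        scores = rng.dirichlet(np.ones(5), size=6)
        wp = WindowPredictions(scores, 0)
        wp_perm = WindowPredictions(scores[::-1], 0)
        assert (
            aggregate_mean(wp).predicted_class
            == aggregate_mean(wp_perm).predicted_class
        )

    def test_predictions_always_in_class_range(self, rng):
        for _ in range(20):
            scores = rng.dirichlet(np.ones(4), size=3)
            wp = WindowPredictions(scores, 0)
            for agg in (aggregate_mean, aggregate_max, aggregate_majority):
                assert 0 <= agg(wp).predicted_class < 4


def exact_binomial_p(n01, n10):
    n = n01 + n10
    k = min(n01, n10)
    tail = sum(comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


class TestMcNemar:
    def test_identical_arrays_give_p_one(self):
        res = mcnemar_test([1, 0, 1, 1], [1, 0, 1, 1])
        assert res.p_value == 1.0
        assert res.n_01 == res.n_10 == 0

    def test_known_discordant_counts(self):
        a = [0] * 5 + [1] + [1] * 10
        b = [1] * 5 + [0] + [1] * 10
        res = mcnemar_test(a, b)
        assert (res.n_01, res.n_10) == (5, 1)
        assert res.p_value == pytest.approx(0.21875, abs=1e-12)

    def test_symmetric_under_model_swap(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert mcnemar_test(a, b).p_value == pytest.approx(
            mcnemar_test(b, a).p_value, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_binomial_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        res = mcnemar_test(a, b, method="exact")
        if res.n_01 + res.n_10 <= 20:
            assert res.p_value == pytest.approx(
                exact_binomial_p(res.n_01, res.n_10), abs=1e-12
            )

    def test_chi2_with_continuity_correction(self):
        a = np.concatenate([np.zeros(20), np.ones(30)]).astype(int)
        b = np.concatenate([np.ones(20), np.zeros(5), np.ones(25)]).astype(int)
        res = mcnemar_test(a, b, method="chi2")
        expected_stat = (abs(res.n_01 - res.n_10) - 1) ** 2 / (res.n_01 + res.n_10)
        assert res.statistic == pytest.approx(expected_stat)
        assert 0 < res.p_value <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test([1, 0], [1])


class TestChanceLevel:
    @pytest.mark.parametrize("k,expected", [(10, 0.1), (1, 1.0), (4, 0.25)])
    def test_reciprocal(self, k, expected):
        assert chance_level(k) == expected


class TestAccuracyReport:
    def records(self, rng, n=400, n_classes=10, perfect=False):
        out = []
        for i in range(n):
            true = int(rng.integers(0, n_classes))
            pred = true if perfect else int(rng.integers(0, n_classes))
            out.append({"predicted": pred, "true": true,
                        "song": true, "subject": i % 4})
        return out

    def test_all_correct_gives_ones(self, rng):
        rep = accuracy_report(self.records(rng, perfect=True))
        assert rep.overall == 1.0
        assert all(v == 1.0 for v in rep.by_song.values())
        assert all(v == 1.0 for v in rep.by_subject.values())

    def test_partition_identity(self, rng):
        recs = self.records(rng)
        rep = accuracy_report(recs)
        counts = {}
        for r in recs:
            counts[r["song"]] = counts.get(r["song"], 0) + 1
        weighted = sum(rep.by_song[s] * c for s, c in counts.items()) / len(recs)
        assert weighted == pytest.approx(rep.overall, abs=1e-12)

    def test_random_predictions_near_chance(self, rng):
        rep = accuracy_report(self.records(rng, n=4000))
        assert rep.overall == pytest.approx(chance_level(10), abs=0.03)

    def test_missing_metadata_rejected(self):
        with pytest.raises(ValueError):
            accuracy_report([{"predicted": 1, "true": 1}])
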