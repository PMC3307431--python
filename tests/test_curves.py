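"""Batch schedules, the four samplers, and learning-curve construction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lcextrap import (
    LabeledDataset,
    SamplingRun,
    batch_schedule,
    build_learning_curve,
)
from lcextrap.curves import (
    UntrainedModelError,
    _cosine_dist_matrix,
    combined_sampler,
    distance_sampler,
    diversity_sampler,
    random_sampler,
)


class TestBatchSchedule:
    @pytest.mark.parametrize(
        "k, m0, n, expected",
        [
            (16, 16, 3, [16, 32, 48]),
            (4, 4, 5, [4, 8, 12, 16, 20]),
        ],
    )
    def test_known_schedules(self, k, m0, n, expected):
        assert batch_schedule(k, n, m0).tolist() == expected

    def test_62nd_element_is_992(self):
        assert batch_schedule(16, 62, 16)[-1] == 992

    def test_m0_offset(self):
        sched = batch_schedule(16, 4, 8)
        assert sched.tolist() == [8, 24, 40, 56]
        # x_j = m0 + (j - 1) * k
        j = np.arange(1, 5)
        assert np.array_equal(sched, 8 + (j - 1) * 16)


class TestRandomSampler:
    def test_deterministic_under_seed(self):
        pool = np.arange(50)
        s1 = random_sampler(pool, 10, np.random.default_rng(4))
        s2 = random_sampler(pool, 10, np.random.default_rng(4))
        assert np.array_equal(s1, s2)

    def test_whole_pool(self):
        pool = np.arange(7)
        sel = random_sampler(pool, 7, np.random.default_rng(0))
        assert sorted(sel) == list(pool)

    def test_uniformity_chi2(self):
        """Selection frequencies over 10,000 seeded draws are uniform."""
        pool = np.arange(8)
        rng = np.random.default_rng(12)
        counts = np.zeros(8)
        for _ in range(10_000):
            counts[random_sampler(pool, 1, rng)[0]] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_oversized_request(self):
        with pytest.raises(ValueError):
            random_sampler(np.arange(3), 5, np.random.default_rng(0))


class TestDistanceSampler:
    def test_selects_nearest_to_margin(self):
        cand = np.arange(4)
        decisions = np.array([-3.0, -0.1, 0.2, 5.0])
        sel = distance_sampler(cand, decisions, 2)
        assert sorted(sel) == [1, 2]

    def test_whole_pool(self):
        cand = np.arange(4)
        sel = distance_sampler(cand, np.array([1.0, -2, 3, 0.5]), 4)
        assert sorted(sel) == [0, 1, 2, 3]

    def test_duplicates_at_margin_selected_first(self):
        decisions = np.array([0.05, 2.0, 0.05, 1.0])
        sel = distance_sampler(np.arange(4), decisions, 2)
        assert sorted(sel) == [0, 2]

    def test_untrained_model_error(self):
        with pytest.raises(UntrainedModelError):
            distance_sampler(np.arange(3), None, 1)


class TestDiversitySampler:
    def test_picks_orthogonal_candidate(self):
        X_train = np.array([[1.0, 0.0]])
        X_cand = np.array([[1.0, 0.01], [0.0, 1.0]])
        sel = diversity_sampler(np.arange(2), X_cand, X_train, 1)
        assert sel.tolist() == [1]

    def test_duplicates_fall_back_to_index_order(self):
        X_train = np.array([[1.0, 1.0]])
        X_cand = np.array([[2.0, 2.0], [3.0, 3.0]])  # same direction as train
        sel = diversity_sampler(np.arange(2), X_cand, X_train, 1)
        assert sel.tolist() == [0]

    def test_greedy_matches_exhaustive_max_min(self):
        """k=2 of 3 candidates agrees with exhaustive subset search."""
        rng = np.random.default_rng(21)
        for _ in range(20):
            X_train = rng.normal(size=(2, 4))
            X_cand = rng.normal(size=(3, 4))
            sel = set(diversity_sampler(np.arange(3), X_cand, X_train, 2).tolist())
            best_obj, best_set = -1.0, None
            for subset in itertools.combinations(range(3), 2):
                pts = X_cand[list(subset)]
                d_train = _cosine_dist_matrix(pts, X_train).min()
                d_within = _cosine_dist_matrix(pts, pts)
                d_pair = d_within[0, 1]
                obj = min(d_train, d_pair)
                if obj > best_obj + 1e-12:
                    best_obj, best_set = obj, set(subset)
            # greedy is optimal here or within a hair of the optimum
            pts = X_cand[sorted(sel)]
            obj_greedy = min(
                _cosine_dist_matrix(pts, X_train).min(),
                _cosine_dist_matrix(pts, pts)[0, 1],
            )
            assert obj_greedy >= best_obj - 0.15

    def test_zero_vector_warns(self):
        X_train = np.array([[1.0, 0.0]])
        X_cand = np.array([[0.0, 0.0], [0.0, 1.0]])
        with pytest.warns(RuntimeWarning):
            diversity_sampler(np.arange(2), X_cand, X_train, 1)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            diversity_sampler(np.arange(2), np.eye(2), np.empty((0, 2)), 1)


class TestCombinedSampler:
    def test_diverse_near_margin_point_included(self):
        # five near-margin duplicates of the training direction plus one
        # near-margin diverse point; k=2 must include the diverse one
        X_train = np.array([[1.0, 0.0]])
        X_cand = np.vstack([np.tile([1.0, 0.001], (5, 1)), [[0.0, 1.0]]])
        decisions = np.array([0.01, 0.011, 0.012, 0.013, 0.014, 0.02])
        sel = combined_sampler(np.arange(6), X_cand, decisions, X_train, 2)
        assert 5 in sel

    def test_subset_of_margin_shortlist(self):
        rng = np.random.default_rng(9)
        X_cand = rng.normal(size=(30, 5))
        decisions = rng.normal(size=30)
        X_train = rng.normal(size=(4, 5))
        k = 3
        sel = combined_sampler(np.arange(30), X_cand, decisions, X_train, k)
        shortlist = np.argsort(np.abs(decisions), kind="stable")[: 3 * k]
        assert set(sel).issubset(set(shortlist))

    def test_whole_pool(self):
        rng = np.random.default_rng(2)
        X_cand = rng.normal(size=(4, 3))
        sel = combined_sampler(
            np.arange(4), X_cand, rng.normal(size=4), rng.normal(size=(2, 3)), 4
        )
        assert sorted(sel) == [0, 1, 2, 3]


class TestLabeledDataset:
    def test_pool_test_disjoint(self, blobs_dataset):
        assert not np.intersect1d(
            blobs_dataset.pool_idx, blobs_dataset.test_idx
        ).size

    def test_rejects_overlapping_split(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            LabeledDataset(X, y, np.arange(6), np.arange(5, 10))

    def test_rejects_single_class(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            LabeledDataset(X, np.zeros(10), np.arange(5), np.arange(5, 10))


class TestBuildLearningCurve:
    def test_schedule_exactness_and_improvement(self, blobs_dataset):
        run = SamplingRun(method="RANDOM", initial_size_m0=16,
                          batch_size_k=16, n_repetitions=10, seed=0)
        curve = build_learning_curve(blobs_dataset, run, n_batches=6)
        assert curve.x.tolist() == [16, 32, 48, 64, 80, 96]
        assert curve.y[-1] >= curve.y[0]
        assert curve.batch_size_k == 16
        assert curve.y_spread is not None and len(curve.y_spread) == 6

    def test_deterministic_under_seed(self, blobs_dataset):
        run = SamplingRun(method="DIST", n_repetitions=2, seed=5)
        c1 = build_learning_curve(blobs_dataset, run, n_batches=4)
        c2 = build_learning_curve(blobs_dataset, run, n_batches=4)
        assert np.array_equal(c1.y, c2.y)

    @pytest.mark.parametrize("method", ["RANDOM", "DIST", "DIV", "CMB"])
    def test_all_samplers_produce_valid_curves(self, blobs_dataset, method):
        run = SamplingRun(method=method, n_repetitions=2, seed=1)
        curve = build_learning_curve(blobs_dataset, run, n_batches=4)
        assert len(curve) == 4
        assert np.all((curve.y >= 0) & (curve.y <= 1))

    def test_more_repetitions_smooth_the_curve(self, blobs_dataset):
        """Point-level variability across rebuilds shrinks with averaging."""

        def rebuild_spread(reps):
            finals = [
                build_learning_curve(
                    blobs_dataset,
                    SamplingRun(method="RANDOM", n_repetitions=reps, seed=s),
                    n_batches=3,
                ).y[-1]
                for s in range(6)
            ]
            return np.std(finals)

        assert rebuild_spread(8) <= rebuild_spread(1) + 1e-12

    def test_pool_too_small_rejected(self, blobs_dataset):
        run = SamplingRun(n_repetitions=1)
        with pytest.raises(ValueError):
            build_learning_curve(blobs_dataset, run, n_batches=1000)
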