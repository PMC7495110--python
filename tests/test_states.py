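from itertools import combinations, permutations

import numpy as np
import pytest

from dfcstates.features import DfcFeatureSet, concatenate_cohort
from dfcstates.states import (
    ExemplarSet,
    _local_maxima,
    assign_states,
    correlation_distances,
    davies_bouldin,
    estimate_k,
    fit_states,
    kmeans_correlation,
    ray_turi,
    select_exemplars,
)


def corr_dist(a, b):
    """Scalar correlation-distance oracle."""
    return 1 - np.corrcoef(a, b)[0, 1]


class TestLocalMaxima:
    def test_hand_enumeration(self):
        np.testing.assert_array_equal(_local_maxima(np.array([1, 5, 1, 2, 1.0])), [1, 3])

    def test_monotone_falls_back_to_global_max(self):
        np.testing.assert_array_equal(_local_maxima(np.arange(10.0)), [9])

    def test_single_interior_spike(self):
        v = np.zeros(11)
        v[6] = 3.0
        np.testing.assert_array_equal(_local_maxima(v), [6])

    def test_plateau_leftmost(self):
        np.testing.assert_array_equal(_local_maxima(np.array([1, 5, 5, 5, 1.0])), [1])

    def test_endpoints_excluded(self):
        np.testing.assert_array_equal(_local_maxima(np.array([9, 1, 5, 1, 2.0])), [2])


class TestSelectExemplars:
    def test_indices_interior_and_nonempty(self, small_feature_sets):
        ex = select_exemplars(small_feature_sets)
        for fs in small_feature_sets:
            idx = ex.indices[fs.subject_id]
            assert idx.size >= 1
            assert (idx >= 0).all() and (idx < fs.n_windows).all()
        assert ex.matrix.shape[0] == sum(len(v) for v in ex.indices.values())

    def test_matrix_rows_match_indices(self, small_feature_sets):
        ex = select_exemplars(small_feature_sets)
        fs = small_feature_sets[0]
        n0 = len(ex.indices[fs.subject_id])
        np.testing.assert_array_equal(ex.matrix[:n0], fs.features[ex.indices[fs.subject_id]])


class TestDaviesBouldin:
    def test_hand_worked_euclidean(self):
        # two clusters on a line: {0, 2} around centroid 1, {9, 11} around 10
        data = np.array([[0.0, 0], [2, 0], [9, 0], [11, 0]])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[1.0, 0], [10.0, 0]])
        # S_0 = S_1 = 1, d(c0, c1) = 9 -> DB = (1/2)(2/9 + 2/9) = 2/9
        assert davies_bouldin(data, labels, cents, metric="euclidean") == pytest.approx(2 / 9, abs=1e-10)

    def test_tight_clusters_db_near_zero(self, rng):
        base = np.vstack([rng.normal(size=8), -rng.normal(size=8)])
        data = np.repeat(base, 20, axis=0) + rng.normal(scale=1e-6, size=(40, 8))
        labels = np.repeat([0, 1], 20)
        cents = base
        assert davies_bouldin(data, labels, cents) < 1e-3

    def test_duplication_invariance(self, rng):
        data = rng.normal(size=(20, 5))
        labels = np.array([0, 1] * 10)
        cents = np.vstack([data[labels == j].mean(axis=0) for j in (0, 1)])
        once = davies_bouldin(data, labels, cents, metric="euclidean")
        twice = davies_bouldin(np.vstack([data, data]), np.hstack([labels, labels]), cents, metric="euclidean")
        assert once == pytest.approx(twice, abs=1e-12)

    def test_empty_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            davies_bouldin(rng.normal(size=(5, 3)), np.zeros(5, dtype=int), rng.normal(size=(2, 3)))


class TestRayTuri:
    def test_hand_worked_euclidean(self):
        data = np.array([[0.0, 0], [2, 0], [9, 0], [11, 0]])
        labels = np.array([0, 0, 1, 1])
        cents = np.array([[1.0, 0], [10.0, 0]])
        # mean squared within = 1; min squared centroid separation = 81
        assert ray_turi(data, labels, cents, metric="euclidean") == pytest.approx(1 / 81, abs=1e-10)

    def test_tight_clusters_rt_near_zero(self, rng):
        base = np.vstack([rng.normal(size=8), -rng.normal(size=8)])
        data = np.repeat(base, 20, axis=0) + rng.normal(scale=1e-6, size=(40, 8))
        assert ray_turi(data, np.repeat([0, 1], 20), base) < 1e-6

    def test_shrinking_spread_decreases_rt(self, rng):
        cents = np.array([[0.0, 0], [10.0, 0]])
        offsets = rng.normal(size=(30, 2))
        labels = np.repeat([0, 1], 15)
        far = cents[labels] + offsets
        near = cents[labels] + offsets / 2
        assert ray_turi(near, labels, cents, metric="euclidean") < ray_turi(far, labels, cents, metric="euclidean")


class TestKmeansCorrelation:
    def test_fixed_point_on_exact_centroids(self, rng):
        cents = rng.normal(size=(3, 10))
        data = np.repeat(cents, 5, axis=0)
        model, labels = kmeans_correlation(data, 3, replicates=5, seed=0)
        assert model.inertia == pytest.approx(0, abs=1e-10)
        # all copies of the same row share a label
        assert len({tuple(labels[i * 5 : (i + 1) * 5]) for i in range(3)}) == 3

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(30, 8))
        _, labels_a = kmeans_correlation(data, 3, replicates=5, seed=1)
        scaled = data.copy()
        scaled[7] = 3 * scaled[7] + 7
        _, labels_b = kmeans_correlation(scaled, 3, replicates=5, seed=1)
        np.testing.assert_array_equal(labels_a, labels_b)

    def test_matches_exhaustive_bipartition_oracle(self, rng):
        # n=6, k=2: enumerate all 31 nontrivial bipartitions under the model's
        # centroid contract (mean of standardized member rows)
        data = rng.normal(size=(6, 12))
        model, _ = kmeans_correlation(data, 2, replicates=20, seed=3)

        def standardize(v):
            v = v - v.mean()
            return v / np.linalg.norm(v)

        def cost_of(groups):
            total = 0.0
            for g in groups:
                rows = [standardize(data[i]) for i in g]
                c = standardize(np.mean(rows, axis=0))
                total += sum(1 - row @ c for row in rows)
            return total

        best = min(
            cost_of([g, [i for i in range(6) if i not in g]])
            for r in range(1, 6)
            for g in combinations(range(6), r)
        )
        assert model.inertia == pytest.approx(best, abs=1e-9)

    def test_deterministic(self, rng):
        data = rng.normal(size=(40, 6))
        m1, l1 = kmeans_correlation(data, 3, replicates=5, seed=9)
        m2, l2 = kmeans_correlation(data, 3, replicates=5, seed=9)
        assert m1.inertia == m2.inertia
        np.testing.assert_array_equal(l1, l2)

    def test_replicate_monotonicity(self, rng):
        data = rng.normal(size=(50, 6))
        costs = [kmeans_correlation(data, 4, replicates=r, seed=5)[0].inertia for r in (1, 5, 15)]
        assert costs[0] >= costs[1] >= costs[2]

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_correlation(rng.normal(size=(2, 5)), 3)

    def test_constant_row_rejected(self, rng):
        data = rng.normal(size=(10, 5))
        data[4] = 2.0
        with pytest.raises(ValueError, match="constant"):
            kmeans_correlation(data, 2)


class TestEstimateK:
    def test_two_well_separated_blobs(self, rng):
        a = rng.normal(size=12)
        blob1 = a + rng.normal(scale=0.05, size=(30, 12))
        blob2 = -a + rng.normal(scale=0.05, size=(30, 12))
        ex = ExemplarSet(indices={}, matrix=np.vstack([blob1, blob2]))
        curve = estimate_k(ex, range(2, 7), replicates=5, seed=0)
        assert curve.chosen_k == 2
        assert curve.chosen_k_db == 2

    def test_deterministic(self, rng):
        ex = ExemplarSet(indices={}, matrix=rng.normal(size=(60, 10)))
        c1 = estimate_k(ex, range(2, 6), replicates=3, seed=4)
        c2 = estimate_k(ex, range(2, 6), replicates=3, seed=4)
        assert c1.rt_index == c2.rt_index
        assert c1.db_index == c2.db_index

    def test_k_range_truncated_when_exemplars_scarce(self, rng):
        ex = ExemplarSet(indices={}, matrix=rng.normal(size=(5, 8)))
        curve = estimate_k(ex, range(2, 11), replicates=3, seed=0)
        assert max(curve.k_values) <= 4


class TestAssignStates:
    def _cohort_from_matrix(self, matrix, n_subjects=1):
        per = matrix.shape[0] // n_subjects
        p = matrix.shape[1] // 2
        sets = [
            DfcFeatureSet(
                subject_id=f"S{i}",
                aswc=matrix[i * per : (i + 1) * per, :p],
                derivatives=matrix[i * per : (i + 1) * per, p:],
                zscored=True,
            )
            for i in range(n_subjects)
        ]
        return concatenate_cohort(sets)

    def test_windows_equal_centroids(self, rng):
        from dfcstates.states import StateModel, _standardize_rows

        cents = _standardize_rows(rng.normal(size=(3, 10)))
        model = StateModel(k=3, centroids=cents)
        cohort = self._cohort_from_matrix(np.asarray(cents))
        seqs = assign_states(model, cohort)
        np.testing.assert_array_equal(seqs[0].states, [1, 2, 3])

    def test_permutation_equivariance(self, rng):
        from dfcstates.states import StateModel

        cents = rng.normal(size=(4, 10))
        data = rng.normal(size=(20, 10))
        cohort = self._cohort_from_matrix(data)
        labels = assign_states(StateModel(k=4, centroids=cents), cohort)[0].states
        perm = np.array([2, 3, 0, 1])
        labels_p = assign_states(StateModel(k=4, centroids=cents[perm]), cohort)[0].states
        inverse = np.argsort(perm)
        np.testing.assert_array_equal(labels_p, inverse[labels - 1] + 1)

    def test_matches_distance_oracle(self, rng):
        from dfcstates.states import StateModel

        cents = rng.normal(size=(3, 12))
        data = rng.normal(size=(30, 12))
        cohort = self._cohort_from_matrix(data)
        labels = assign_states(StateModel(k=3, centroids=cents), cohort)[0].states
        d = np.array([[corr_dist(row, c) for c in cents] for row in data])
        np.testing.assert_array_equal(labels, d.argmin(axis=1) + 1)

    def test_dimension_mismatch_rejected(self, rng):
        from dfcstates.states import StateModel

        cohort = self._cohort_from_matrix(rng.normal(size=(10, 8)))
        with pytest.raises(ValueError, match="dimension"):
            assign_states(StateModel(k=2, centroids=rng.normal(size=(2, 6))), cohort)


class TestFitStates:
    def test_occupancy_renumbering(self, small_feature_sets):
        cohort = concatenate_cohort(small_feature_sets)
        model, seqs = fit_states(cohort, 3, replicates=5, seed=2)
        all_states = np.concatenate([s.states for s in seqs])
        counts = np.bincount(all_states, minlength=4)[1:]
        assert (np.diff(counts) <= 0).all(), "state 1 must be the modal state"
        assert model.occupancy_order is not None

    def test_sequence_lengths(self, small_feature_sets):
        cohort = concatenate_cohort(small_feature_sets)
        _, seqs = fit_states(cohort, 3, replicates=5, seed=2)
        assert all(len(s.states) == small_feature_sets[0].n_windows for s in seqs)


class TestEndToEndRecovery:
    def test_hidden_states_recovered(self, small_cohort, small_feature_sets):
        cfg, subjects, truth = small_cohort
        cohort = concatenate_cohort(small_feature_sets)
        model, seqs = fit_states(cohort, cfg.k_true, replicates=10, seed=5)
        span = 3 + 22 + 25 - 3  # volumes spanned by one aligned window post-discard
        pred, true = [], []
        for tc, seq in zip(subjects, seqs):
            hid = truth.state_sequences[tc.subject_id][3:]
            for w, lab in enumerate(seq.states):
                seg = hid[w : w + span]
                vals, cnts = np.unique(seg, return_counts=True)
                if cnts.max() == len(seg):  # exclude windows spanning a transition
                    pred.append(lab)
                    true.append(vals[0])
        pred, true = np.array(pred), np.array(true)
        assert len(pred) > 50
        best = max(
            np.mean(np.array([p[x - 1] for x in pred]) == true)
            for p in permutations(range(1, cfg.k_true + 1))
        )
        assert best > 0.8


class TestEstimateKConsistency:
    def test_mode_over_20_seeds_is_k_true(self):
        # reduced scale: 12 subjects, 20 components, 180 volumes, k_true = 3
        from dfcstates import prep
        from dfcstates.features import aswc_and_derivatives, sliding_window_correlations, zscore_feature_blocks
        from dfcstates.synthetic import SyntheticCohortConfig, simulate_cohort

        chosen = []
        for seed in range(20):
            cfg = SyntheticCohortConfig(
                n_per_group=6, n_components=20, n_volumes=180, k_true=3,
                separation=0.9, mean_dwell_target=35, noise_sd=0.3, seed=100 + seed,
            )
            subjects, _ = simulate_cohort(cfg)
            sets = []
            for tc in subjects:
                clean = prep.preprocess(tc)
                sets.append(zscore_feature_blocks(aswc_and_derivatives(sliding_window_correlations(clean))))
            ex = select_exemplars(sets)
            chosen.append(estimate_k(ex, range(2, 8), replicates=5, seed=seed).chosen_k)
        mode = max(set(chosen), key=chosen.count)
        assert mode == 3


class TestSpreadInit:
    def test_spread_init_valid_and_deterministic(self, rng):
        data = rng.normal(size=(50, 8))
        m1, l1 = kmeans_correlation(data, 3, replicates=5, seed=2, init="spread")
        m2, l2 = kmeans_correlation(data, 3, replicates=5, seed=2, init="spread")
        assert m1.inertia == m2.inertia
        np.testing.assert_array_equal(l1, l2)
        assert np.isfinite(m1.inertia)
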