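"""L1 k-means state estimation, cluster-number diagnostics, dwell times,
reliability filtering and subject state medoids."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import dfcstates as d
from dfcstates.clustering import estimate_mean_dwell, run_lengths, upper_vec

from conftest import series_from_vectors


def brute_force_l1_kmeans(X, k):
    """Exhaustive search over all label assignments (oracle for tiny n):
    optimal total L1 cost with element-wise-median centroids."""
    n = X.shape[0]
    best_cost, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(set(labels.tolist())) < k:
            continue
        cost = 0.0
        for j in range(k):
            members = X[labels == j]
            med = np.median(members, axis=0)
            cost += np.abs(members - med).sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_cost, best_labels


class TestClusterStates:
    def test_two_groups_of_identical_matrices_separate_perfectly(self, rng):
        a = rng.uniform(-0.5, 0.5, size=6)
        b = a + 2.0
        s1 = series_from_vectors(np.tile(a, (4, 1)), 4, "s1")
        s2 = series_from_vectors(np.tile(b, (4, 1)), 4, "s2")
        model = d.cluster_states([s1, s2], k=2, n_replicates=5, seed=0)
        assert model.total_l1_cost == pytest.approx(0.0, abs=1e-12)
        assert len(set(model.assignments["s1"])) == 1
        assert len(set(model.assignments["s2"])) == 1
        assert model.assignments["s1"][0] != model.assignments["s2"][0]

    def test_matches_exhaustive_partition_search(self, rng):
        # two well-separated triplets in 5 dimensions
        X = np.vstack(
            [
                rng.normal(0.0, 0.05, size=(3, 6)),
                rng.normal(1.5, 0.05, size=(3, 6)),
            ]
        )
        series = series_from_vectors(X, 4, "s")
        model = d.cluster_states([series], k=2, n_replicates=10, seed=1)
        oracle_cost, oracle_labels = brute_force_l1_kmeans(X, 2)
        assert model.total_l1_cost == pytest.approx(oracle_cost, abs=1e-10)
        got = np.asarray(model.assignments["s"])
        same = (got[:, None] == got[None, :])
        expect = (oracle_labels[:, None] == oracle_labels[None, :])
        np.testing.assert_array_equal(same, expect)

    def test_recovers_latent_states_on_synthetic_data(self, small_three_state_dataset):
        _, series, truth = small_three_state_dataset
        model = d.cluster_states(series, k=3, n_replicates=10, seed=2)
        true_labels = np.concatenate(
            [
                d.window_truth_labels(truth.state_sequences[s.subject_id], 22)
                for s in series
            ]
        )
        # 12-region states share most edges, so separation is much
        # weaker than at full scale; this is a smoke-level recovery bound
        ari = adjusted_rand_score(true_labels, model.pooled_labels())
        assert ari > 0.7

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((12, 6))
        series = series_from_vectors(X, 4, "s")
        m1 = d.cluster_states([series], 3, n_replicates=4, seed=7)
        m2 = d.cluster_states([series], 3, n_replicates=4, seed=7)
        np.testing.assert_array_equal(m1.assignments["s"], m2.assignments["s"])
        np.testing.assert_array_equal(m1.centroids, m2.centroids)

    def test_best_of_many_not_worse_than_single_replicate(self, rng):
        X = rng.standard_normal((40, 10))
        series = series_from_vectors(X, 5, "s")
        c_many = d.cluster_states([series], 4, n_replicates=20, seed=3).total_l1_cost
        c_one = d.cluster_states([series], 4, n_replicates=1, seed=3).total_l1_cost
        assert c_many <= c_one + 1e-12

    def test_partition_invariant_to_subject_order(self, rng):
        a = rng.normal(0, 0.05, size=(6, 6))
        b = rng.normal(3, 0.05, size=(6, 6))
        s1 = series_from_vectors(a, 4, "s1")
        s2 = series_from_vectors(b, 4, "s2")
        m_fwd = d.cluster_states([s1, s2], 2, n_replicates=5, seed=4)
        m_rev = d.cluster_states([s2, s1], 2, n_replicates=5, seed=4)
        lab_fwd = np.concatenate([m_fwd.assignments["s1"], m_fwd.assignments["s2"]])
        lab_rev = np.concatenate([m_rev.assignments["s1"], m_rev.assignments["s2"]])
        assert adjusted_rand_score(lab_fwd, lab_rev) == pytest.approx(1.0)

    def test_k_bounds(self, rng):
        series = series_from_vectors(rng.standard_normal((3, 6)), 4, "s")
        with pytest.raises(ValueError):
            d.cluster_states([series], 1)
        with pytest.raises(ValueError):
            d.cluster_states([series], 5)

    def test_mean_update_variant_runs(self, rng):
        series = series_from_vectors(rng.standard_normal((10, 6)), 4, "s")
        model = d.cluster_states(
            [series], 2, n_replicates=3, seed=0, centroid_update="mean"
        )
        assert model.k == 2


class TestDiagnostics:
    def test_calinski_harabasz_peaks_at_true_k(self, rng):
        centers = np.array([[0.0] * 6, [2.5] * 6, [-2.5] * 6])
        X = np.vstack([c + rng.normal(0, 0.1, size=(8, 6)) for c in centers])
        series = series_from_vectors(X, 4, "s")
        table = d.cluster_number_diagnostics(
            [series], range(2, 6), seed=0, n_replicates=5, n_reference=5
        )
        best_k = int(table.loc[table["calinski_harabasz"].idxmax(), "k"])
        assert best_k == 3

    def test_elbow_cost_non_increasing(self, rng):
        X = rng.standard_normal((30, 6))
        series = series_from_vectors(X, 4, "s")
        table = d.cluster_number_diagnostics(
            [series], range(2, 6), seed=1, n_replicates=10, n_reference=3
        )
        costs = table["elbow_cost"].to_numpy()
        assert np.all(np.diff(costs) <= 1e-9)

    def test_gap_statistic_finite(self, rng):
        X = rng.standard_normal((20, 6))
        series = series_from_vectors(X, 4, "s")
        table = d.cluster_number_diagnostics(
            [series], range(2, 4), seed=2, n_replicates=3, n_reference=4
        )
        assert np.isfinite(table["gap_statistic"]).all()


class TestDwell:
    def test_hand_enumerated_runs(self):
        rec = d.mean_dwell_time(np.array([1, 1, 1, 2, 2, 1]), 1)
        assert rec.occupancy_windows == 4
        assert rec.mean_dwell_windows == pytest.approx(2.0)

    def test_single_run_covers_everything(self):
        rec = d.mean_dwell_time(np.ones(148, dtype=int), 1)
        assert rec.mean_dwell_windows == pytest.approx(148.0)
        assert rec.occupancy_windows == 148

    def test_absent_state(self):
        rec = d.mean_dwell_time(np.array([1, 2, 1]), 3)
        assert rec.mean_dwell_windows is None
        assert rec.occupancy_windows == 0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            d.mean_dwell_time(np.array([]), 1)

    @given(
        st.lists(st.integers(min_value=1, max_value=3), min_size=1, max_size=60)
    )
    @settings(max_examples=50, deadline=None)
    def test_occupancy_and_run_identities(self, labels):
        labels = np.array(labels)
        total_occ = 0
        for state in (1, 2, 3):
            rec = d.mean_dwell_time(labels, state)
            runs = run_lengths(labels, state)
            total_occ += rec.occupancy_windows
            if runs:
                # n_runs * MDT == occupancy
                assert len(runs) * rec.mean_dwell_windows == pytest.approx(
                    rec.occupancy_windows
                )
        assert total_occ == labels.size

    def test_censoring_aware_estimator(self):
        # two completed exits, one censored tail run: 8 occupied / 2 exits
        labels = np.array([1, 1, 2, 1, 1, 1, 2, 1, 1, 1])
        assert estimate_mean_dwell(labels, 1) == pytest.approx(8 / 2)
        assert estimate_mean_dwell(labels, 3) is None
        assert estimate_mean_dwell(np.array([2, 2]), 2) == 2.0  # never exits


class TestReliability:
    def _model(self, labels_by_subject, k):
        return d.StateModel(
            k=k,
            centroids=np.zeros((k, 3, 3)),
            assignments={s: np.asarray(v) for s, v in labels_by_subject.items()},
            total_l1_cost=0.0,
            replicate_seed=0,
            n_replicates=1,
        )

    def test_state_under_ten_windows_in_one_group_unreliable(self):
        model = self._model(
            {"a": np.r_[np.ones(9, int), np.full(491, 2)], "b": np.full(500, 2)}, 2
        )
        rel = d.reliability_filter(model, {"a": "case", "b": "control"})
        assert d.reliable_state_ids(rel) == [2]
        flags = {(r.state_id, r.group): r.reliable for r in rel}
        assert flags[(1, "case")] is False  # 9 windows
        assert flags[(2, "case")] is True

    def test_exactly_ten_in_both_groups_is_reliable(self):
        model = self._model(
            {"a": np.r_[np.ones(10, int), np.full(5, 2)],
             "b": np.r_[np.ones(10, int), np.full(15, 2)]},
            2,
        )
        rel = d.reliability_filter(model, {"a": "case", "b": "control"})
        assert 1 in d.reliable_state_ids(rel)

    def test_balanced_synthetic_states_all_reliable(self, small_three_state_dataset):
        _, series, truth = small_three_state_dataset
        model = d.cluster_states(series, k=2, n_replicates=5, seed=9)
        rel = d.reliability_filter(model, truth.subject_group)
        assert d.reliable_state_ids(rel) == [1, 2]


class TestMedoid:
    def test_single_window_returned_as_is(self, rng):
        series = series_from_vectors(rng.standard_normal((3, 6)), 4, "s")
        labels = np.array([1, 2, 2])
        med = d.subject_state_medoid(series, labels, 1)
        np.testing.assert_array_equal(med, series.matrices[0])

    def test_elementwise_middle_matrix_wins(self):
        vectors = np.array([[0.0] * 6, [1.0] * 6, [2.0] * 6])
        series = series_from_vectors(vectors, 4, "s")
        med = d.subject_state_medoid(series, np.array([1, 1, 1]), 1)
        np.testing.assert_array_equal(med, series.matrices[1])

    def test_matches_bruteforce_pairwise_l1(self, rng):
        vectors = rng.standard_normal((7, 10))
        series = series_from_vectors(vectors, 5, "s")
        med = d.subject_state_medoid(series, np.ones(7, int), 1)
        sums = [
            sum(np.abs(vectors[i] - vectors[j]).sum() for j in range(7))
            for i in range(7)
        ]
        expected = series.matrices[int(np.argmin(sums))]
        np.testing.assert_array_equal(med, expected)

    def test_invariant_to_window_order(self, rng):
        vectors = rng.standard_normal((5, 6))
        series = series_from_vectors(vectors, 4, "s")
        med1 = d.subject_state_medoid(series, np.ones(5, int), 1)
        perm = np.array([3, 1, 4, 0, 2])
        series_p = series_from_vectors(vectors[perm], 4, "s")
        med2 = d.subject_state_medoid(series_p, np.ones(5, int), 1)
        np.testing.assert_array_equal(med1, med2)

    def test_absent_state_errors(self, rng):
        series = series_from_vectors(rng.standard_normal((3, 6)), 4, "s")
        with pytest.raises(ValueError):
            d.subject_state_medoid(series, np.ones(3, int), 2)


def test_upper_vec_roundtrip(rng):
    from dfcstates.clustering import vec_to_matrix

    v = rng.standard_normal(6)
    m = vec_to_matrix(v, 4)
    np.testing.assert_array_equal(upper_vec(m), v)
    assert np.all(np.diag(m) == 1.0)
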