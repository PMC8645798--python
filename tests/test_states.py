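"""Correlation-distance k-means, state assignment, dwell metrics, occurrence."""

import itertools

import numpy as np
import pytest

import dfnckit as dk
from dfnckit.states import ClusteringConfig, _normalize_rows, dwell_metrics


def _brute_force_dwell(seq, k):
    """Independent run-length oracle: explicit scan."""
    runs = []
    start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[i - 1]:
            runs.append((seq[start], i - start))
            start = i
    mdt = np.zeros(k)
    for s in range(1, k + 1):
        lens = [l for st, l in runs if st == s]
        if lens:
            mdt[s - 1] = np.mean(lens)
    occ = np.array([(np.asarray(seq) == s).mean() for s in range(1, k + 1)])
    return mdt, len(runs) - 1, occ


class TestKMeansCorrelation:
    def test_exact_copies_recovered_with_zero_inertia(self, rng):
        patterns = rng.normal(size=(5, 30))
        X = np.repeat(patterns, 20, axis=0)
        part = dk.kmeans_correlation(X, ClusteringConfig(k=5, n_init=20, seed=0))
        assert part.inertia == pytest.approx(0.0, abs=1e-9)
        # each pattern maps to exactly one recovered state
        labels = part.labels.reshape(5, 20)
        assert all(len(set(row)) == 1 for row in labels)
        assert len({row[0] for row in labels}) == 5

    def test_two_group_partition_matches_brute_force(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=30), rng.normal(size=30)
        X = np.vstack([a + 0.1 * rng.normal(size=(6, 30)),
                       b + 0.1 * rng.normal(size=(6, 30))])
        part = dk.kmeans_correlation(X, ClusteringConfig(k=2, n_init=50, seed=1))

        Xn = _normalize_rows(X)

        def inertia_of(assign):
            tot = 0.0
            for g in (0, 1):
                members = Xn[np.array(assign) == g]
                if len(members) == 0:
                    return np.inf
                m = members.mean(axis=0)
                m = m - m.mean()
                n = np.linalg.norm(m)
                if n == 0:
                    return np.inf
                tot += np.sum(1 - members @ (m / n))
            return tot

        best = min(
            (inertia_of(assign) for assign in itertools.product([0, 1], repeat=12)),
        )
        assert part.inertia == pytest.approx(best, abs=1e-8)

    def test_objective_nonincreasing_over_iterations(self, rng):
        X = rng.normal(size=(200, 20))
        part = dk.kmeans_correlation(X, ClusteringConfig(k=4, n_init=5, seed=3))
        trace = part.inertia_trace
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_states_ordered_by_descending_occupancy(self, rng):
        patterns = rng.normal(size=(3, 40))
        X = np.vstack([np.repeat(patterns[[0]], 50, axis=0),
                       np.repeat(patterns[[1]], 30, axis=0),
                       np.repeat(patterns[[2]], 20, axis=0)])
        X = X + 0.01 * rng.normal(size=X.shape)
        part = dk.kmeans_correlation(X, ClusteringConfig(k=3, n_init=20, seed=0))
        assert np.all(np.diff(part.occupancy_global) <= 0)
        assert part.occupancy_global.sum() == pytest.approx(1.0)

    def test_label_permutation_equivariance(self, rng):
        patterns = rng.normal(size=(4, 25))
        X = np.repeat(patterns, 15, axis=0) + 0.05 * rng.normal(size=(60, 25))
        p1 = dk.kmeans_correlation(X, ClusteringConfig(k=4, n_init=30, seed=2))
        perm = rng.permutation(60)
        p2 = dk.kmeans_correlation(X[perm], ClusteringConfig(k=4, n_init=30, seed=5))
        assert p1.inertia == pytest.approx(p2.inertia, abs=1e-6)
        # centroids match up to relabeling (greedy by correlation)
        cc = np.corrcoef(np.vstack([p1.centroids, p2.centroids]))[:4, 4:]
        assert np.sort(cc.max(axis=1))[0] > 0.999

    def test_exemplar_init_recovers_same_structure(self, rng):
        patterns = rng.normal(size=(3, 40))
        X = np.repeat(patterns, 30, axis=0) + 0.05 * rng.normal(size=(90, 40))
        slices = [(f"s{i}", slice(30 * i, 30 * (i + 1))) for i in range(3)]
        full = dk.kmeans_correlation(X, ClusteringConfig(k=3, n_init=20, seed=0))
        two_stage = dk.kmeans_correlation(
            X, ClusteringConfig(k=3, n_init=20, seed=0),
            session_slices=slices, exemplar_init=True,
        )
        cc = np.corrcoef(np.vstack([full.centroids, two_stage.centroids]))[:3, 3:]
        assert np.sort(cc.max(axis=1))[0] > 0.99
        with pytest.raises(ValueError, match="session_slices"):
            dk.kmeans_correlation(X, ClusteringConfig(k=3, n_init=5), exemplar_init=True)

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(ValueError):
            dk.kmeans_correlation(rng.normal(size=(3, 10)), ClusteringConfig(k=5, n_init=1))

    def test_constant_rows_filtered_with_warning(self, rng):
        X = rng.normal(size=(30, 10))
        X[4] = 2.5
        with pytest.warns(UserWarning, match="constant"):
            part = dk.kmeans_correlation(X, ClusteringConfig(k=2, n_init=5, seed=0))
        assert len(part.labels) == 30


class TestAssignToStates:
    def test_centroid_window_assigned_to_itself(self, rng):
        cents = rng.normal(size=(3, 12))
        lab = dk.assign_to_states(cents[1][None, :], cents)
        assert lab[0] == 2

    def test_tie_breaks_toward_lower_label(self):
        c = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0]])
        cents = np.vstack([c[0], c[0]])  # states 1 and 2 identical
        lab = dk.assign_to_states(np.array([[2.0, 0.0, -2.0]]), cents)
        assert lab[0] == 1

    def test_matches_brute_force_argmin(self, rng):
        X = rng.normal(size=(40, 15))
        cents = rng.normal(size=(4, 15))
        lab = dk.assign_to_states(X, cents)
        for i in range(40):
            d = [1 - np.corrcoef(X[i], c)[0, 1] for c in cents]
            assert lab[i] == int(np.argmin(d)) + 1

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            dk.assign_to_states(rng.normal(size=(5, 10)), rng.normal(size=(3, 12)))


class TestDwellMetrics:
    def test_hand_example(self):
        m = dwell_metrics([1, 1, 1, 2, 2, 1], 2)
        assert np.allclose(m.mdt, [2.0, 2.0])
        assert m.nt == 2
        assert np.allclose(m.occupancy, [2 / 3, 1 / 3])

    def test_constant_sequence(self):
        m = dwell_metrics(np.ones(171, dtype=int), 2)
        assert m.mdt[0] == 171 and m.nt == 0
        assert not m.visited[1] and m.mdt[1] == 0

    def test_alternating_sequence(self):
        m = dwell_metrics(np.tile([1, 2], 5), 2)
        assert np.allclose(m.mdt, [1.0, 1.0])
        assert m.nt == 9

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            seq = rng.integers(1, k + 1, size=int(rng.integers(1, 60)))
            m = dwell_metrics(seq, k)
            mdt, nt, occ = _brute_force_dwell(list(seq), k)
            assert np.allclose(m.mdt, mdt)
            assert m.nt == nt
            assert np.allclose(m.occupancy, occ)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            dwell_metrics([1, 2, 3], 2)
        with pytest.raises(ValueError):
            dwell_metrics([], 2)


class TestOccurrenceProfile:
    def test_constant_state_one(self):
        assigns = {f"s{i}": np.ones(20, dtype=int) for i in range(4)}
        subj = {f"s{i}": f"sub{i}" for i in range(4)}
        prof = dk.occurrence_profile(assigns, subj, k=3, n_boot=0)
        assert np.all(prof.freq[0] == 1.0)
        assert np.all(prof.freq[1:] == 0.0)

    def test_columns_sum_to_one(self, rng):
        assigns = {f"s{i}": rng.integers(1, 4, 30) for i in range(6)}
        subj = {f"s{i}": f"sub{i // 2}" for i in range(6)}
        prof = dk.occurrence_profile(assigns, subj, k=3, n_boot=10, seed=0)
        assert np.allclose(prof.freq.sum(axis=0), 1.0)
        assert prof.lo.shape == prof.freq.shape
        assert np.all(prof.lo <= prof.hi)

    def test_no_bootstrap_gives_point_estimates_only(self, rng):
        assigns = {"a": rng.integers(1, 3, 10)}
        prof = dk.occurrence_profile(assigns, {"a": "sub0"}, k=2, n_boot=0)
        assert prof.lo is None and prof.n_boot == 0

    def test_bootstrap_deterministic_under_seed(self, rng):
        assigns = {f"s{i}": rng.integers(1, 4, 15) for i in range(5)}
        subj = {f"s{i}": f"sub{i}" for i in range(5)}
        p1 = dk.occurrence_profile(assigns, subj, k=3, n_boot=20, seed=9)
        p2 = dk.occurrence_profile(assigns, subj, k=3, n_boot=20, seed=9)
        assert np.array_equal(p1.lo, p2.lo) and np.array_equal(p1.hi, p2.hi)
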