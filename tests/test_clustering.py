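"""Two-phase clustering: k-means oracle equivalence, criterion correctness,
profile arithmetic, hierarchical cuts, concordance matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    silhouette_samples,
)

from sbpatterns.clustering import (
    DayClusterModel,
    calinski_harabasz,
    concordance,
    hier_cluster,
    kml_fit,
    profiles_from_assignments,
    select_k_phase1,
    silhouette,
)


def embed(values_1d):
    """Embed scalar points as 14-dim trajectories (first coordinate)."""
    X = np.zeros((len(values_1d), 14))
    X[:, 0] = values_1d
    return X


def brute_force_best_sse_partition(X, k):
    """Exhaustive minimum-SSE partition over all label assignments."""
    n = X.shape[0]
    best = None
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        labels = np.array(labels)
        sse = sum(
            float(np.sum((X[labels == c] - X[labels == c].mean(axis=0)) ** 2))
            for c in range(k)
        )
        if best is None or sse < best[0] - 1e-12:
            best = (sse, labels)
    return best


def brute_force_ch(X, labels):
    """Independent Calinski-Harabasz evaluation by explicit loops."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    clusters = sorted(set(labels.tolist()))
    k = len(clusters)
    grand = X.mean(axis=0)
    B = W = 0.0
    for c in clusters:
        pts = X[labels == c]
        cen = pts.mean(axis=0)
        B += len(pts) * np.dot(cen - grand, cen - grand)
        for p in pts:
            W += np.dot(p - cen, p - cen)
    return (B / (k - 1)) / (W / (n - k))


def brute_force_silhouette(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = len(X)
    widths = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths[i] = 0.0
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels.tolist())
            if c != labels[i]
        )
        widths[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return widths


def brute_force_complete_linkage_heights(X):
    """Naive agglomerative complete linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(X))]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestKmlFit:
    def test_recovers_noiseless_archetypes_exactly(self):
        curves = np.array(
            [[50.0] * 14, [20.0] * 14, np.linspace(20, 55, 14), np.linspace(55, 20, 14)]
        )
        truth = np.repeat(np.arange(4), 25)
        X = curves[truth]
        model = kml_fit(X, k=4, seed=0)
        assert adjusted_rand_score(truth, model.assignments) == 1.0
        recovered = {tuple(c) for c in model.centroids.round(9)}
        assert recovered == {tuple(c) for c in curves.round(9)}

    def test_matches_exhaustive_best_sse_on_toy_set(self):
        X = embed([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        best_sse, best_labels = brute_force_best_sse_partition(X, 2)
        model = kml_fit(X, k=2, seed=1)
        assert model.sse == pytest.approx(best_sse)
        assert adjusted_rand_score(best_labels, model.assignments) == 1.0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 14))
        a = kml_fit(X, k=3, seed=7)
        b = kml_fit(X, k=3, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.restart_scores == b.restart_scores

    def test_sse_descends_monotonically(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 14)) + rng.choice([0, 6], size=(200, 1))
        model = kml_fit(X, k=4, seed=0)
        hist = np.array(model.sse_history)
        assert np.all(np.diff(hist) <= 1e-8)

    def test_ch_value_is_best_restart(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 14))
        model = kml_fit(X, k=3, n_restarts=5, seed=3)
        assert model.ch_value == max(model.restart_scores)

    def test_letters_order_by_centroid_volume(self):
        X = np.vstack([np.full((10, 14), 10.0), np.full((10, 14), 50.0)])
        model = kml_fit(X, k=2, seed=0)
        letters = model.letter_assignments()
        assert set(letters[:10]) == {"B"} and set(letters[10:]) == {"A"}

    def test_k_exceeding_distinct_points_rejected(self):
        X = embed([1.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            kml_fit(X, k=3)


class TestCalinskiHarabasz:
    def test_perfect_separation_returns_inf(self):
        X = embed([0, 0, 5, 5])
        assert calinski_harabasz(X, np.array([0, 0, 1, 1])) == np.inf

    def test_matches_brute_force_and_sklearn(self):
        X = embed([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        ours = calinski_harabasz(X, labels)
        assert ours == pytest.approx(brute_force_ch(X, labels), rel=1e-10)
        assert ours == pytest.approx(calinski_harabasz_score(X, labels), rel=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 14))
        labels = rng.integers(0, 3, 30)
        while len(set(labels)) < 3:
            labels = rng.integers(0, 3, 30)
        assert calinski_harabasz(2 * X, labels) == pytest.approx(
            calinski_harabasz(X, labels), rel=1e-10
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            calinski_harabasz(embed([0, 1, 2]), np.zeros(3, int))

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 14))
        labels = rng.integers(0, 4, 25)
        while len(set(labels)) < 4:
            labels = rng.integers(0, 4, 25)
        assert calinski_harabasz(X, labels) == pytest.approx(
            brute_force_ch(X, labels), rel=1e-10
        )


class TestSelectK:
    def test_recovers_archetype_count_on_clean_data(self):
        rng = np.random.default_rng(7)
        curves = np.array(
            [[50.0] * 14, [22.0] * 14, np.linspace(20, 55, 14), np.linspace(55, 20, 14)]
        )
        truth = rng.integers(0, 4, 400)
        X = curves[truth] + rng.normal(0, 4, (400, 14))
        chosen, diag, models = select_k_phase1(X, seed=0)
        assert chosen == 4
        assert bool(diag["stable"].iloc[0])

    def test_single_cluster_data_flagged_unstable(self):
        rng = np.random.default_rng(8)
        X = np.full((300, 14), 40.0) + rng.normal(0, 5, (300, 14))
        chosen, diag, models = select_k_phase1(X, seed=0)
        assert not bool(diag["stable"].iloc[0])

    def test_diagnostics_row_per_candidate(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 14))
        _, diag, _ = select_k_phase1(X, k_range=[2, 3, 4], seed=0)
        assert diag["k"].tolist() == [2, 3, 4]
        assert {"ch", "aic", "bic", "sse"} <= set(diag.columns)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k_phase1(np.zeros((10, 14)), k_range=[])


class TestProfiles:
    @staticmethod
    def model_with(assignments, k=4):
        assignments = np.asarray(assignments)
        return DayClusterModel(
            k=k,
            centroids=np.arange(k * 14).reshape(k, 14)[::-1].astype(float),
            assignments=assignments,
            ch_value=1.0,
            restart_scores=[1.0],
            labels={i: "ABCD"[i] for i in range(k)},
        )

    def test_degenerate_single_cluster_profile(self):
        model = self.model_with([0] * 7)
        out = profiles_from_assignments(model, ["P0"] * 7)
        assert out.loc[0, ["prop_A", "prop_B", "prop_C", "prop_D"]].tolist() == [1, 0, 0, 0]

    def test_proportion_arithmetic(self):
        model = self.model_with([0, 0, 1, 2])
        out = profiles_from_assignments(model, ["P0"] * 4)
        assert out.loc[0, ["prop_A", "prop_B", "prop_C", "prop_D"]].tolist() == [
            0.5, 0.25, 0.25, 0.0,
        ]

    def test_matches_tally_oracle(self):
        rng = np.random.default_rng(10)
        pids = np.repeat([f"P{i}" for i in range(20)], 6)
        assignments = rng.integers(0, 4, len(pids))
        model = self.model_with(assignments)
        out = profiles_from_assignments(model, pids).set_index("participant_id")
        for pid in set(pids):
            sub = assignments[pids == pid]
            for c in range(4):
                assert out.loc[pid, f"prop_{'ABCD'[c]}"] == pytest.approx(
                    (sub == c).mean()
                )
        sums = out[[c for c in out.columns]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestSilhouette:
    def test_tight_far_clusters_near_one(self):
        X = embed([0, 0.01, 0.02, 100, 100.01, 100.02])
        widths, avg = silhouette(X, np.array([0, 0, 0, 1, 1, 1]))
        assert avg > 0.999

    def test_identical_points_give_zero(self):
        X = np.zeros((6, 14))
        widths, avg = silhouette(X, np.array([0, 0, 0, 1, 1, 1]))
        assert np.all(widths == 0.0) and avg == 0.0

    def test_matches_hand_and_sklearn_on_1d_example(self):
        X = embed([0.0, 1.0, 2.0, 8.0, 9.0, 20.0])
        labels = np.array([0, 0, 0, 1, 1, 2])
        widths, avg = silhouette(X, labels)
        np.testing.assert_allclose(
            widths, brute_force_silhouette(X, labels), rtol=1e-10
        )
        # sklearn shares the singleton-zero convention
        np.testing.assert_allclose(widths, silhouette_samples(X, labels), rtol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 14)), np.zeros(4, int))


class TestHierCluster:
    @staticmethod
    def profile_frame(rows, pids=None):
        rows = np.asarray(rows, float)
        frame = pd.DataFrame(rows, columns=[f"prop_{c}" for c in "ABCD"])
        frame.insert(0, "participant_id", pids or [f"P{i}" for i in range(len(rows))])
        return frame

    def test_separable_simplex_corners(self):
        corners = np.eye(4)
        rows = np.repeat(corners, 5, axis=0)
        out = hier_cluster(self.profile_frame(rows), K_range=range(2, 5))
        assert out.K == 4
        # patterns are numbered by their dominant day-cluster letter
        assert out.patterns.iloc[:5].tolist() == [1] * 5
        assert out.patterns.iloc[-5:].tolist() == [4] * 5
        assert out.dominant_cluster == {1: "A", 2: "B", 3: "C", 4: "D"}

    def test_two_singletons_have_zero_silhouette(self):
        out = hier_cluster(
            self.profile_frame([[1, 0, 0, 0], [0, 0, 0, 1]]), K_range=[2]
        )
        assert out.K == 2
        assert out.avg_silhouette == 0.0

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(11)
        raw = rng.dirichlet(np.ones(4), size=8)
        from scipy.cluster.hierarchy import linkage

        Z = linkage(raw, method="complete")
        np.testing.assert_allclose(
            sorted(Z[:, 2]), brute_force_complete_linkage_heights(raw), rtol=1e-10
        )

    def test_silhouette_tie_prefers_smaller_K(self):
        # two exact corners duplicated: any K splits perfectly; ties -> K=2
        rows = [[1, 0, 0, 0]] * 4 + [[0, 0, 0, 1]] * 4
        out = hier_cluster(self.profile_frame(rows), K_range=range(2, 5))
        assert out.K == 2

    def test_more_K_than_participants_rejected(self):
        with pytest.raises(ValueError):
            hier_cluster(self.profile_frame([[1, 0, 0, 0]] * 3), K_range=range(2, 9))


class TestConcordance:
    def test_identical_assignments(self):
        a = np.array([0, 1, 2, 3, 0, 1])
        assert concordance(a, a)[0] == 100.0

    def test_label_permutation_is_perfect(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        day_pct, part_pct = concordance(a, b, pd.Series(a), pd.Series(b))
        assert day_pct == 100.0 and part_pct == 100.0

    def test_constructed_eighty_percent_agreement(self):
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0] * 4 + [1] + [1] * 4 + [0])
        assert concordance(a, b)[0] == pytest.approx(80.0)

    def test_best_matching_beats_identity_matching(self):
        # optimal matching must consider permutations, confirmed against a
        # brute-force search over label bijections
        rng = np.random.default_rng(12)
        a = rng.integers(0, 3, 30)
        b = (a + 1) % 3
        flip = rng.random(30) < 0.2
        b[flip] = rng.integers(0, 3, flip.sum())
        got = concordance(a, b)[0]
        best = 0.0
        for perm in itertools.permutations(range(3)):
            mapped = np.array([perm[x] for x in b])
            best = max(best, 100.0 * np.mean(mapped == a))
        assert got == pytest.approx(best)

    def test_mismatched_units_rejected(self):
        with pytest.raises(ValueError):
            concordance(np.array([0, 1]), np.array([0, 1, 2]))
        with pytest.raises(ValueError):
            concordance(
                pd.Series([0, 1], index=["a", "b"]),
                pd.Series([0, 1], index=["a", "c"]),
            )
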