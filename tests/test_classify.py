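"""Staging classifier: kernel, normalization, CV machinery, accuracy tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from papca import classify
from papca.io import worked_example_cycles


class TestPoly3Kernel:
    def test_values(self):
        assert classify.poly3_kernel([1.0, 0.0], [0.0, 1.0], 1.0) == 0.0
        assert classify.poly3_kernel([2.0], [1.0], 0.5) == pytest.approx(1.0)
        assert classify.poly3_kernel([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], 1.0) == pytest.approx(27.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            classify.poly3_kernel([1.0, 2.0], [1.0], 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_gram_symmetric_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 4))
        gamma = float(rng.uniform(0.05, 2.0))
        G = classify.poly3_gram(X, gamma=gamma)
        assert np.allclose(G, G.T, atol=1e-10)
        assert np.linalg.eigvalsh(G).min() >= -1e-8
        i, j = rng.integers(0, 8, 2)
        assert G[i, j] == pytest.approx(classify.poly3_kernel(X[i], X[j], gamma), rel=1e-12)


class TestMinMaxNormalize:
    def test_basic_mapping(self):
        train = np.array([[2.0], [4.0], [6.0]])
        scaled, _, _ = classify.minmax_normalize(train, groups=[(0,)])
        assert np.allclose(scaled.ravel(), [0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        train = np.full((4, 1), 3.7)
        scaled, other, _ = classify.minmax_normalize(train, np.array([[9.9]]), groups=[(0,)])
        assert np.all(scaled == 0.0) and np.all(other == 0.0)

    def test_held_out_beyond_max_not_clipped(self):
        train = np.array([[0.0], [1.0]])
        _, other, _ = classify.minmax_normalize(train, np.array([[2.5]]), groups=[(0,)])
        assert other[0, 0] == pytest.approx(2.5)

    def test_groups_share_one_transform(self):
        # slopes (cols 0-2) and midbands (cols 3-5) are scaled per type, so
        # within-type ordering and spacing are preserved
        train = np.array([
            [-2.0, -1.0, 0.0, -40.0, -20.0, 0.0],
            [-1.5, -0.5, -1.0, -30.0, -10.0, -20.0],
        ])
        scaled, _, scaler = classify.minmax_normalize(train)
        assert scaled[:, :3].min() == 0.0 and scaled[:, :3].max() == 1.0
        assert scaled[:, 3:].min() == 0.0 and scaled[:, 3:].max() == 1.0
        assert scaled[0, 0] == pytest.approx(0.0)
        assert scaled[0, 2] == pytest.approx(1.0)
        assert scaled[0, 1] == pytest.approx(0.5)


def _solve_pairwise_qp(X, y, C, gamma):
    """Soft-margin dual QP on the cubic-kernel Gram matrix (scipy, per pair)."""
    from scipy.optimize import minimize

    K = classify.poly3_gram(X, gamma=gamma)
    ys = np.where(y == np.unique(y)[0], 1.0, -1.0)
    Q = np.outer(ys, ys) * K
    n = len(ys)

    def objective(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(
        objective, np.zeros(n), jac=grad, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ ys, "jac": lambda a: ys},
        options={"maxiter": 500, "ftol": 1e-12},
    )
    a = res.x
    sv = (a > 1e-6) & (a < C - 1e-6)
    if not np.any(sv):
        sv = a > 1e-6
    b = np.mean(ys[sv] - (a * ys) @ K[:, sv])
    return a, ys, b


class TestPolySVC:
    def toy_clusters(self, seed=0, n=12, spread=0.15):
        rng = np.random.default_rng(seed)
        centers = np.array([[1.0, 0.2, 0.2], [0.2, 1.0, 0.2], [0.2, 0.2, 1.0]])
        X = np.vstack([rng.normal(c, spread, size=(n, 3)) for c in centers]) + 0.5
        y = np.repeat([0, 1, 2], n)
        return X, y

    def test_separable_training_accuracy_100(self):
        X, y = self.toy_clusters()
        clf = classify.PolySVC(C=10.0, gamma=0.5).fit(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_order_permutation_invariance(self):
        X, y = self.toy_clusters(seed=3)
        perm = np.random.default_rng(0).permutation(len(y))
        a = classify.PolySVC(C=3.0, gamma=0.5).fit(X, y)
        b = classify.PolySVC(C=3.0, gamma=0.5).fit(X[perm], y[perm])
        grid = np.random.default_rng(1).uniform(0.0, 1.8, size=(100, 3))
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            classify.PolySVC().fit(np.ones((4, 2)), np.zeros(4))

    def test_matches_dual_qp_oracle_per_pair(self):
        # binary machines agree with an explicit dual-QP solve on the same
        # Gram matrix
        X, y = self.toy_clusters(seed=5, n=8)
        C, gamma = 3.0, 0.5
        probe = np.random.default_rng(2).uniform(0.0, 1.8, size=(60, 3))
        for pair in ((0, 1), (0, 2), (1, 2)):
            sel = np.isin(y, pair)
            Xp, yp = X[sel], y[sel]
            clf = classify.PolySVC(C=C, gamma=gamma).fit(Xp, yp)
            a, ys, b = _solve_pairwise_qp(Xp, yp, C, gamma)
            dec = (a * ys) @ classify.poly3_gram(Xp, probe, gamma=gamma) + b
            oracle = np.where(dec > 0, pair[0], pair[1])
            assert np.mean(clf.predict(probe) == oracle) >= 0.98

    def test_vote_arithmetic_and_tie_rule(self):
        # votes 1:2, with the third machine deciding between them -> majority;
        # a perfect 3-way cycle falls to the lowest class index
        votes = np.zeros((1, 3), dtype=int)
        for (i, j), d in zip(((0, 1), (0, 2), (1, 2)), (1.0, 1.0, 1.0)):
            if d >= 0:
                votes[0, i] += 1
            else:
                votes[0, j] += 1
        assert np.argmax(votes[0]) == 0
        cyclic = np.zeros((1, 3), dtype=int)
        for (i, j), d in zip(((0, 1), (0, 2), (1, 2)), (1.0, -1.0, 1.0)):
            if d >= 0:
                cyclic[0, i] += 1
            else:
                cyclic[0, j] += 1
        assert np.all(cyclic == 1)  # three-way tie
        assert np.argmax(cyclic[0]) == 0  # lowest index wins


class TestThreefoldCV:
    def separable_features(self, n_per_class=12, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([
            rng.normal(mu, 0.05, size=(n_per_class, 6))
            for mu in ([0.2] * 6, [0.5] * 6, [0.8] * 6)
        ])
        y = np.repeat(["normal", "steatosis", "fibrosis"], n_per_class)
        return X, y

    def test_fold_sizes_and_partition(self):
        X, y = self.separable_features()
        report = classify.threefold_cv(X, y, seed=1)
        tested = np.concatenate([c.test_idx for c in report.cycles])
        assert sorted(tested) == list(range(36))
        for c in report.cycles:
            assert c.train_idx.size == 24 and c.test_idx.size == 12
            for cls in np.unique(y):
                assert np.sum(y[c.test_idx] == cls) == 4

    def test_separable_data_perfect_accuracy(self):
        X, y = self.separable_features()
        report = classify.threefold_cv(X, y, seed=2)
        assert report.mean_test_accuracy == 1.0
        assert report.mean_train_accuracy == 1.0

    def test_unbalanced_counts_rejected(self):
        X = np.zeros((10, 6))
        y = np.array(["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="divisible"):
            classify.threefold_cv(X, y)

    def test_seed_changes_folds_not_partition_property(self):
        X, y = self.separable_features()
        r1 = classify.threefold_cv(X, y, seed=1)
        r2 = classify.threefold_cv(X, y, seed=9)
        assert not np.array_equal(r1.fold_assignment, r2.fold_assignment)
        assert np.array_equal(np.sort(r2.fold_assignment), np.repeat([1, 2, 3], 12))


class TestGridSearch:
    def test_single_candidate(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))]) + 0.1
        y = np.array(["a"] * 3 + ["b"] * 3)
        best = classify.grid_search(X, y, [2.0], [0.5], seed=0)
        assert best.C == 2.0 and best.gamma == 0.5

    def test_separable_ties_resolve_to_smallest(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.2, 0.02, (6, 2)), rng.normal(0.9, 0.02, (6, 2))])
        y = np.array(["a"] * 6 + ["b"] * 6)
        best = classify.grid_search(X, y, [1.0, 10.0, 100.0], [0.5, 1.0], seed=0)
        assert best.C == 1.0 and best.gamma == 0.5

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(m, 0.3, (6, 2)) for m in (0.2, 0.6, 1.0)])
        y = np.repeat(["a", "b", "c"], 6)
        C_grid, gamma_grid = [0.5, 5.0], [0.1, 1.0]
        best = classify.grid_search(X, y, C_grid, gamma_grid, seed=4)
        scores = {}
        for C in C_grid:
            for gamma in gamma_grid:
                cfg = classify.SVMConfig(C=C, gamma=gamma)
                scores[(C, gamma)] = classify.threefold_cv(X, y, cfg, seed=4).mean_test_accuracy
        best_score = max(scores.values())
        winners = sorted([k for k, v in scores.items() if v == best_score])
        assert (best.C, best.gamma) == winners[0]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            classify.grid_search(np.zeros((6, 2)), ["a", "b"] * 3, [], [1.0])


class TestAccuracyTable:
    def test_counts_and_percentages(self):
        truths = np.repeat([1, 2, 3], 4)
        cycle1 = [1, 1, 1, 1, 2, 2, 2, 2, 3, 1, 3, 3]
        table = classify.accuracy_table({"slope": [cycle1]}, truths)
        row = table[(table["feature_set"] == "slope") & (table["cycle"] == "1")].iloc[0]
        assert row["n_correct"] == 11
        assert row["accuracy_pct"] == pytest.approx(100 * 11 / 12)
        assert row["display"] == "91.7% (11/12)"

    def test_all_correct(self):
        truths = np.repeat([1, 2, 3], 4)
        table = classify.accuracy_table({"both": [truths]}, truths)
        assert table.iloc[0]["n_correct"] == 12

    def test_mean_of_cycle_accuracies(self):
        truths = np.repeat([1, 2, 3], 4)
        preds, _ = worked_example_cycles()
        table = classify.accuracy_table({"slope": preds["slope"]}, truths)
        accs = table[table["cycle"] != "mean"]["accuracy_pct"].to_numpy()
        assert np.allclose(accs, [100 * 11 / 12, 100 * 10 / 12, 100 * 9 / 12])
        mean_row = table[table["cycle"] == "mean"].iloc[0]
        assert mean_row["accuracy_pct"] == pytest.approx(np.mean(accs))
        assert mean_row["accuracy_pct"] == pytest.approx(83.3, abs=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="truths"):
            classify.accuracy_table({"x": [[1, 2]]}, [1, 2, 3])
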