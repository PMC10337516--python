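import numpy as np
import pytest

import scipy.sparse as sp

from ehrgan.data import ProcessedDataset, SplitSpec
from ehrgan.evaluate import (baseline_label_propagation, classification_metrics,
                             dimensionwise_prediction, dimensionwise_probability,
                             disclosure_curve, extract_frontier_nodes,
                             knn_disclosure_attack, repeated_cv)
from ehrgan.graph import PatientGraph, prune_graph
from ehrgan.synthetic import generate_bernoulli_table


class TestClassificationMetrics:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        s = np.linspace(0, 1, 10)
        assert classification_metrics(y, s).auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        y = np.array([0, 1] * 10)
        assert classification_metrics(y, np.full(20, 0.3)).auc == pytest.approx(0.5)

    def test_matches_concordant_pair_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        auc = classification_metrics(y, s).auc
        pos, neg = s[y == 1], s[y == 0]
        pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        s = rng.random(40)
        a1 = classification_metrics(y, s).auc
        a2 = classification_metrics(y, np.exp(3 * s)).auc
        assert a1 == pytest.approx(a2)

    def test_single_class_flagged_not_fabricated(self):
        m = classification_metrics(np.zeros(5, dtype=int), np.random.rand(5))
        assert np.isnan(m.auc) and m.flags


class _OracleMethod:
    """Returns the true label as the positive-class score."""

    def fit(self, train_ds):
        pass

    def score(self, X):
        return self.truth[X[:, 0].astype(int)]


class TestRepeatedCv:
    def _ds(self, n=60):
        y = np.repeat([0, 1], n // 2)
        X = np.zeros((n, 2))
        X[:, 0] = np.arange(n) / n  # row index carrier
        return ProcessedDataset(X=X, y=y, mask=np.ones(n, bool), M=2)

    def test_oracle_method_gets_auc_one(self):
        ds = self._ds()

        class Oracle:
            def fit(self, t):
                pass

            def score(self, X):
                idx = (X[:, 0] * len(ds.y)).round().astype(int)
                p = ds.y[idx].astype(float)
                return np.column_stack([1 - p, p])

        m = repeated_cv(Oracle(), ds, SplitSpec(label_rate=0.5, folds=5, repeats=3, seed=0))
        assert m.auc == pytest.approx(1.0)
        assert m.auc_sd == pytest.approx(0.0)

    def test_majority_dummy_has_zero_minority_recall(self):
        ds = self._ds()

        class Majority:
            def fit(self, t):
                pass

            def score(self, X):
                return np.column_stack([np.ones(len(X)), np.zeros(len(X))])

        m = repeated_cv(Majority(), ds, SplitSpec(label_rate=0.5, folds=5, repeats=3, seed=1))
        assert m.recall == pytest.approx(0.0)

    def test_same_seed_reproduces(self):
        ds = self._ds()

        class Rand:
            def fit(self, t):
                self.rng = np.random.default_rng(int(t.mask.sum()))

            def score(self, X):
                p = self.rng.random(len(X))
                return np.column_stack([1 - p, p])

        spec = SplitSpec(label_rate=0.5, folds=5, repeats=2, seed=5)
        assert repeated_cv(Rand(), ds, spec).auc == repeated_cv(Rand(), ds, spec).auc

    def test_every_record_tested_once_per_repeat(self):
        ds = self._ds()
        seen = []

        class Spy:
            def fit(self, t):
                pass

            def score(self, X):
                seen.append((X[:, 0] * len(ds.y)).round().astype(int))
                return np.column_stack([np.zeros(len(X)), np.ones(len(X))])

        repeated_cv(Spy(), ds, SplitSpec(label_rate=0.5, folds=5, repeats=1, seed=2))
        tested = np.sort(np.concatenate(seen))
        assert np.array_equal(tested, np.arange(len(ds.y)))


class TestLabelPropagation:
    def test_path_midpoint_is_half(self):
        g = prune_graph({(0, 1): 1.0, (1, 2): 1.0})
        F = baseline_label_propagation(g, [0, 0, 1], [True, False, True])
        assert np.allclose(F[1], [0.5, 0.5], atol=1e-5)

    def test_all_labeled_clamps(self):
        g = prune_graph({(0, 1): 1.0, (1, 2): 0.5})
        y = np.array([0, 1, 0])
        F = baseline_label_propagation(g, y, [True] * 3)
        assert np.array_equal(F.argmax(axis=1), y)

    def test_fixed_point_matches_linear_solve(self):
        # planted 2-block graph; harmonic solution F_U = (D_UU - W_UU)^-1 W_UL F_L
        rng = np.random.default_rng(4)
        edges = {}
        for base in (0, 15):
            for i in range(base, base + 15):
                for j in range(i + 1, base + 15):
                    if rng.random() < 0.5:
                        edges[(i, j)] = float(rng.random() * 0.9 + 0.1)
        edges[(0, 15)] = 0.2
        g = prune_graph(edges)
        n = g.n_nodes
        y = (g.nodes >= 15).astype(int)
        mask = np.zeros(n, bool)
        mask[[0, 1, 16, 17]] = True
        F = baseline_label_propagation(g, y, mask, tol=1e-10)

        pos = {int(v): i for i, v in enumerate(g.nodes)}
        W = np.zeros((n, n))
        for i, j, w in g.edges():
            W[pos[i], pos[j]] = W[pos[j], pos[i]] = w
        D = np.diag(W.sum(1))
        U, L = ~mask, mask
        FL = np.eye(2)[y[L]]
        FU = np.linalg.solve(D[np.ix_(U, U)] - W[np.ix_(U, U)], W[np.ix_(U, L)] @ FL)
        assert np.allclose(F[U], FU, atol=1e-5)

    def test_isolated_unlabeled_node_uniform_with_warning(self):
        import networkx as nx

        g0 = nx.Graph()
        g0.add_edge(0, 1, weight=1.0)
        g0.add_node(2)
        g = PatientGraph(graph=g0, noise_nodes=[], n_components=2)
        with pytest.warns(UserWarning, match="isolated"):
            F = baseline_label_propagation(g, [0, 1, 0], [True, True, False])
        assert np.allclose(F[2], 0.5)


class TestDimensionwiseProbability:
    def test_self_comparison_on_diagonal(self):
        R = generate_bernoulli_table(500, [0.2, 0.5, 0.8], seed=0)
        rep = dimensionwise_probability(R, R.copy(), [0, 1, 2])
        assert rep.mean_abs_dev == pytest.approx(0.0)

    def test_binarization_threshold(self):
        R = generate_bernoulli_table(100, [0.5], seed=1)
        S = np.full((100, 1), 0.7)
        rep = dimensionwise_probability(R, S, [0])
        assert rep.probabilities[0][1] == pytest.approx(1.0)

    def test_exact_bernoulli_within_3se(self):
        n = 10_000
        p = np.array([0.2, 0.8])
        R = generate_bernoulli_table(n, p, seed=2)
        S = generate_bernoulli_table(n, p, seed=3)
        rep = dimensionwise_probability(R, S, [0, 1])
        for (pr, ps), pk in zip(rep.probabilities, p):
            se = np.sqrt(pk * (1 - pk) / n)
            assert abs(ps - pr) <= 2 * 3 * se

    def test_no_binary_columns_rejected(self):
        with pytest.raises(ValueError):
            dimensionwise_probability(np.zeros((5, 2)), np.zeros((5, 2)), [])


class TestDimensionwisePrediction:
    def test_copy_synthetic_equal_f1(self):
        rng = np.random.default_rng(5)
        z = rng.random(300)
        R = np.column_stack([(z > 0.5), (z > 0.4), (z > 0.6), rng.random(300) > 0.5]).astype(float)
        H = R[200:]
        rep = dimensionwise_prediction(R[:200], R[:200].copy(), H, [0, 1, 2, 3])
        for f1r, f1s in rep.predictions:
            assert f1s == pytest.approx(f1r)

    def test_leakage_fixture_gives_perfect_f1(self):
        rng = np.random.default_rng(6)
        col = (rng.random(200) > 0.5).astype(float)
        R = np.column_stack([col, col])  # target duplicated among features
        rep = dimensionwise_prediction(R[:150], R[:150].copy(), R[150:], [0, 1])
        assert all(f1 == pytest.approx(1.0) for pair in rep.predictions for f1 in pair)

    def test_noise_synthetic_predicts_worse_on_structured_data(self):
        worse = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = rng.random(400)
            R = np.column_stack([(z > 0.5), (z > 0.45), (z > 0.55)]).astype(float)
            S = generate_bernoulli_table(300, [0.5, 0.5, 0.5], seed=100 + seed)
            rep = dimensionwise_prediction(R[:300], S, R[300:], [0, 1, 2])
            mean_r = np.mean([a for a, _ in rep.predictions])
            mean_s = np.mean([b for _, b in rep.predictions])
            worse += mean_s <= mean_r + 1e-12
        assert worse >= 4

    def test_constant_target_skipped(self):
        R = np.column_stack([np.ones(50), np.random.default_rng(7).random(50) > 0.5]).astype(float)
        rep = dimensionwise_prediction(R, R.copy(), R, [0, 1])
        assert rep.skipped_dims == [0]


def _parity_rows(n, bits, seed):
    """Distinct binary rows with an even-parity bit appended: any two rows
    differ in >= 2 coordinates, so every (d-1)-column projection is unique."""
    rng = np.random.default_rng(seed)
    seen, rows = set(), []
    while len(rows) < n:
        v = tuple(int(b) for b in rng.integers(0, 2, bits))
        if v in seen:
            continue
        seen.add(v)
        rows.append(v + (sum(v) % 2,))
    return np.array(rows, dtype=float)


class TestDisclosureAttack:
    def test_copy_synthetic_upper_bound(self):
        R = _parity_rows(80, 7, seed=8)
        rep = knn_disclosure_attack(R, R.copy(), compromised_fraction=0.2,
                                    r_known=7, k_attack=1, repeats=10, seed=0)
        assert rep.per_r[7]["precision"] == pytest.approx(1.0)
        assert rep.per_r[7]["sensitivity"] == pytest.approx(1.0)

    def test_all_zero_synthetic_degenerate(self):
        rng = np.random.default_rng(9)
        R = (rng.random((50, 5)) > 0.3).astype(float)
        S = np.zeros((50, 5))
        rep = knn_disclosure_attack(R, S, r_known=2, repeats=5, seed=1)
        assert rep.per_r[2]["precision"] == 0.0
        assert rep.per_r[2]["sensitivity"] == 0.0
        assert rep.flags

    def test_independent_null_precision_near_prevalence(self):
        p = np.array([0.3, 0.5, 0.7, 0.4, 0.6])
        R = generate_bernoulli_table(200, p, seed=2)
        S = generate_bernoulli_table(200, p, seed=3)
        rep = knn_disclosure_attack(R, S, compromised_fraction=0.01, r_known=2,
                                    k_attack=1, repeats=100, seed=4)
        # under independence a positive estimate is right with prob ~ column prevalence
        prev = p.mean()
        se = np.sqrt(prev * (1 - prev) / (100 * 3 * 2))  # repeats x unknown dims x records
        assert abs(rep.per_r[2]["precision"] - prev) <= 5 * se

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            knn_disclosure_attack(np.zeros((10, 4)), np.zeros((10, 4)), r_known=4)

    def test_precision_monotone_in_r_on_copy_fixture(self):
        R = _parity_rows(40, 12, seed=10)
        rep = disclosure_curve(R, R.copy(), r_values=[2, 5, 8, 12], repeats=50, seed=5,
                               compromised_fraction=0.25)
        precs = [rep.per_r[r]["precision"] for r in (2, 5, 8, 12)]
        assert all(a <= b + 1e-9 for a, b in zip(precs, precs[1:]))


class TestFrontierNodes:
    def test_bridge_endpoints_only(self):
        edges = {(0, 1): 1.0, (1, 2): 1.0, (0, 2): 1.0,
                 (3, 4): 1.0, (4, 5): 1.0, (3, 5): 1.0, (2, 3): 0.5}
        g = prune_graph(edges)
        classes = {v: (0 if v < 3 else 1) for v in range(6)}
        assert extract_frontier_nodes(g, classes) == {2, 3}

    def test_uniform_class_empty(self):
        g = prune_graph({(0, 1): 1.0, (1, 2): 1.0})
        assert extract_frontier_nodes(g, {0: 1, 1: 1, 2: 1}) == set()

    def test_matches_edge_scan_oracle(self):
        rng = np.random.default_rng(11)
        edges = {}
        for _ in range(200):
            i, j = rng.integers(0, 40, 2)
            if i != j:
                edges[(min(i, j), max(i, j))] = 0.5
        g = prune_graph(edges)
        classes = {int(v): int(rng.integers(0, 3)) for v in g.nodes}
        expected = set()
        for i, j, _ in g.edges():
            if classes[i] != classes[j]:
                expected.update((i, j))
        assert extract_frontier_nodes(g, classes) == expected
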