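import numpy as np
import pytest

from serumml import interpret
from serumml.bench import make_model
from conftest import make_matrix
from oracles import exact_shapley, vote_then_fill


def linear_fn(coefs, intercept=0.0):
    coefs = np.asarray(coefs, float)
    return lambda X: np.atleast_2d(X) @ coefs + intercept


class TestModelImportances:
    def test_informative_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (120, 6))
        y = (X[:, 2] > 0).astype(int)
        rf = make_model("random_forest", seed=0)
        rf.fit(X, y)
        r = interpret.model_importances(rf, [f"{m:.2f}" for m in range(6)])
        assert r.ranks[2] == 1

    def test_scores_normalised(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(0, 1, (60, 4)), rng.integers(0, 2, 60)
        rf = make_model("decision_tree", seed=1)
        rf.fit(X, y)
        r = interpret.model_importances(rf, list("abcd"))
        assert r.scores.sum() == pytest.approx(1.0)
        assert np.all(r.scores >= 0)

    def test_model_without_importances_rejected(self):
        knn = make_model("knn")
        with pytest.raises(ValueError, match="random_forest"):
            interpret.model_importances(knn, ["a"])


class TestKernelShap:
    def test_local_accuracy_full_enumeration(self):
        # base + sum(contributions) == model output, to 1e-6, d <= 10
        rng = np.random.default_rng(2)
        d = 6
        bg = rng.normal(0, 1, (25, d))
        X = rng.normal(0, 1, (4, d))
        fn = lambda Z: np.tanh(np.atleast_2d(Z).sum(axis=1))
        phi, base = interpret.shap_attributions(fn, bg, X)
        for i in range(len(X)):
            assert base + phi[i].sum() == pytest.approx(float(fn(X[i][None])[0]),
                                                        abs=1e-6)

    def test_exact_shapley_recovered(self):
        # kernel solution equals direct subset-enumeration Shapley values
        rng = np.random.default_rng(3)
        d = 5
        bg = rng.normal(0, 1, (12, d))
        x = rng.normal(0, 1, d)
        fn = lambda Z: np.sin(np.atleast_2d(Z)[:, 0]) + \
            np.atleast_2d(Z)[:, 1] * np.atleast_2d(Z)[:, 2]
        phi, _ = interpret.shap_attributions(fn, bg, x[None])
        oracle = exact_shapley(fn, x, bg)
        assert np.allclose(phi[0], oracle, atol=1e-8)

    def test_linear_model_closed_form(self):
        # independent features: phi_i = coef_i * (x_i - background mean_i)
        rng = np.random.default_rng(4)
        coefs = np.array([2.0, -1.0, 0.5, 0.0])
        bg = rng.normal(0, 1, (40, 4))
        x = rng.normal(0, 1, 4)
        phi, _ = interpret.shap_attributions(linear_fn(coefs), bg, x[None])
        assert np.allclose(phi[0], coefs * (x - bg.mean(axis=0)), atol=1e-8)

    def test_duplicated_feature_symmetry(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(0, 1, (30, 3))
        bg[:, 1] = bg[:, 0]
        x = np.array([1.3, 1.3, -0.2])
        fn = lambda Z: np.atleast_2d(Z)[:, 0] + np.atleast_2d(Z)[:, 1]
        phi, _ = interpret.shap_attributions(fn, bg, x[None])
        assert phi[0, 0] == pytest.approx(phi[0, 1], abs=1e-8)

    def test_oversized_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            interpret.draw_background(np.ones((10, 3)), n=20)

    def test_sampled_budget_additivity_holds(self):
        # d > 11 forces coalition sampling; local accuracy still exact
        rng = np.random.default_rng(6)
        d = 14
        bg = rng.normal(0, 1, (20, d))
        x = rng.normal(0, 1, d)
        coefs = rng.normal(0, 1, d)
        fn = linear_fn(coefs)
        phi, base = interpret.shap_attributions(fn, bg, x[None], budget=600, seed=6)
        assert base + phi[0].sum() == pytest.approx(float(fn(x[None])[0]), abs=1e-8)


class TestLime:
    def test_ignored_feature_gets_zero_weight(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (80, 4))
        fn = lambda Z: 1 / (1 + np.exp(-np.atleast_2d(Z)[:, 0]))
        r = interpret.lime_rankings(fn, X, list("abcd"),
                                    explain_idx=np.arange(6),
                                    n_perturbations=1500, seed=7)
        assert abs(r.scores[3]) < 0.05 * abs(r.scores[0])
        assert r.ranks[0] == 1

    def test_linear_target_sign_recovery(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (60, 3))
        coefs = np.array([1.5, -2.0, 0.8])
        r = interpret.lime_rankings(linear_fn(coefs, 0.5), X, list("abc"),
                                    explain_idx=np.arange(5),
                                    n_perturbations=2000, seed=8)
        assert np.all(np.sign(r.scores) == np.sign(coefs))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (40, 3))
        fn = linear_fn([1.0, 2.0, -1.0])
        a = interpret.lime_rankings(fn, X, list("abc"), explain_idx=np.arange(3),
                                    n_perturbations=500, seed=3)
        b = interpret.lime_rankings(fn, X, list("abc"), explain_idx=np.arange(3),
                                    n_perturbations=500, seed=3)
        assert np.array_equal(a.scores, b.scores)

    def test_zero_variance_features_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            interpret.lime_rankings(linear_fn([1.0]), np.ones((10, 1)), ["a"])


class TestConsensus:
    def _ranking(self, method, names, order):
        scores = np.zeros(len(names))
        ranks = np.empty(len(names), int)
        for r, f in enumerate(order, start=1):
            i = names.index(f)
            ranks[i] = r
            scores[i] = 1.0 / r
        return interpret.ImportanceRanking(method, names, scores, ranks)

    def test_identical_rankings_give_common_top_k(self):
        names = [f"{1000 + 100 * i}.00" for i in range(6)]
        order = names[::-1]
        rks = [self._ranking(m, names, order) for m in ("gini", "shap", "lime")]
        cons = interpret.consensus_top_k(rks, k=3)
        assert set(cons.selected) == set(order[:3])

    def test_two_of_three_majority_selected(self):
        names = ["1000.00", "2000.00", "3000.00", "4000.00"]
        a = self._ranking("gini", names, ["1000.00", "2000.00", "3000.00", "4000.00"])
        b = self._ranking("shap", names, ["1000.00", "2000.00", "4000.00", "3000.00"])
        c = self._ranking("lime", names, ["3000.00", "4000.00", "1000.00", "2000.00"])
        cons = interpret.consensus_top_k([a, b, c], k=2)
        # 1000 and 2000 are top-2 in two methods each -> majority
        assert set(cons.selected) == {"1000.00", "2000.00"}
        assert cons.votes["1000.00"] == 2

    def test_order_invariance(self):
        names = [f"{1000 + i}.00" for i in range(6)]
        rng = np.random.default_rng(10)
        rks = [self._ranking(m, names, list(rng.permutation(names)))
               for m in ("gini", "shap", "lime")]
        c1 = interpret.consensus_top_k(rks, k=3)
        c2 = interpret.consensus_top_k(rks[::-1], k=3)
        assert c1.selected == c2.selected

    def test_matches_enumeration_oracle(self):
        names = [f"{1000 + 10 * i}.00" for i in range(6)]
        rng = np.random.default_rng(11)
        rks = [self._ranking(m, names, list(rng.permutation(names)))
               for m in ("gini", "shap", "lime")]
        cons = interpret.consensus_top_k(rks, k=3)
        oracle = vote_then_fill(
            [{f: int(r.ranks[r.feature_names.index(f)]) for f in names}
             for r in rks], k=3)
        assert cons.selected == oracle

    def test_mismatched_feature_sets_rejected(self):
        a = self._ranking("gini", ["1.00", "2.00"], ["1.00", "2.00"])
        b = self._ranking("shap", ["1.00", "3.00"], ["1.00", "3.00"])
        with pytest.raises(ValueError, match="feature sets"):
            interpret.consensus_top_k([a, b, a], k=1)


class TestImportanceIntersection:
    def test_planted_dominant_features_recovered(self):
        # moderate effects (2x at lognormal sigma 0.5) keep every tree family
        # dependent on all three informative features
        rng = np.random.default_rng(12)
        n, d = 240, 15
        X = rng.lognormal(0, 0.5, (n, d))
        y = np.array(["cancer"] * 120 + ["healthy"] * 120)
        X[:120, [2, 7, 11]] *= 2.0
        fm = make_matrix(X, y)
        got = interpret.cross_validated_importance_intersection(fm, top_m=5, seed=0)
        expect = {f"{fm.feature_mzs[i]:.2f}" for i in (2, 7, 11)}
        assert got == expect

    def test_empty_intersection_warns(self):
        rng = np.random.default_rng(13)
        fm = make_matrix(rng.normal(0, 1, (40, 30)),
                         ["cancer"] * 20 + ["healthy"] * 20)
        with pytest.warns(UserWarning, match="share no features"):
            got = interpret.cross_validated_importance_intersection(fm, top_m=1,
                                                                    seed=1)
        assert got == set() or isinstance(got, set)
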