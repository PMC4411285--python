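"""M5 model trees, rule extraction, and the accuracy-model interface."""

import numpy as np
import pytest

from pananchor import m5rules
from pananchor.features import AttributeVector, BoxCoxParams
from pananchor.m5rules import (
    RuleModel,
    build_model_tree,
    extract_rules,
    load_rule_model,
    predict_distance,
    save_rule_model,
    select_anchors,
    train_accuracy_model,
)


def _r2(obs, pred):
    return 1 - ((obs - pred) ** 2).sum() / ((obs - obs.mean()) ** 2).sum()


def _rule_model(rules, default, y, names=None):
    names = names or ["x1", "x2"]
    bc = BoxCoxParams(names, np.ones(len(names)), np.zeros(len(names)),
                      np.zeros(len(names)), np.ones(len(names)))
    return RuleModel("G", names, rules, default, bc,
                     y_min=float(y.min()), y_max=float(y.max()))


class TestModelTree:
    def test_globally_linear_collapses_to_one_leaf_with_true_slope(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (500, 3))
        y = 2.0 + 3.0 * X[:, 0] - 1.5 * X[:, 2] + rng.normal(0, 0.1, 500)
        tree = build_model_tree(X, y)
        leaves = tree.leaves()
        assert len(leaves) == 1
        m = leaves[0][1].model
        assert m.coef[0] == pytest.approx(3.0, rel=0.05)
        assert m.coef[2] == pytest.approx(-1.5, rel=0.05)

    def test_step_function_first_split_at_breakpoint(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (600, 2))
        y = np.where(X[:, 0] <= 0.43, 1.0, 5.0) + rng.normal(0, 0.1, 600)
        tree = build_model_tree(X, y)
        grid = np.sort(X[:, 0])
        resolution = np.diff(grid).max()
        assert tree.root.split_attr == 0
        assert abs(tree.root.split_val - 0.43) < 3 * resolution + 0.01

    def test_constant_response_single_zero_slope_leaf(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (200, 3))
        tree = build_model_tree(X, np.full(200, 7.0))
        assert len(tree.leaves()) == 1
        assert np.all(tree.root.model.coef == 0)
        assert tree.root.model.intercept == 7.0

    def test_tiny_dataset_is_single_global_model(self):
        X = np.arange(6, dtype=float)[:, None]
        y = 2 * X[:, 0]
        tree = build_model_tree(X, y, min_leaf=4)
        assert len(tree.leaves()) == 1

    def test_child_sizes_respect_min_leaf(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (300, 2))
        y = np.sin(6 * X[:, 0]) + rng.normal(0, 0.2, 300)
        tree = build_model_tree(X, y, min_leaf=10)

        def walk(node):
            if node.is_leaf:
                assert node.n >= 10
            else:
                walk(node.left)
                walk(node.right)

        walk(tree.root)


class TestRules:
    def test_linear_data_gives_exactly_one_rule(self):
        # "fits one linear model" = noise well below the sd stopping floor
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (400, 2))
        y = 1.0 + 3.0 * X[:, 1] + rng.normal(0, 0.05, 400)
        rules, _ = extract_rules(X, y)
        assert len(rules) == 1
        assert rules[0].conditions == []

    def test_three_well_separated_regimes(self):
        """Disjoint regime supports: about one rule per regime."""
        rng = np.random.default_rng(5)
        xs = np.concatenate([
            rng.uniform(0.0, 0.30, 300),
            rng.uniform(0.36, 0.64, 300),
            rng.uniform(0.70, 1.0, 300),
        ])
        X = xs[:, None]
        y = np.select(
            [xs <= 0.33, xs <= 0.66], [1 + xs, 50 - 2 * xs], default=100 + xs
        ) + rng.normal(0, 0.02, 900)
        rules, _ = extract_rules(X, y)
        assert 2 <= len(rules) <= 4
        assert sorted(r.coverage for r in rules)[-3:] == [300, 300, 300]

    def test_rule_list_exhaustive_on_training_data(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (500, 3))
        y = np.where(X[:, 1] > 0.5, X[:, 0], -X[:, 2]) + rng.normal(0, 0.1, 500)
        rules, default = extract_rules(X, y)
        for row in X:
            assert any(r.matches(row) for r in rules) or default is not None
        assert sum(r.coverage for r in rules) == len(X)


class TestPrediction:
    def test_single_rule_model_prediction_is_its_linear_model(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (300, 2))
        y = 4.0 + 2.0 * X[:, 0]
        rules, default = extract_rules(X, y)
        model = _rule_model(rules, default, y)
        x = np.array([0.5, 0.5])
        assert model.predict_transformed(x[None, :])[0] == pytest.approx(
            rules[0].model.predict(x[None, :])[0]
        )

    def test_no_matching_rule_falls_back_to_default(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (300, 2))
        y = X[:, 0]
        rules, default = extract_rules(X, y)
        # force every rule to be unmatchable
        for r in rules:
            r.conditions = [(0, ">", 99.0)]
        model = _rule_model(rules, default, y)
        x = np.array([0.5, 0.5])
        assert model.predict_transformed(x[None, :])[0] == pytest.approx(
            np.clip(default.predict(x[None, :])[0], y.min(), y.max())
        )

    def test_piecewise_linear_benchmark_heldout_r2(self):
        """Known two-attribute piecewise-linear truth: held-out r2 >= 0.9."""
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, (3000, 2))
        y = np.where(X[:, 0] <= 0, 3 + 2 * X[:, 1], -1 - X[:, 1]) + rng.normal(0, 0.1, 3000)
        rules, default = extract_rules(X[:2000], y[:2000])
        model = _rule_model(rules, default, y[:2000])
        assert _r2(y[2000:], model.predict_transformed(X[2000:])) >= 0.9

    def test_permuted_response_heldout_r2_near_zero(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(-1, 1, (2000, 2))
        y = np.where(X[:, 0] <= 0, 3 + 2 * X[:, 1], -1 - X[:, 1]) + rng.normal(0, 0.1, 2000)
        y_perm = rng.permutation(y[:1500])
        rules, default = extract_rules(X[:1500], y_perm)
        model = _rule_model(rules, default, y_perm)
        assert _r2(y[1500:], model.predict_transformed(X[1500:])) < 0.05


class TestTrainAccuracyModel:
    def _training_data(self, n=400, seed=11):
        rng = np.random.default_rng(seed)
        X = np.column_stack([
            rng.uniform(1, 10, n),
            rng.uniform(0, 1, n),
            rng.gamma(2.0, size=n),
        ])
        log_d = np.where(X[:, 1] > 0.5, 6 - 0.3 * X[:, 0], 3.5) + rng.normal(0, 0.3, n)
        return X, 10.0 ** log_d - 1

    def test_training_r2_exceeds_heldout_r2(self):
        X, d = self._training_data()
        model = train_accuracy_model(X[:300], d[:300], "G", ["a", "b", "c"])
        y_te = np.log10(d[300:] + 1)
        heldout = _r2(y_te, model.predict_transformed(
            m5rules.boxcox_apply(model.boxcox, X[300:])))
        assert model.training_r2 >= heldout
        assert len(model.rules) >= 1

    def test_deterministic(self):
        X, d = self._training_data()
        a = train_accuracy_model(X, d, "G", ["a", "b", "c"])
        b = train_accuracy_model(X, d, "G", ["a", "b", "c"])
        assert len(a.rules) == len(b.rules)
        assert a.training_r2 == b.training_r2

    def test_insufficient_instances_error(self):
        X, d = self._training_data(n=80)
        with pytest.raises(ValueError, match="insufficient"):
            train_accuracy_model(X, d, "G", ["a", "b", "c"])

    def test_prediction_back_transform_and_class_check(self):
        X, d = self._training_data()
        model = train_accuracy_model(X, d, "G", ["a", "b", "c"])
        attrs = AttributeVector("G", ["a", "b", "c"], X[0])
        pred = predict_distance(model, attrs)
        assert pred >= 0.0
        with pytest.raises(ValueError):
            predict_distance(model, AttributeVector("J", ["a", "b", "c"], X[0]))

    def test_persistence_round_trip(self, tmp_path):
        X, d = self._training_data()
        model = train_accuracy_model(X, d, "G", ["a", "b", "c"])
        path = tmp_path / "model.txt"
        save_rule_model(model, path)
        again = load_rule_model(path)
        Xt = m5rules.boxcox_apply(model.boxcox, X)
        assert np.allclose(
            model.predict_transformed(Xt), again.predict_transformed(Xt)
        )
        assert again.model_class == "G"
        assert len(again.rules) == len(model.rules)


class TestSelectAnchors:
    @pytest.mark.parametrize(
        "cls,pred,kept",
        [
            ("G", 49_999.0, True),
            ("G", 50_000.0, True),
            ("G", 50_001.0, False),
            ("GJ", 100_001.0, False),
            ("GJ", 99_999.0, True),
            ("J", 100_000.0, True),
        ],
    )
    def test_class_threshold_boundaries(self, cls, pred, kept):
        out = select_anchors([("tag", cls, pred)])
        assert (len(out) == 1) == kept

    def test_infinite_thresholds_keep_everything(self):
        items = [(i, "G", float(i) * 1e6) for i in range(10)]
        out = select_anchors(items, {"G": np.inf, "J": np.inf, "GJ": np.inf})
        assert len(out) == 10

    def test_unknown_class_is_error(self):
        with pytest.raises(ValueError):
            select_anchors([("t", "Q", 1.0)])
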