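import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import RepeatedStratifiedKFold

import spongeffects as sp
from spongeffects.classify import default_grid, make_model
from spongeffects.enrichment import ScoreMatrix


def cluster_scores(n_classes=3, per_class=15, n_modules=6, sep=5.0, seed=0):
    """Well-separated Gaussian clusters per class in module-score space."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(n_classes, n_modules))
    rows, labels = [], []
    for c in range(n_classes):
        rows.append(centers[c] + rng.normal(0, 1.0, size=(per_class, n_modules)))
        labels.extend([f"k{c}"] * per_class)
    X = np.vstack(rows)
    samples = [f"s{i:03d}" for i in range(len(labels))]
    values = pd.DataFrame(
        X.T, index=[f"mod{j}" for j in range(n_modules)], columns=samples
    )
    return ScoreMatrix(values=values, method="OE"), pd.Series(labels, index=samples)


class TestSubsetAccuracy:
    @pytest.mark.parametrize(
        "pred, truth, expected",
        [
            (["a", "b", "c"], ["a", "b", "c"], 1.0),
            (["a", "a", "a"], ["b", "b", "b"], 0.0),
            (["a", "b", "c", "d"], ["a", "b", "c", "x"], 0.75),
        ],
    )
    def test_fraction_of_exact_matches(self, pred, truth, expected):
        assert sp.subset_accuracy(pred, truth) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sp.subset_accuracy(["a"], ["a", "b"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sp.subset_accuracy([], [])


class TestCrossValidate:
    def test_separable_clusters_recovered(self):
        scores, labels = cluster_scores(seed=1)
        result = sp.cross_validate(
            scores, labels,
            spec=sp.ModelSpec(fixed={"n_estimators": 100}),
            folds=5, repeats=2, seed=0,
        )
        assert result.cv_subset_accuracy >= 0.95
        assert result.train_subset_accuracy == 1.0
        assert result.importance is not None
        assert (result.importance >= 0).all()

    def test_permuted_labels_hover_at_chance(self):
        scores, labels = cluster_scores(n_classes=5, per_class=30, sep=5.0, seed=2)
        rng = np.random.default_rng(0)
        permuted = pd.Series(
            labels.to_numpy()[rng.permutation(len(labels))], index=labels.index
        )
        result = sp.cross_validate(
            scores, permuted,
            spec=sp.ModelSpec(grid={"mtry": [2]}, fixed={"n_estimators": 100}),
            folds=5, repeats=1, seed=0,
        )
        assert 0.12 <= result.cv_subset_accuracy <= 0.28

    def test_tie_break_prefers_smallest_parameter(self):
        scores, labels = cluster_scores(sep=50.0, seed=3)  # everything wins
        result = sp.cross_validate(
            scores, labels,
            spec=sp.ModelSpec(grid={"mtry": [5, 1, 3]}, fixed={"n_estimators": 50}),
            folds=5, repeats=1, seed=0,
        )
        assert result.cv_results["cv_subset_accuracy"].nunique() == 1
        assert result.best_params == {"mtry": 1}

    def test_determinism_same_seed_same_outcome(self):
        scores, labels = cluster_scores(sep=1.0, seed=4)
        a = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=9,
                              spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        b = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=9,
                              spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        assert a.best_params == b.best_params
        assert a.cv_subset_accuracy == b.cv_subset_accuracy
        assert np.array_equal(a.importance.to_numpy(), b.importance.to_numpy())

    def test_stratified_splits_preserve_class_proportions(self):
        scores, labels = cluster_scores(n_classes=3, per_class=20, seed=5)
        y = labels.to_numpy()
        splitter = RepeatedStratifiedKFold(n_splits=5, n_repeats=2, random_state=0)
        for _, test_idx in splitter.split(scores.values.to_numpy().T, y):
            _, counts = np.unique(y[test_idx], return_counts=True)
            assert counts.max() - counts.min() <= 1

    def test_class_smaller_than_folds_rejected(self):
        scores, labels = cluster_scores(per_class=4, seed=6)
        with pytest.raises(ValueError, match="fewer than folds"):
            sp.cross_validate(scores, labels, folds=10)

    def test_unlabeled_sample_rejected(self):
        scores, labels = cluster_scores(seed=7)
        with pytest.raises(ValueError, match="without labels"):
            sp.cross_validate(scores, labels.iloc[:-1], folds=5)

    @pytest.mark.parametrize("family", ["linear_svm", "gradient_boosting"])
    def test_other_families_share_the_interface(self, family):
        scores, labels = cluster_scores(seed=8)
        grid = {"C": [1.0]} if family == "linear_svm" else {
            "nrounds": [50], "max_depth": [2], "eta": [0.3]
        }
        result = sp.cross_validate(
            scores, labels, spec=sp.ModelSpec(family=family, grid=grid),
            folds=5, repeats=1, seed=0,
        )
        assert result.cv_subset_accuracy >= 0.9
        assert result.importance is None


class TestModelSpec:
    def test_default_forest_grid_brackets_sqrt_p(self):
        grid = default_grid("random_forest", 100)
        assert grid == {"mtry": [5, 10, 20]}

    def test_invalid_parameter_for_family_rejected(self):
        with pytest.raises(ValueError, match="invalid for family"):
            sp.ModelSpec(family="linear_svm", grid={"mtry": [1]})

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            sp.ModelSpec(grid={"mtry": []})

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            sp.ModelSpec(family="deep_net")

    def test_make_model_maps_conventional_names(self):
        model = make_model("gradient_boosting",
                           {"nrounds": 77, "max_depth": 3, "eta": 0.2}, seed=0)
        assert model.n_estimators == 77 and model.learning_rate == 0.2


class TestEvaluateExternal:
    def test_training_data_reproduces_train_accuracy(self):
        scores, labels = cluster_scores(seed=10)
        result = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=0,
                                   spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        assert sp.evaluate_external(result, scores, labels) == result.train_subset_accuracy

    def test_idempotent_and_non_mutating(self):
        scores, labels = cluster_scores(seed=11)
        result = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=0,
                                   spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        first = sp.evaluate_external(result, scores, labels)
        second = sp.evaluate_external(result, scores, labels)
        assert first == second

    def test_noise_scores_near_chance(self):
        scores, labels = cluster_scores(n_classes=5, per_class=30, seed=12)
        result = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=0,
                                   spec=sp.ModelSpec(fixed={"n_estimators": 100}))
        rng = np.random.default_rng(1)
        noise = ScoreMatrix(
            values=pd.DataFrame(
                rng.normal(size=scores.values.shape),
                index=scores.values.index, columns=scores.values.columns,
            ),
            method="OE",
        )
        acc = sp.evaluate_external(result, noise, labels)
        assert abs(acc - 0.2) < 0.15

    def test_missing_module_named_in_error(self):
        scores, labels = cluster_scores(seed=13)
        result = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=0,
                                   spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        reduced = ScoreMatrix(values=scores.values.drop(index="mod3"), method="OE")
        with pytest.raises(ValueError, match="mod3"):
            sp.evaluate_external(result, reduced, labels)


class TestGiniImportance:
    def test_descending_with_identifier_tiebreak(self):
        scores, labels = cluster_scores(seed=14)
        result = sp.cross_validate(scores, labels, folds=5, repeats=1, seed=0,
                                   spec=sp.ModelSpec(fixed={"n_estimators": 50}))
        imp = sp.gini_importance(result, top_k=6)
        assert list(imp) == sorted(imp, reverse=True)

    def test_non_forest_model_rejected(self):
        scores, labels = cluster_scores(seed=15)
        result = sp.cross_validate(
            scores, labels, spec=sp.ModelSpec(family="linear_svm", grid={"C": [1.0]}),
            folds=5, repeats=1, seed=0,
        )
        with pytest.raises(ValueError, match="random_forest"):
            sp.gini_importance(result)

    def test_noise_rankings_unstable_across_seeds(self):
        # with no signal anywhere, two seeded simulations should not agree on
        # which modules matter
        n_modules, n_samples = 40, 100
        ranks = []
        for seed in (0, 1):
            rng = np.random.default_rng(16 + seed)
            values = pd.DataFrame(
                rng.normal(size=(n_modules, n_samples)),
                index=[f"mod{j}" for j in range(n_modules)],
                columns=[f"s{i}" for i in range(n_samples)],
            )
            labels = pd.Series(["a", "b"] * (n_samples // 2), index=values.columns)
            res = sp.cross_validate(
                ScoreMatrix(values=values, method="OE"), labels,
                folds=5, repeats=1, seed=seed,
                spec=sp.ModelSpec(grid={"mtry": [6]}, fixed={"n_estimators": 100}),
            )
            ranks.append(res.importance.rank())
        rho = np.corrcoef(ranks[0], ranks[1])[0, 1]
        assert rho < 0.5
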