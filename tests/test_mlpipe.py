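import numpy as np
import pandas as pd
import pytest

from strkin import (
    Hyperparameters,
    ModelMetrics,
    assemble_offspring_only,
    assemble_pair_dataset,
    benchmark_models,
    evaluate,
    feature_importance,
    grid_search,
    normalize_frequencies,
    pca_summary,
    simulate_cohort,
    split_dataset,
    synth_frequency_table,
    train_classifier,
)
from strkin.datasets import INCEST_LABEL, NORMAL_LABEL, LabeledDataset


def toy_dataset(n=400, informative=True, seed=0, n_noise_markers=3):
    """Categorical dataset where marker M1 carries the class signal."""
    rng = np.random.default_rng(seed)
    half = n // 2
    labels = np.array([NORMAL_LABEL] * half + [INCEST_LABEL] * half)
    cols = {}
    sig = np.where(labels == INCEST_LABEL, "9", "8") if informative else rng.choice(
        ["8", "9"], size=n
    )
    cols["child_M1_1"] = sig
    cols["child_M1_2"] = sig
    for m in range(2, 2 + n_noise_markers):
        for slot in (1, 2):
            cols[f"child_M{m}_{slot}"] = rng.choice(["10", "11", "12"], size=n)
    df = pd.DataFrame(cols)
    for c in df.columns:
        df[c] = df[c].astype("category")
    df["label"] = labels
    markers = tuple(f"M{m}" for m in range(1, 2 + n_noise_markers))
    ds = LabeledDataset(df, markers, tuple(cols.keys()), "offspring-only")
    return split_dataset(ds, (0.6, 0.2, 0.2), seed=seed)


@pytest.fixture(scope="module")
def trained_toy():
    ds = toy_dataset()
    hp = Hyperparameters(iterations=50, depth=3, early_stopping_rounds=10)
    model = train_classifier(ds.partition("train"), ds.partition("validation"), hp, seed=1)
    return ds, model


class TestModelMetrics:
    @pytest.mark.parametrize("counts", [(40, 5, 7, 48), (1, 2, 3, 4), (100, 0, 0, 100)])
    def test_scalars_match_sklearn_oracles(self, counts):
        """Every panel scalar recomputes from the stored confusion matrix and
        agrees with sklearn's implementations on reconstructed label vectors."""
        from sklearn.metrics import (
            accuracy_score,
            balanced_accuracy_score,
            cohen_kappa_score,
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        tp, fp, fn, tn = counts
        y_true = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
        y_pred = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
        m = ModelMetrics.from_predictions(y_true, y_pred)
        assert m.confusion() == {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        assert abs(m.accuracy - accuracy_score(y_true, y_pred)) < 1e-12
        assert abs(m.balanced_accuracy - balanced_accuracy_score(y_true, y_pred)) < 1e-12
        assert abs(m.precision - precision_score(y_true, y_pred)) < 1e-12
        assert abs(m.recall - recall_score(y_true, y_pred)) < 1e-12
        assert abs(m.f1 - f1_score(y_true, y_pred)) < 1e-12
        assert abs(m.mcc - matthews_corrcoef(y_true, y_pred)) < 1e-12
        assert abs(m.kappa - cohen_kappa_score(y_true, y_pred)) < 1e-12
        assert abs(m.balanced_accuracy - (m.recall + m.specificity) / 2) < 1e-12
        assert abs(m.fpr - (1 - m.specificity)) < 1e-12

    def test_auc_trapezoid_equals_rank_statistic(self, rng):
        """ROC AUC from the curve equals the Mann-Whitney U statistic."""
        from scipy.stats import mannwhitneyu
        from sklearn.metrics import auc, roc_curve

        y = rng.integers(0, 2, size=300)
        y[:5], y[5:10] = 1, 0  # both classes present
        scores = rng.normal(size=300) + y
        m = ModelMetrics.from_predictions(y, (scores > 0.5).astype(int), scores)
        fpr, tpr, _ = roc_curve(y, scores)
        trap = auc(fpr, tpr)
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        rank_auc = u / ((y == 1).sum() * (y == 0).sum())
        assert abs(m.roc_auc - trap) < 1e-9
        assert abs(m.roc_auc - rank_auc) < 1e-9

    def test_perfect_predictions(self):
        m = ModelMetrics(tp=50, fp=0, fn=0, tn=50)
        assert m.accuracy == 1.0
        assert m.mcc == 1.0
        assert m.kappa == 1.0
        assert m.fpr == 0.0

    def test_constant_prediction_on_balanced_data(self):
        m = ModelMetrics(tp=50, fp=50, fn=0, tn=0)
        assert m.balanced_accuracy == 0.5
        assert m.mcc == 0.0
        assert m.kappa == 0.0


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self, trained_toy):
        ds, model = trained_toy
        val = ds.partition("validation")
        assert (model.predict(val.X) == val.y).mean() == 1.0

    def test_permuted_labels_give_chance_auc(self):
        ds = toy_dataset(informative=False, seed=3)
        hp = Hyperparameters(iterations=30, depth=3, early_stopping_rounds=10)
        model = train_classifier(ds.partition("train"), ds.partition("validation"), hp, seed=1)
        m = evaluate(model, ds.partition("test"))
        assert 0.3 < m.roc_auc < 0.7

    def test_single_class_rejected(self):
        ds = toy_dataset()
        df = ds.df[ds.df["label"] == NORMAL_LABEL].reset_index(drop=True)
        single = LabeledDataset(df, ds.markers, ds.feature_columns, ds.design)
        single = split_dataset(single, (0.6, 0.2, 0.2), seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(
                single.partition("train"), single.partition("validation"), seed=1
            )

    def test_training_is_deterministic(self):
        ds = toy_dataset(seed=5)
        hp = Hyperparameters(iterations=30, depth=3, early_stopping_rounds=10)
        test = ds.partition("test")
        preds = []
        for _ in range(2):
            model = train_classifier(
                ds.partition("train"), ds.partition("validation"), hp, seed=9
            )
            preds.append(model.predict_proba(test.X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_evaluate_empty_test_rejected(self, trained_toy):
        ds, model = trained_toy
        empty = LabeledDataset(
            ds.df.iloc[:0].copy(), ds.markers, ds.feature_columns, ds.design
        )
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, empty)

    def test_model_round_trips_through_save(self, trained_toy, tmp_path):
        ds, model = trained_toy
        model.save(tmp_path)
        assert (tmp_path / "model.txt").exists()
        assert (tmp_path / "model_manifest.json").exists()


class TestGridSearch:
    def test_single_cell_returned(self):
        ds = toy_dataset(seed=2)
        grid = {"iterations": [25], "learning_rate": [0.2], "depth": [3]}
        best, scores = grid_search(
            ds.partition("train"), ds.partition("validation"), grid, seed=1
        )
        assert best.iterations == 25
        assert best.learning_rate == 0.2
        assert best.depth == 3
        assert len(scores) == 1

    def test_full_grid_has_eight_cells(self):
        ds = toy_dataset(seed=2)
        grid = {"iterations": [10, 20], "learning_rate": [0.05, 0.2], "depth": [2, 3]}
        best, scores = grid_search(
            ds.partition("train"), ds.partition("validation"), grid, seed=1
        )
        assert len(scores) == 8
        assert scores["validation_auc"].between(0, 1).all()

    def test_tie_break_prefers_smaller_model(self):
        # perfectly separable data ties every cell at AUC 1.0
        ds = toy_dataset(seed=2)
        grid = {"iterations": [10, 20], "learning_rate": [0.2], "depth": [2, 3]}
        best, _ = grid_search(
            ds.partition("train"), ds.partition("validation"), grid, seed=1
        )
        assert best.iterations == 10
        assert best.depth == 2

    def test_empty_grid_rejected(self):
        ds = toy_dataset(seed=2)
        with pytest.raises(ValueError, match="grid"):
            grid_search(ds.partition("train"), ds.partition("validation"), {}, seed=1)


class TestFeatureImportance:
    def test_planted_marker_ranks_first_and_sums_to_100(self, trained_toy):
        ds, model = trained_toy
        imp = feature_importance(model)
        assert imp.iloc[0]["marker"] == "M1"
        assert imp["importance"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_unfitted_model_rejected(self):
        from strkin.mlpipe import KinshipClassifier

        model = KinshipClassifier(object(), ("child_M1_1",), Hyperparameters(), 0)
        with pytest.raises(ValueError, match="not fitted"):
            feature_importance(model)


class TestPCA:
    def test_ratios_descending_and_bounded(self):
        ds = toy_dataset(seed=4)
        ratios, coords = pca_summary(ds, n_components=3)
        assert np.all(np.diff(ratios) <= 1e-12)
        assert ratios.sum() <= 1.0 + 1e-9
        assert set(coords.columns) == {"PC1", "PC2", "PC3", "label"}
        assert len(coords) == len(ds)

    def test_duplicate_feature_adds_no_second_component(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "child_M1_1": x,
                "child_M1_2": x,  # perfect duplicate
                "label": [NORMAL_LABEL] * 200,
            }
        )
        ds = LabeledDataset(df, ("M1",), ("child_M1_1", "child_M1_2"), "offspring-only")
        ratios, _ = pca_summary(ds, n_components=2)
        assert ratios[0] == pytest.approx(1.0, abs=1e-9)
        assert ratios[1] == pytest.approx(0.0, abs=1e-9)

    def test_too_many_components_rejected(self):
        ds = toy_dataset(seed=4)
        with pytest.raises(ValueError, match="n_components"):
            pca_summary(ds, n_components=100)


class TestBenchmark:
    def test_single_learner_single_row(self):
        ds = toy_dataset(seed=6)
        out = benchmark_models(
            ds.partition("train"), ds.partition("test"), ["Naive Bayes"], seed=1
        )
        assert list(out["learner"]) == ["Naive Bayes"]
        assert out.iloc[0]["accuracy"] > 0.9  # separable toy

    def test_unavailable_learner_skipped_with_warning(self):
        ds = toy_dataset(seed=6)
        with pytest.warns(UserWarning, match="CatBoost"):
            out = benchmark_models(
                ds.partition("train"), ds.partition("test"), ["CatBoost", "Naive Bayes"], seed=1
            )
        assert "CatBoost" in out.attrs["skipped"]
        assert list(out["learner"]) == ["Naive Bayes"]

    def test_deterministic(self):
        ds = toy_dataset(seed=6)
        args = (ds.partition("train"), ds.partition("test"), ["Random forest"])
        a = benchmark_models(*args, seed=3)
        b = benchmark_models(*args, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_learner_rejected(self):
        ds = toy_dataset(seed=6)
        with pytest.raises(ValueError, match="unknown"):
            benchmark_models(ds.partition("train"), ds.partition("test"), ["Oracle"], seed=1)


@pytest.fixture(scope="module")
def cohort29ml():
    t = normalize_frequencies(synth_frequency_table(29, 8, 1.0, seed=13))
    return simulate_cohort(t, 1200, seed=4)


class TestSignalProperties:
    def test_more_markers_do_not_hurt(self, cohort29ml):
        """Test accuracy is non-decreasing in marker-panel size."""
        hp = Hyperparameters(iterations=300, early_stopping_rounds=30)
        accs = {}
        for markers in (cohort29ml.panel.loci, cohort29ml.panel.loci[:21]):
            ds = split_dataset(
                assemble_pair_dataset(cohort29ml, markers=markers, seed=1), seed=1
            )
            model = train_classifier(
                ds.partition("train"), ds.partition("validation"), hp, seed=1
            )
            accs[len(markers)] = evaluate(model, ds.partition("test")).accuracy
        assert accs[29] >= accs[21] - 0.01

    def test_offspring_only_less_informative_than_pairs(self, cohort29ml):
        """With leakage-free family-grouped partitions the mother+child model
        outperforms the child-only model on the same cohort."""
        hp = Hyperparameters(iterations=300, early_stopping_rounds=30)
        accs = {}
        for name, builder in (
            ("pair", assemble_pair_dataset),
            ("offspring", assemble_offspring_only),
        ):
            ds = split_dataset(builder(cohort29ml, seed=1), seed=1, group="family")
            model = train_classifier(
                ds.partition("train"), ds.partition("validation"), hp, seed=1
            )
            accs[name] = evaluate(model, ds.partition("test")).accuracy
        assert accs["pair"] > accs["offspring"]
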