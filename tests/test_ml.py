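import math

import numpy as np
import pandas as pd
import pytest

from ppisasa.fixtures import SyntheticTableSpec, make_descriptor_table
from ppisasa.ml import (
    FAMILIES,
    ConfusionTable,
    ModelSpec,
    SplitSpec,
    confusion_metrics,
    cross_validate,
    descriptor_importance,
    evaluate_model,
    fit_model,
    predict_and_enrich,
    stratified_split,
)


def oracle_confusion(tp, tn, fp, fn):
    """Independent direct-formula evaluation of the eight statistics."""
    n = tp + tn + fp + fn
    out = {}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["concordance"] = (tp + tn) / n if n else None
    out["youden_j"] = (
        out["sensitivity"] + out["specificity"] - 1
        if out["sensitivity"] is not None and out["specificity"] is not None
        else None
    )
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / den if den else None
    if out["precision"] is not None and out["sensitivity"] is not None:
        ps = out["precision"] + out["sensitivity"]
        out["f1"] = 2 * out["precision"] * out["sensitivity"] / ps if ps else None
    else:
        out["f1"] = None
    if n:
        p_o = (tp + tn) / n
        p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
        out["kappa"] = (p_o - p_e) / (1 - p_e) if p_e != 1 else None
    else:
        out["kappa"] = None
    return out


class TestConfusionMetrics:
    def test_perfect_table(self):
        m = confusion_metrics(ConfusionTable(tp=50, tn=40, fp=0, fn=0))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 1.0
        assert m["youden_j"] == 1.0
        assert m["mcc"] == 1.0
        assert m["kappa"] == 1.0

    def test_undefined_specificity(self):
        m = confusion_metrics(ConfusionTable(tp=8, fn=2, tn=0, fp=0))
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] is None

    def test_hand_example(self):
        m = confusion_metrics(ConfusionTable(tp=30, tn=50, fp=10, fn=10))
        expected = oracle_confusion(30, 50, 10, 10)
        for key, value in expected.items():
            assert m[key] == pytest.approx(value), key

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, tn=0, fp=0, fn=0)

    def test_exhaustive_small_sweep(self):
        # 6^4 = 1296 tables; agree with the independent oracle everywhere
        for tp in range(6):
            for tn in range(6):
                for fp in range(6):
                    for fn in range(6):
                        ours = confusion_metrics(ConfusionTable(tp=tp, tn=tn, fp=fp, fn=fn))
                        theirs = oracle_confusion(tp, tn, fp, fn)
                        for key in theirs:
                            if theirs[key] is None:
                                assert ours[key] is None, (key, tp, tn, fp, fn)
                            else:
                                assert ours[key] == pytest.approx(theirs[key]), (
                                    key, tp, tn, fp, fn,
                                )


def _table(n_active=100, n_inactive=900, effect=3.0, seed=0, n_informative=10):
    return make_descriptor_table(
        SyntheticTableSpec(
            n_active=n_active,
            n_inactive=n_inactive,
            n_informative=n_informative,
            effect_size=effect,
            seed=seed,
        )
    )


class TestStratifiedSplit:
    def test_exact_proportions(self):
        table = _table(100, 900)
        train, test = stratified_split(table, SplitSpec(seed=1))
        assert train["label"].sum() == 70
        assert test["label"].sum() == 30
        assert len(train) == 700 and len(test) == 300

    def test_deterministic(self):
        table = _table(50, 200)
        a_train, _ = stratified_split(table, SplitSpec(seed=7))
        b_train, _ = stratified_split(table, SplitSpec(seed=7))
        pd.testing.assert_frame_equal(a_train, b_train)

    def test_rounding_within_one(self):
        table = _table(101, 200)
        train, test = stratified_split(table, SplitSpec(seed=2))
        assert train["label"].sum() in (70, 71)
        assert train["label"].sum() + test["label"].sum() == 101
        assert len(train) + len(test) == 301
        assert set(train.index).isdisjoint(test.index)

    def test_single_class_rejected(self):
        table = _table(10, 10)
        table["label"] = 1
        with pytest.raises(ValueError):
            stratified_split(table, SplitSpec())

    def test_tiny_class_rejected(self):
        table = _table(2, 20)
        table = table[table["label"] == 0].head(20).assign(label=0)
        table.loc[table.index[0], "label"] = 1
        with pytest.raises(ValueError):
            stratified_split(table, SplitSpec())


@pytest.mark.parametrize("family", FAMILIES)
def test_separable_data_high_training_accuracy(family):
    # construction guarantees near-separability (effect size 6)
    table = _table(60, 140, effect=6.0, seed=3)
    hp = {"max_iter": 300} if "neural" in family else {}
    if family == "random_forest":
        hp["n_estimators"] = 50
    model = fit_model(ModelSpec(family=family, seed=0, hyperparameters=hp), table)
    accuracy = (model.predict(table) == table["label"].to_numpy()).mean()
    assert accuracy >= 0.95


class TestFitModel:
    def test_constant_labels_rejected(self):
        table = _table(20, 20)
        table["label"] = 0
        with pytest.raises(ValueError):
            fit_model(ModelSpec(family="tree"), table)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(family="gradient_boosting")

    def test_deterministic_predictions(self):
        table = _table(40, 160, seed=4)
        spec = ModelSpec(family="random_forest", hyperparameters={"n_estimators": 30}, seed=9)
        p1 = fit_model(spec, table).predict_proba(table)
        p2 = fit_model(spec, table).predict_proba(table)
        np.testing.assert_array_equal(p1, p2)

    def test_class_weighting_helps_sensitivity(self):
        # weighted fit on an 8:1 imbalanced set vs unweighted counterpart
        from sklearn.linear_model import LogisticRegression

        sens_weighted, sens_plain = [], []
        for seed in range(10):
            table = _table(40, 320, effect=1.0, seed=seed)
            train, test = stratified_split(table, SplitSpec(seed=seed))
            model = fit_model(ModelSpec(family="logistic_regression", seed=seed), train)
            y = test["label"].to_numpy()
            pred = model.predict(test)
            tp, fn = ((pred == 1) & (y == 1)).sum(), ((pred == 0) & (y == 1)).sum()
            sens_weighted.append(tp / (tp + fn))
            Xtr = model.scaler.transform(train[model.feature_names].to_numpy(float))
            Xte = model.scaler.transform(test[model.feature_names].to_numpy(float))
            plain = LogisticRegression(max_iter=1000, random_state=seed).fit(
                Xtr, train["label"].astype(int)
            )
            pred0 = plain.predict(Xte)
            tp0, fn0 = ((pred0 == 1) & (y == 1)).sum(), ((pred0 == 0) & (y == 1)).sum()
            sens_plain.append(tp0 / (tp0 + fn0))
        assert np.mean(sens_weighted) >= np.mean(sens_plain)


class TestCrossValidate:
    def test_folds_disjoint_exhaustive(self):
        table = _table(100, 900, seed=5)
        spec = ModelSpec(family="tree", seed=0)
        result = cross_validate(spec, table, k=10)
        assert len(result["folds"]) == 10
        assert result["summary"]["auc"]["mean"] is not None

    def test_k_exceeding_class_rejected(self):
        table = _table(5, 95, seed=6)
        with pytest.raises(ValueError):
            cross_validate(ModelSpec(family="tree"), table, k=10)

    def test_separated_classes_high_auc(self):
        table = _table(60, 540, effect=3.0, seed=7)
        spec = ModelSpec(
            family="random_forest", hyperparameters={"n_estimators": 60}, seed=0
        )
        result = cross_validate(spec, table, k=5)
        assert result["summary"]["auc"]["mean"] >= 0.95


class TestPredictAndEnrich:
    def test_perfect_model_max_ef(self):
        table = _table(50, 50, effect=8.0, seed=8)
        train, test = stratified_split(table, SplitSpec(seed=0))
        model = fit_model(ModelSpec(family="logistic_regression", seed=0), train)
        metrics = predict_and_enrich(model, test, fractions=(0.2,))
        active_rate = test["label"].mean()
        assert metrics.ef[0.2] == pytest.approx(1 / active_rate, rel=0.01)

    def test_constant_probability_deterministic(self):
        table = _table(30, 70, seed=9)
        train, test = stratified_split(table, SplitSpec(seed=0))
        model = fit_model(ModelSpec(family="tree", seed=0), train)
        m1 = predict_and_enrich(model, test)
        m2 = predict_and_enrich(model, test)
        assert m1.ef == m2.ef and m1.bedroc == m2.bedroc


class TestDescriptorImportance:
    def test_informative_column_top_ranked(self):
        table = _table(80, 320, effect=4.0, seed=10, n_informative=1)
        from ppisasa.descriptors import descriptor_names

        informative = descriptor_names()[0]
        model = fit_model(
            ModelSpec(family="random_forest", hyperparameters={"n_estimators": 60}, seed=0),
            table,
        )
        importance = descriptor_importance(model, table, n_permutations=3, seed=0)
        assert importance.index[0] == informative

    def test_uninformative_near_zero(self):
        table = _table(200, 800, effect=3.0, seed=11, n_informative=1)
        model = fit_model(ModelSpec(family="logistic_regression", seed=0), table)
        importance = descriptor_importance(model, table, n_permutations=3, seed=0)
        from ppisasa.descriptors import descriptor_names

        uninformative = descriptor_names()[40]
        assert importance[uninformative] < 0.02

    def test_duplicate_informative_both_positive(self):
        table = _table(100, 400, effect=4.0, seed=12, n_informative=1)
        from ppisasa.descriptors import descriptor_names

        names = descriptor_names()
        table[names[1]] = table[names[0]] + np.random.default_rng(0).normal(
            0, 0.01, len(table)
        )
        model = fit_model(ModelSpec(family="naive_bayes", seed=0), table)
        importance = descriptor_importance(model, table, n_permutations=3, seed=1)
        assert importance[names[0]] > 0
        assert importance[names[1]] > 0


def test_evaluate_model_report_fields():
    table = _table(50, 200, seed=13)
    train, test = stratified_split(table, SplitSpec(seed=0))
    model = fit_model(ModelSpec(family="tree", seed=0), train)
    report = evaluate_model(model, test)
    assert set(report) >= {
        "auc", "sensitivity", "specificity", "precision", "concordance",
        "youden_j", "mcc", "f1", "kappa", "confusion",
    }
    ct = report["confusion"]
    assert ct["tp"] + ct["tn"] + ct["fp"] + ct["fn"] == len(test)
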