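"""Classifier families over descriptor tables.

Eight families with published-default hyperparameters: single Gini tree
(max depth 20, min 10 samples per split), bagged forest of 10 such trees,
random forest (500 trees, 9 candidate features per split), Gaussian naive
Bayes, RBF-kernel C-SVM (C = 1, gamma = 0.0125), logistic regression (GLM),
a two-hidden-layer (80 + 80) SGD neural net (learning rate 0.1, momentum
0.9, max 5000 iterations), and a 10-member bagging ensemble of that net.

Class imbalance is handled "by class": tree/forest/SVM/logistic use
balanced class weights, naive Bayes uses balanced sample weights, and the
neural-net families (which accept neither) use seeded balanced minority
oversampling.  Descriptors are min-max normalized on the training partition
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import UndefinedMetricError, roc_auc, screen_metrics

FAMILIES = (
    "tree",
    "bagged_forest",
    "random_forest",
    "naive_bayes",
    "svm",
    "logistic_regression",
    "neural_net",
    "neural_net_bagging",
)

_OVERSAMPLED_FAMILIES = ("naive_bayes", "neural_net", "neural_net_bagging")


@dataclass
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class SplitSpec:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ConfusionTable:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(ct: ConfusionTable) -> dict[str, float | None]:
    """Sensitivity, specificity, precision, concordance, Youden J, MCC, F1
    and Cohen's kappa from a 2x2 table.  A zero denominator yields None
    (undefined), never 0."""
    tp, tn, fp, fn = ct.tp, ct.tn, ct.fp, ct.fn
    n = ct.total

    def ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    conc = ratio(tp + tn, n)
    youden = sens + spec - 1 if sens is not None and spec is not None else None
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None
    f1 = (
        2 * prec * sens / (prec + sens)
        if prec is not None and sens is not None and (prec + sens) > 0
        else None
    )
    kappa = None
    if n > 0:
        p_o = (tp + tn) / n
        p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
        kappa = (p_o - p_e) / (1 - p_e) if p_e != 1 else None
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "concordance": conc,
        "youden_j": youden,
        "mcc": mcc,
        "f1": f1,
        "kappa": kappa,
    }


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec, label_column: str = "label"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified train/test partition of a labeled table."""
    labels = table[label_column].astype(int)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes required for a stratified split")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    train_idx, test_idx = train_test_split(
        table.index.to_numpy(),
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    return table.loc[np.sort(train_idx)], table.loc[np.sort(test_idx)]


def _build_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    tree_kwargs = dict(
        criterion="gini",
        max_depth=hp.pop("max_depth", 20),
        min_samples_split=hp.pop("min_samples_split", 10),
        class_weight="balanced",
        random_state=seed,
    )
    if spec.family == "tree":
        return DecisionTreeClassifier(**tree_kwargs)
    if spec.family == "bagged_forest":
        n = hp.pop("n_estimators", 10)
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(**tree_kwargs),
            n_estimators=n,
            bootstrap=True,
            random_state=seed,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            max_features=hp.pop("max_features", 9),
            criterion="gini",
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "naive_bayes":
        return GaussianNB()
    if spec.family == "svm":
        return SVC(
            C=hp.pop("C", 1.0),
            kernel="rbf",
            gamma=hp.pop("gamma", 0.0125),
            class_weight="balanced",
            probability=True,
            random_state=seed,
        )
    if spec.family == "logistic_regression":
        return LogisticRegression(
            class_weight="balanced", max_iter=hp.pop("max_iter", 1000), random_state=seed
        )
    mlp = MLPClassifier(
        hidden_layer_sizes=hp.pop("hidden_layer_sizes", (80, 80)),
        solver="sgd",
        learning_rate_init=hp.pop("learning_rate", 0.1),
        momentum=hp.pop("momentum", 0.9),
        max_iter=hp.pop("max_iter", 5000),
        alpha=hp.pop("alpha", 1e-4),
        n_iter_no_change=hp.pop("n_iter_no_change", 25),
        tol=1e-4,
        random_state=seed,
    )
    if spec.family == "neural_net":
        return mlp
    # neural_net_bagging: ensemble size default 10
    return BaggingClassifier(
        estimator=mlp, n_estimators=hp.pop("n_estimators", 10), random_state=seed
    )


def _balance_by_oversampling(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    counts = np.bincount(y, minlength=2)
    minority = int(np.argmin(counts))
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: object
    scaler: MinMaxScaler
    feature_names: list[str]
    threshold: float = 0.5

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Probability-like score for class 1."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        Xs = self.scaler.transform(X)
        proba = self.estimator.predict_proba(Xs)
        class_index = list(self.estimator.classes_).index(1)
        return proba[:, class_index]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


def _extract_xy(
    table: pd.DataFrame, feature_names: Sequence[str] | None, label_column: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if feature_names is None:
        skip = {label_column, "compound_id", "pose_id", "n_imputed"}
        feature_names = [
            c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])
        ]
    X = table[list(feature_names)].to_numpy(dtype=float)
    y = table[label_column].astype(int).to_numpy()
    return X, y, list(feature_names)


def fit_model(
    spec: ModelSpec,
    train: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    label_column: str = "label",
) -> FittedModel:
    """Fit one family on a labeled descriptor table (min-max normalized on
    the training partition, class weighting by class)."""
    X, y, names = _extract_xy(train, feature_names, label_column)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    scaler = MinMaxScaler().fit(X)
    Xs = scaler.transform(X)
    estimator = _build_estimator(spec)
    if spec.family == "naive_bayes":
        weights = len(y) / (2.0 * np.bincount(y, minlength=2))
        estimator.fit(Xs, y, sample_weight=weights[y])
    elif spec.family in ("neural_net", "neural_net_bagging"):
        Xb, yb = _balance_by_oversampling(Xs, y, spec.seed)
        estimator.fit(Xb, yb)
    else:
        estimator.fit(Xs, y)
    return FittedModel(spec=spec, estimator=estimator, scaler=scaler, feature_names=names)


def evaluate_model(
    model: FittedModel, table: pd.DataFrame, label_column: str = "label"
) -> dict:
    """AUC + the eight confusion metrics at the model's threshold."""
    y = table[label_column].astype(int).to_numpy()
    proba = model.predict_proba(table)
    pred = (proba >= model.threshold).astype(int)
    ct = ConfusionTable(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )
    out = {"auc": roc_auc(y, proba)}
    out.update(confusion_metrics(ct))
    out["confusion"] = {"tp": ct.tp, "tn": ct.tn, "fp": ct.fp, "fn": ct.fn}
    return out


def cross_validate(
    spec: ModelSpec,
    train: pd.DataFrame,
    k: int = 10,
    feature_names: Sequence[str] | None = None,
    label_column: str = "label",
) -> dict:
    """Stratified k-fold CV; per-fold AUC/metrics reported as mean +/- SD."""
    y = train[label_column].astype(int).to_numpy()
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(f"k = {k} exceeds minority class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    fold_rows = []
    idx = train.reset_index(drop=True)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = fit_model(spec, idx.iloc[tr], feature_names, label_column)
        result = evaluate_model(model, idx.iloc[te], label_column)
        result.pop("confusion")
        result["fold"] = fold
        fold_rows.append(result)
    folds = pd.DataFrame(fold_rows)
    summary = {}
    for col in folds.columns:
        if col == "fold":
            continue
        vals = folds[col].astype(float).dropna()
        summary[col] = {
            "mean": float(vals.mean()) if len(vals) else None,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
        }
    return {"folds": folds, "summary": summary}


def predict_and_enrich(
    model: FittedModel,
    test: pd.DataFrame,
    fractions: tuple[float, ...] = (0.01, 0.05),
    alpha: float = 20.0,
    label_column: str = "label",
):
    """Rank the test set by class-1 probability and compute screen metrics."""
    y = test[label_column].astype(int).to_numpy()
    proba = model.predict_proba(test)
    ids = (
        test["compound_id"].to_numpy()
        if "compound_id" in test.columns
        else np.arange(len(test))
    )
    return screen_metrics(y, proba, fractions=fractions, alpha=alpha, ids=ids)


def descriptor_importance(
    model: FittedModel,
    table: pd.DataFrame,
    n_permutations: int = 5,
    seed: int = 0,
    label_column: str = "label",
) -> pd.Series:
    """Permutation importance: mean AUC drop per descriptor, floored at 0."""
    rng = np.random.default_rng(seed)
    y = table[label_column].astype(int).to_numpy()
    X = table[model.feature_names].to_numpy(dtype=float)
    baseline = roc_auc(y, model.predict_proba(X))
    importances = {}
    for j, name in enumerate(model.feature_names):
        drops = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - roc_auc(y, model.predict_proba(Xp)))
        importances[name] = max(0.0, float(np.mean(drops)))
    return pd.Series(importances).sort_values(ascending=False)
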