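"""Training, tuning and evaluation of the binary kinship classifier.

The classifier is a gradient-boosted decision-tree model (LightGBM) fit on
categorical allele columns with log-loss, monitored on validation ROC AUC with
early stopping. The positive class is ``IncestKinship`` everywhere: a true
positive is an incest-conceived pair flagged as such.

Besides the main model the module provides the full evaluation panel derived
from one 2x2 confusion matrix (accuracy, balanced accuracy, PPV/precision,
recall/detection rate, specificity, NPV, F1, FPR, FNR, MCC, Cohen's kappa)
plus ranked-score ROC/PR curves, an exhaustive hyperparameter grid search, an
off-the-shelf learner benchmark, marker-level feature importances, and a PCA
summary of the feature space.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .datasets import INCEST_LABEL, LabeledDataset, encode_numeric

__all__ = [
    "Hyperparameters",
    "ModelMetrics",
    "KinshipClassifier",
    "train_classifier",
    "grid_search",
    "evaluate",
    "benchmark_models",
    "feature_importance",
    "pca_summary",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Boosting hyperparameters; defaults are the tuned values (1000 rounds,
    learning rate 0.1, depth 10) with 50-round early stopping on validation
    AUC."""

    iterations: int = 1000
    learning_rate: float = 0.1
    depth: int = 10
    early_stopping_rounds: int = 50
    loss: str = "log-loss"
    eval_metric: str = "auc"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


DEFAULT_GRID = {
    "iterations": [500, 1000],
    "learning_rate": [0.01, 0.1],
    "depth": [6, 10],
}


@dataclass
class ModelMetrics:
    """Evaluation panel for one binary run, anchored to the confusion matrix.

    Matrix orientation: positive class = IncestKinship; ``tp`` counts incest
    pairs called incest, ``tn`` normal pairs called normal. Every scalar is a
    pure function of (tp, fp, fn, tn) except the ranked-score quantities
    (ROC AUC and the ROC/PR curve points).
    """

    tp: int
    fp: int
    fn: int
    tn: int
    roc_auc: float = float("nan")
    roc_points: np.ndarray | None = None  # columns fpr, tpr
    pr_points: np.ndarray | None = None  # columns recall, precision

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def recall(self) -> float:
        """Detection rate / sensitivity."""
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.recall + self.specificity) / 2.0

    @property
    def precision(self) -> float:
        """Positive predictive value."""
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.recall

    @property
    def mcc(self) -> float:
        tp, fp, fn, tn = map(float, (self.tp, self.fp, self.fn, self.tn))
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return (tp * tn - fp * fn) / denom if denom else 0.0

    @property
    def kappa(self) -> float:
        tp, fp, fn, tn = map(float, (self.tp, self.fp, self.fn, self.tn))
        n = tp + fp + fn + tn
        po = (tp + tn) / n
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
        return (po - pe) / (1.0 - pe) if pe != 1.0 else 0.0

    def scalars(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "npv": self.npv,
            "f1": self.f1,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "mcc": self.mcc,
            "kappa": self.kappa,
            "roc_auc": self.roc_auc,
        }

    def confusion(self) -> dict[str, int]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
    ) -> "ModelMetrics":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        m = cls(tp, fp, fn, tn)
        if scores is not None and len(np.unique(y_true)) == 2:
            m.roc_auc = float(roc_auc_score(y_true, scores))
            fpr, tpr, _ = roc_curve(y_true, scores)
            m.roc_points = np.column_stack([fpr, tpr])
            prec, rec, _ = precision_recall_curve(y_true, scores)
            m.pr_points = np.column_stack([rec, prec])
        return m


class KinshipClassifier:
    """LightGBM model plus the feature schema needed to score new tables."""

    def __init__(self, estimator, feature_columns: Sequence[str], hp: Hyperparameters, seed: int):
        self.estimator = estimator
        self.feature_columns = tuple(feature_columns)
        self.hp = hp
        self.seed = seed
        # remember training category sets so prediction frames align by value
        self.categories_: dict[str, list[str]] = {}

    def _align(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.columns) != list(self.feature_columns):
            X = X[list(self.feature_columns)]
        out = {}
        for col in self.feature_columns:
            cats = self.categories_.get(col)
            s = X[col]
            if cats is not None:
                s = s.astype(str).astype(pd.CategoricalDtype(categories=cats))
            out[col] = s
        return pd.DataFrame(out, index=X.index)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive (IncestKinship) class."""
        return self.estimator.predict_proba(self._align(X))[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    @property
    def best_iteration(self) -> int | None:
        return getattr(self.estimator, "best_iteration_", None)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "model.txt").write_text(self.estimator.booster_.model_to_string())
        manifest = {
            "feature_columns": list(self.feature_columns),
            "hyperparameters": asdict(self.hp),
            "seed": self.seed,
            "categories": self.categories_,
            "best_iteration": self.best_iteration,
        }
        (directory / "model_manifest.json").write_text(json.dumps(manifest, indent=2))


def train_classifier(
    train: LabeledDataset,
    validation: LabeledDataset,
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> KinshipClassifier:
    """Fit the gradient-boosted kinship classifier.

    Log-loss objective, validation ROC AUC monitoring, early stopping after
    ``hp.early_stopping_rounds`` rounds without improvement. Raises if the
    training labels are single-class or the validation schema differs.
    """
    import lightgbm as lgb

    hp = hp or Hyperparameters()
    if train.feature_columns != validation.feature_columns:
        raise ValueError("train and validation datasets have different schemas")
    y_train = train.y
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    X_train = train.X
    X_val = validation.X
    est = lgb.LGBMClassifier(
        n_estimators=hp.iterations,
        learning_rate=hp.learning_rate,
        max_depth=hp.depth,
        num_leaves=min(2**hp.depth, 1024),
        objective="binary",
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
    )
    est.fit(
        X_train,
        y_train,
        eval_set=[(X_val, validation.y)],
        eval_metric="auc",
        callbacks=[lgb.early_stopping(hp.early_stopping_rounds, verbose=False)],
    )
    model = KinshipClassifier(est, train.feature_columns, hp, seed)
    model.categories_ = {
        col: list(X_train[col].cat.categories)
        for col in train.feature_columns
        if isinstance(X_train[col].dtype, pd.CategoricalDtype)
    }
    return model


def evaluate(model: KinshipClassifier, test: LabeledDataset) -> ModelMetrics:
    """Score a test partition and derive the full metric panel."""
    if len(test) == 0:
        raise ValueError("empty test set")
    scores = model.predict_proba(test.X)
    y_pred = (scores >= 0.5).astype(int)
    return ModelMetrics.from_predictions(test.y, y_pred, scores)


def grid_search(
    train: LabeledDataset,
    validation: LabeledDataset,
    grid: dict[str, Sequence] | None = None,
    seed: int = 0,
) -> tuple[Hyperparameters, pd.DataFrame]:
    """Exhaustively score every grid cell on validation ROC AUC.

    Ties break deterministically toward fewer iterations, then smaller depth.
    Returns the winning :class:`Hyperparameters` and the per-cell score table.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty hyperparameter grid")
    keys = list(grid.keys())
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        hp = Hyperparameters(**dict(zip(keys, combo)))
        model = train_classifier(train, validation, hp, seed)
        auc = float(
            roc_auc_score(validation.y, model.predict_proba(validation.X))
        )
        rows.append({**dict(zip(keys, combo)), "validation_auc": auc})
    scores = pd.DataFrame(rows)
    best_row = scores.sort_values(
        by=["validation_auc", "iterations", "depth"],
        ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    best = Hyperparameters(
        **{k: best_row[k] for k in keys if k in Hyperparameters.__dataclass_fields__}
    )
    return best, scores


# ---------------------------------------------------------------------------
# off-the-shelf learner benchmark


def _learner_registry(seed: int) -> dict[str, Callable[[], object]]:
    def _catboost():
        from catboost import CatBoostClassifier  # noqa: F401 - optional

        return CatBoostClassifier(verbose=0, random_seed=seed)

    def _lightgbm():
        import lightgbm as lgb

        return lgb.LGBMClassifier(random_state=seed, verbose=-1)

    def _xgboost():
        import xgboost as xgb

        return xgb.XGBClassifier(random_state=seed, verbosity=0)

    from sklearn.ensemble import (
        AdaBoostClassifier,
        ExtraTreesClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
    )
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    return {
        "Random forest": lambda: RandomForestClassifier(random_state=seed),
        "Support vector machine": lambda: SVC(random_state=seed),
        "Naive Bayes": lambda: GaussianNB(),
        "K-Nearest Neighbors": lambda: KNeighborsClassifier(),
        "CatBoost": _catboost,
        "XGBoost": _xgboost,
        "LightGBM": _lightgbm,
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "Gradient boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "Extra trees": lambda: ExtraTreesClassifier(random_state=seed),
        "Multi-layer Perceptron": lambda: MLPClassifier(random_state=seed, max_iter=300),
    }


def benchmark_models(
    train: LabeledDataset,
    test: LabeledDataset,
    learners: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a panel of off-the-shelf learners (library defaults) on the same
    split and report accuracy, precision, recall, F1 and ROC AUC per learner.

    Features are numerically encoded (allele repeat values) so every sklearn
    learner can consume them. Learners whose import fails are skipped with a
    warning and listed in the result's ``attrs["skipped"]``.
    """
    registry = _learner_registry(seed)
    names = list(learners) if learners is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise ValueError(f"unknown learners {unknown!r}")
    X_train = encode_numeric(train.X).to_numpy(dtype=float)
    X_test = encode_numeric(test.X).to_numpy(dtype=float)
    y_train, y_test = train.y, test.y
    rows, skipped = [], []
    for name in names:
        try:
            est = registry[name]()
        except ImportError as exc:
            warnings.warn(f"learner {name!r} unavailable, skipped: {exc}")
            skipped.append(name)
            continue
        est.fit(X_train, y_train)
        y_pred = est.predict(X_test)
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X_test)[:, 1]
        else:
            scores = est.decision_function(X_test)
        m = ModelMetrics.from_predictions(y_test, y_pred, scores)
        rows.append(
            {
                "learner": name,
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "roc_auc": m.roc_auc,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def feature_importance(
    model: KinshipClassifier, marker_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Marker-level importances: per-feature gains summed over each marker's
    allele columns, normalized to 100, sorted descending."""
    est = model.estimator
    if not hasattr(est, "booster_"):
        raise ValueError("model is not fitted")
    gains = est.booster_.feature_importance(importance_type="gain")
    per_marker: dict[str, float] = {}
    for col, gain in zip(model.feature_columns, gains):
        # columns follow <prefix><locus>_<slot>
        base = col.rsplit("_", 1)[0]
        marker = base.split("_", 1)[1] if "_" in base else base
        per_marker[marker] = per_marker.get(marker, 0.0) + float(gain)
    if marker_names is not None:
        missing = [m for m in marker_names if m not in per_marker]
        if missing:
            raise KeyError(f"markers {missing!r} not among model features")
        per_marker = {m: per_marker[m] for m in marker_names}
    total = sum(per_marker.values())
    if total <= 0:
        raise ValueError("model reports zero total importance")
    df = pd.DataFrame(
        {"marker": list(per_marker), "importance": [100.0 * v / total for v in per_marker.values()]}
    )
    return df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


def pca_summary(
    ds: LabeledDataset, n_components: int = 2, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Standardized principal-component decomposition of the feature table.

    Returns the explained-variance ratios (descending) and per-row coordinates
    with the kinship label attached.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    if n_components > len(ds.feature_columns):
        raise ValueError(
            f"n_components={n_components} exceeds {len(ds.feature_columns)} features"
        )
    X = StandardScaler().fit_transform(encode_numeric(ds.X).to_numpy(dtype=float))
    pca = PCA(n_components=n_components, random_state=seed)
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    frame["label"] = ds.labels.to_numpy()
    return pca.explained_variance_ratio_, frame
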