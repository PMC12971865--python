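"""Visual-behavior level prediction under leave-one-out cross-validation.

Four classifier families are supported -- random forest (RF), RBF-kernel
support vector machine (SVM), a single classification tree (CART) and a
small multilayer perceptron (ANN).  Hyperparameter defaults are
documented design choices, all overridable through :class:`ModelSpec`.
Features are z-scaled inside each training fold for the margin/gradient
families (SVM, ANN); tree families use raw features.

Feature influence is ranked with the random forest's Gini importance
(normalized mean decrease in node impurity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from gazeskill.metrics import FEATURE_COLUMNS

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "PredictionReport",
    "build_estimator",
    "loocv_evaluate",
    "gini_importance",
    "compare_models",
]

MODEL_FAMILIES = ("RF", "SVM", "CART", "ANN")

_DEFAULT_PARAMS: dict[str, dict] = {
    "RF": {"n_estimators": 500, "max_depth": None},
    "SVM": {"C": 1.0, "kernel": "rbf", "gamma": "auto"},  # gamma = 1/d
    "CART": {"criterion": "gini", "ccp_alpha": 0.0},
    # lbfgs: the n<=tens regime this targets is too small for sgd/adam
    "ANN": {"hidden_layer_sizes": (8,), "solver": "lbfgs", "max_iter": 2000, "early_stopping": False},
}
_SCALED_FAMILIES = {"SVM", "ANN"}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    scale: bool | None = None  # None -> family default

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {MODEL_FAMILIES}")

    @property
    def scaled(self) -> bool:
        return self.family in _SCALED_FAMILIES if self.scale is None else self.scale


@dataclass
class PredictionReport:
    family: str
    y_true: np.ndarray
    y_pred: np.ndarray
    classes: list
    accuracy: float
    f1: float
    f1_average: str
    confusion: pd.DataFrame
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.y_true.size)


def build_estimator(spec: ModelSpec):
    params = dict(_DEFAULT_PARAMS[spec.family])
    params.update(spec.params)
    if spec.family == "RF":
        est = RandomForestClassifier(random_state=spec.seed, **params)
    elif spec.family == "SVM":
        est = SVC(random_state=spec.seed, **params)
    elif spec.family == "CART":
        est = DecisionTreeClassifier(random_state=spec.seed, **params)
    else:
        est = MLPClassifier(random_state=spec.seed, **params)
    if spec.scaled:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _as_matrix(metrics_table: pd.DataFrame | np.ndarray, features: Sequence[str] | None):
    if isinstance(metrics_table, pd.DataFrame):
        features = list(features or [c for c in FEATURE_COLUMNS if c in metrics_table.columns])
        return metrics_table[features].to_numpy(float), features
    X = np.asarray(metrics_table, dtype=float)
    features = list(features or [f"f{i}" for i in range(X.shape[1])])
    return X, features


def loocv_evaluate(
    metrics_table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    spec: ModelSpec,
    features: Sequence[str] | None = None,
) -> PredictionReport:
    """Leave-one-out evaluation of one classifier family.

    Every sample is held out once; all fitting (including feature
    scaling) happens on the remaining n-1 rows only.  Folds whose
    training split lacks a class are skipped with a warning and excluded
    from the aggregate.  Accuracy is correct/total; F1 is binary for two
    classes and macro-averaged otherwise.
    """
    X, _ = _as_matrix(metrics_table, features)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    if y.size < len(classes) + 1:
        raise ValueError("need at least one more sample than there are classes")
    preds, trues, skipped = [], [], []
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < len(classes):
            skipped.append(i)
            continue
        est = build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
            est.fit(X[mask], y[mask])
        preds.append(est.predict(X[i : i + 1])[0])
        trues.append(y[i])
    if skipped:
        warnings.warn(
            f"{len(skipped)} LOOCV fold(s) skipped (training split missing a class)", UserWarning
        )
    y_true = np.asarray(trues)
    y_pred = np.asarray(preds)
    accuracy = float(np.mean(y_true == y_pred)) if y_true.size else float("nan")
    if len(classes) == 2:
        f1_average = "binary"
        f1 = float(f1_score(y_true, y_pred, average="binary", pos_label=classes[-1], zero_division=0))
    else:
        f1_average = "macro"
        f1 = float(f1_score(y_true, y_pred, average="macro", zero_division=0))
    conf = pd.DataFrame(
        confusion_matrix(y_true, y_pred, labels=classes), index=classes, columns=classes
    )
    return PredictionReport(
        family=spec.family,
        y_true=y_true,
        y_pred=y_pred,
        classes=classes,
        accuracy=accuracy,
        f1=f1,
        f1_average=f1_average,
        confusion=conf,
        skipped_folds=skipped,
    )


def gini_importance(
    metrics_table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    spec: ModelSpec | None = None,
    features: Sequence[str] | None = None,
) -> pd.Series:
    """Normalized Gini (mean decrease in impurity) importances from an RF.

    The forest is fitted on the full data set; the returned Series is
    sorted descending and sums to one.  Rejects non-RF specs.
    """
    spec = spec or ModelSpec("RF")
    if spec.family != "RF":
        raise ValueError("Gini importance requires a random-forest model spec")
    X, names = _as_matrix(metrics_table, features)
    est = build_estimator(ModelSpec("RF", params=spec.params, seed=spec.seed, scale=False))
    est.fit(X, np.asarray(labels))
    imp = np.asarray(est.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=names).sort_values(ascending=False)


def compare_models(
    metrics_table: pd.DataFrame | np.ndarray,
    labels: Sequence,
    specs: Sequence[ModelSpec],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Accuracy/F1 table over several families, best first.

    Sorted by accuracy, ties broken by F1 and then family name;
    deterministic given the specs' seeds.
    """
    if not specs:
        raise ValueError("need at least one model spec")
    rows = []
    for spec in specs:
        rep = loocv_evaluate(metrics_table, labels, spec, features=features)
        rows.append(
            {"family": spec.family, "accuracy": rep.accuracy, "f1": rep.f1, "n": rep.n}
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        by=["accuracy", "f1", "family"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
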