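"""Three-class receptor classification with cross-validated model selection.

Model families: gradient-boosted trees (xgboost, native missing-value
routing), linear SVM, and k-nearest neighbors (both on zero-imputed,
standardized features).  Hyperparameters are chosen on the same stratified
10-fold loop used for evaluation; metrics follow the one-vs-rest
confusion-count formulas (accuracy, precision, recall, F1, averaged
unweighted over classes).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import CLASS_ORDER

FAMILIES = ("gbt", "linear-svm", "knn")

#: Hyperparameter search grids.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gbt": {
        "n_estimators": [100, 300],
        "max_depth": [3, 5],
        "learning_rate": [0.01, 0.03, 0.09],
        "subsample": [0.9, 1.0],
        "colsample_bytree": [0.3, 0.5, 0.9],
        "gamma": [0, 1, 5],
    },
    "linear-svm": {"C": [0.01, 0.1, 1.0, 10.0]},
    "knn": {"k": [3, 5, 7, 9, 11, 13, 15]},
}

#: Reduced grids for quick runs on small synthetic panels.
QUICK_GRIDS: dict[str, dict[str, list]] = {
    "gbt": {
        "n_estimators": [100],
        "max_depth": [3, 5],
        "learning_rate": [0.09],
        "subsample": [1.0],
        "colsample_bytree": [0.5, 0.9],
        "gamma": [0],
    },
    "linear-svm": {"C": [0.1, 1.0]},
    "knn": {"k": [3, 5, 7]},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family plus its hyperparameter grid and seed."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        grid = self.grid or DEFAULT_GRIDS[self.family]
        object.__setattr__(self, "grid", {k: list(v) for k, v in grid.items()})
        if any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("empty hyperparameter grid")
        if self.family == "knn":
            ks = self.grid.get("k", [])
            if any(k < 1 or k % 2 == 0 for k in ks):
                raise ValueError("knn k values must be odd and >= 1")


def _complexity_key(family: str, params: dict) -> tuple:
    """Tie-break ordering: smaller models first."""
    if family == "gbt":
        return (params["n_estimators"], params["max_depth"], params["gamma"],
                params["learning_rate"], params["subsample"], params["colsample_bytree"])
    if family == "knn":
        return (params["k"],)
    return (params["C"],)


def _make_estimator(family: str, params: dict, seed: int):
    if family == "gbt":
        return xgb.XGBClassifier(
            objective="multi:softprob",
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            learning_rate=params["learning_rate"],
            subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"],
            gamma=params["gamma"],
            tree_method="exact",  # hist binning misroutes near-boundary points on small folds
            n_jobs=1,
            random_state=seed,
            eval_metric="mlogloss",
        )
    if family == "linear-svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="linear", C=params["C"], probability=True,
                            random_state=seed)),
            ]
        )
    if family == "knn":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=params["k"], metric="euclidean")),
            ]
        )
    raise ValueError(family)


def _prepare_X(family: str, features: pd.DataFrame) -> np.ndarray:
    X = features.to_numpy(float)
    if family == "gbt":
        return X  # native missing-branch routing
    return np.nan_to_num(X, nan=0.0)


def encode_labels(labels: pd.Series) -> np.ndarray:
    """Class labels to integers in the fixed order metabolic<inflammatory<other."""
    unknown = set(labels.unique()) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return labels.map({c: i for i, c in enumerate(CLASS_ORDER)}).to_numpy()


# ---------------------------------------------------------------------------
# folds and metrics


def stratified_folds(
    labels: pd.Series, n_folds: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified K-fold partition of the labeled receptors.

    Non-shuffled: folds depend only on label order, so the split is
    reproducible without a random state.  Every class must have at least
    ``n_folds`` members.
    """
    counts = labels.value_counts()
    too_small = counts[counts < n_folds]
    if len(too_small):
        raise ValueError(
            f"class(es) smaller than n_folds={n_folds}: "
            f"{too_small.to_dict()}; use fewer folds"
        )
    y = encode_labels(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = 3) -> pd.DataFrame:
    """One-vs-rest TP/FP/TN/FN counts per class."""
    rows = []
    for c in range(n_classes):
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        tn = int(((y_true != c) & (y_pred != c)).sum())
        rows.append({"class": CLASS_ORDER[c], "TP": tp, "FP": fp, "TN": tn, "FN": fn})
    return pd.DataFrame(rows).set_index("class")


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; metric set to 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(cm: pd.DataFrame) -> dict[str, float]:
    """Per-class one-vs-rest metrics and their unweighted class averages.

    Accuracy = (TP+TN)/n, Recall = TP/(TP+FN), Precision = TP/(TP+FP),
    F1 = TP/(TP + (FP+FN)/2); ``average_accuracy`` is the mean per-class
    accuracy and ``overall_agreement`` the plain fraction of correct
    predictions.
    """
    accs, precs, recs, f1s = [], [], [], []
    n = float(cm.iloc[0][["TP", "FP", "TN", "FN"]].sum())
    for cls, row in cm.iterrows():
        tp, fp, tn, fn = float(row["TP"]), float(row["FP"]), float(row["TN"]), float(row["FN"])
        accs.append(_safe_div(tp + tn, tp + fp + tn + fn, f"accuracy[{cls}]"))
        recs.append(_safe_div(tp, tp + fn, f"recall[{cls}]"))
        precs.append(_safe_div(tp, tp + fp, f"precision[{cls}]"))
        f1s.append(_safe_div(tp, tp + 0.5 * (fp + fn), f"F1[{cls}]"))
    total_tp = float(cm["TP"].sum())
    out = {
        "accuracy": float(np.mean(accs)),
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "f1": float(np.mean(f1s)),
        "average_accuracy": float(np.mean(accs)),
        "overall_agreement": _safe_div(total_tp, n, "overall agreement"),
    }
    for i, cls in enumerate(cm.index):
        out[f"accuracy_{cls}"] = accs[i]
        out[f"precision_{cls}"] = precs[i]
        out[f"recall_{cls}"] = recs[i]
        out[f"f1_{cls}"] = f1s[i]
    return out


# ---------------------------------------------------------------------------
# cross-validated training


@dataclass
class CVResult:
    family: str
    best_params: dict
    grid_table: pd.DataFrame  # one row per grid point with mean/sd accuracy
    fold_metrics: pd.DataFrame  # per-fold metrics for the best grid point
    pooled_confusion: pd.DataFrame
    pooled_metrics: dict[str, float]
    oof_predictions: pd.DataFrame  # receptor, true, predicted, class probabilities

    @property
    def mean_metrics(self) -> dict[str, float]:
        return self.fold_metrics.mean().to_dict()

    @property
    def std_metrics(self) -> dict[str, float]:
        return self.fold_metrics.std(ddof=1).to_dict()

    def misclassification_report(self) -> pd.DataFrame:
        """Labeled receptors whose out-of-fold prediction disagrees with truth."""
        oof = self.oof_predictions
        return oof.loc[oof["true"] != oof["predicted"]].copy()


def _grid_points(spec: ClassifierSpec) -> list[dict]:
    keys = sorted(spec.grid)
    points = [dict(zip(keys, combo)) for combo in itertools.product(*(spec.grid[k] for k in keys))]
    points.sort(key=lambda p: _complexity_key(spec.family, p))
    return points


def _run_cv(
    features: pd.DataFrame,
    y: np.ndarray,
    family: str,
    params: dict,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """One grid point over all folds; returns per-fold metrics, oof labels+probs."""
    X = _prepare_X(family, features)
    n = len(y)
    oof_pred = np.full(n, -1, dtype=int)
    oof_proba = np.full((n, len(CLASS_ORDER)), np.nan)
    fold_rows = []
    for tr, te in folds:
        if len(np.unique(y[tr])) < len(CLASS_ORDER):
            raise ValueError("a training fold is missing a class entirely")
        est = _make_estimator(family, params, seed)
        est.fit(X[tr], y[tr])
        proba = est.predict_proba(X[te])
        pred = np.argmax(proba, axis=1)  # first max wins: fixed class order
        oof_pred[te] = pred
        oof_proba[te] = proba
        fold_rows.append(compute_metrics(confusion_counts(y[te], pred)))
    fold_metrics = pd.DataFrame(fold_rows)
    return fold_metrics, oof_pred, oof_proba


def train_eval(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
    n_folds: int = 10,
) -> CVResult:
    """Grid search + evaluation on one stratified K-fold loop.

    The best grid point maximizes the across-fold mean accuracy; ties go to
    the smaller model (fewer trees, smaller k, smaller C).  Out-of-fold
    predictions of the best point are pooled into one confusion table.
    """
    labels = labels.loc[features.index.intersection(labels.index)]
    features = features.loc[labels.index]
    y = encode_labels(labels)
    if folds is None:
        folds = stratified_folds(labels, n_folds=n_folds)

    best = None
    grid_rows = []
    for params in _grid_points(spec):
        fold_metrics, oof_pred, oof_proba = _run_cv(
            features, y, spec.family, params, folds, spec.seed
        )
        mean_acc = float(fold_metrics["accuracy"].mean())
        grid_rows.append({**params, "mean_accuracy": mean_acc,
                          "sd_accuracy": float(fold_metrics["accuracy"].std(ddof=1))})
        if best is None or mean_acc > best[0]:
            best = (mean_acc, params, fold_metrics, oof_pred, oof_proba)

    _, best_params, fold_metrics, oof_pred, oof_proba = best
    pooled_cm = confusion_counts(y, oof_pred)
    oof = pd.DataFrame(
        {
            "true": [CLASS_ORDER[c] for c in y],
            "predicted": [CLASS_ORDER[c] for c in oof_pred],
            "p_metabolic": oof_proba[:, 0],
            "p_inflammatory": oof_proba[:, 1],
            "p_other": oof_proba[:, 2],
        },
        index=features.index,
    )
    return CVResult(
        family=spec.family,
        best_params=best_params,
        grid_table=pd.DataFrame(grid_rows),
        fold_metrics=fold_metrics,
        pooled_confusion=pooled_cm,
        pooled_metrics=compute_metrics(pooled_cm),
        oof_predictions=oof,
    )


# ---------------------------------------------------------------------------
# final model


@dataclass
class FittedModel:
    """A final estimator plus the feature schema it was trained on."""

    estimator: object
    family: str
    columns: list[str]
    schema_hash: str
    best_params: dict

    def check_schema(self, features: pd.DataFrame) -> None:
        if list(features.columns) != self.columns:
            missing = [c for c in self.columns if c not in features.columns]
            extra = [c for c in features.columns if c not in self.columns]
            raise ValueError(
                f"feature schema mismatch: missing={missing[:5]}, extra={extra[:5]}"
            )

    def predict_proba_table(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-receptor class probabilities, argmax label, and max probability."""
        self.check_schema(features)
        X = _prepare_X(self.family, features)
        proba = self.estimator.predict_proba(X)
        pred = np.argmax(proba, axis=1)
        return pd.DataFrame(
            {
                "p_metabolic": proba[:, 0],
                "p_inflammatory": proba[:, 1],
                "p_other": proba[:, 2],
                "predicted": [CLASS_ORDER[c] for c in pred],
                "max_probability": proba.max(axis=1),
            },
            index=features.index,
        )


def schema_hash(columns: list[str]) -> str:
    return hashlib.sha256("\n".join(columns).encode()).hexdigest()


def fit_final(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec,
    best_params: dict,
) -> tuple[FittedModel, pd.DataFrame]:
    """Fit the chosen configuration on all labeled receptors.

    Returns the fitted model (carrying a schema hash so prediction-time
    feature matrices must match column-for-column) and the probability table
    on the training receptors.
    """
    labels = labels.loc[features.index.intersection(labels.index)]
    features = features.loc[labels.index]
    y = encode_labels(labels)
    est = _make_estimator(spec.family, best_params, spec.seed)
    est.fit(_prepare_X(spec.family, features), y)
    model = FittedModel(
        estimator=est,
        family=spec.family,
        columns=features.columns.tolist(),
        schema_hash=schema_hash(features.columns.tolist()),
        best_params=dict(best_params),
    )
    return model, model.predict_proba_table(features)


def save_model(model: FittedModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    path.with_suffix(".schema.json").write_text(
        json.dumps({"columns": model.columns, "schema_hash": model.schema_hash,
                    "family": model.family, "best_params": model.best_params}, indent=2)
    )


def load_model(path: str | Path) -> FittedModel:
    return joblib.load(path)
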