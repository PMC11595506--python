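"""Cross-validated classification of selected features.

Three classifiers (LDA, KNN, SVM with an RBF kernel) are evaluated with
k-fold or stratified k-fold cross-validation.  Standardization is fit on
the training folds only — no information from a test fold ever reaches a
fit.  Out-of-fold continuous scores (LDA posterior, KNN vote fraction,
SVM decision value) are pooled over all folds for a single ROC/AUC;
accuracy and the confusion matrix use each model's default decision
rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _metrics
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import LabelError
from .selection import encode_labels, select_features
from .study import FeatureTable

logger = logging.getLogger("fishrad.classify")

__all__ = [
    "ModelSpec",
    "CVSpec",
    "ModelEvaluation",
    "make_folds",
    "train_eval",
    "roc_curve",
    "confusion",
    "run_case_study",
    "CASE_STUDY_UNITS",
]


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration."""

    kind: str = "svm"  # lda | knn | svm
    knn_k: int = 10
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lda", "knn", "svm"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def build(self, n_train: int | None = None):
        if self.kind == "lda":
            est = LinearDiscriminantAnalysis()
        elif self.kind == "knn":
            k = self.knn_k
            if n_train is not None and n_train < k:
                logger.warning(
                    "knn_k=%d exceeds the training-fold size %d; clamping",
                    k, n_train,
                )
                k = n_train
            est = KNeighborsClassifier(n_neighbors=k)
        else:
            est = SVC(kernel=self.svm_kernel, C=self.svm_c)
        if self.standardize:
            return Pipeline([("scale", StandardScaler()), ("model", est)])
        return Pipeline([("model", est)])


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation scheme."""

    scheme: str = "stratified_kfold"  # kfold | stratified_kfold
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "stratified_kfold"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")


@dataclass
class ModelEvaluation:
    """Out-of-fold results of one (features, model, CV) analysis."""

    model: ModelSpec
    cv: CVSpec
    scores: np.ndarray  # out-of-fold continuous score per sample
    predictions: np.ndarray  # out-of-fold predicted 0/1 label per sample
    y_true: np.ndarray
    auc: float
    accuracy: float
    confusion_matrix: np.ndarray  # rows true, cols predicted
    fold_accuracy: list[float] = field(default_factory=list)
    features: list[str] = field(default_factory=list)
    fold_errors: list[str] = field(default_factory=list)


def make_folds(labels, cv: CVSpec) -> np.ndarray:
    """Assign each sample to exactly one test fold (deterministic by seed)."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < cv.k:
        raise ValueError(f"cannot make {cv.k} folds from {n} samples")
    if cv.scheme == "stratified_kfold":
        if len(np.unique(labels)) < 2:
            raise LabelError("stratified folds need both classes present")
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def _continuous_score(pipeline, model: ModelSpec, X: np.ndarray) -> np.ndarray:
    if model.kind == "svm":
        return pipeline.decision_function(X)
    return pipeline.predict_proba(X)[:, 1]


def train_eval(
    table: FeatureTable,
    labels,
    model: ModelSpec,
    cv: CVSpec,
    features: list[str] | None = None,
) -> ModelEvaluation:
    """Cross-validated evaluation of one classifier on selected features."""
    y = encode_labels(labels)
    feats = features if features is not None else table.feature_names
    X = table.data[feats].to_numpy(dtype=float)
    folds = make_folds(y, cv)
    n = len(y)
    scores = np.empty(n, dtype=float)
    preds = np.empty(n, dtype=int)
    fold_acc = []
    fold_errors = []
    for fold in range(cv.k):
        test = folds == fold
        train = ~test
        pipe = model.build(n_train=int(train.sum()))
        try:
            pipe.fit(X[train], y[train])
            scores[test] = _continuous_score(pipe, model, X[test])
            preds[test] = pipe.predict(X[test])
        except (ValueError, IndexError, np.linalg.LinAlgError) as exc:
            # e.g. LDA on a degenerate training fold (one class present or
            # zero within-class scatter): report, fall back to the prior
            fold_errors.append(f"fold {fold}: {exc}")
            logger.warning("%s fold %d failed (%s); using majority fallback",
                           model.kind, fold, exc)
            majority = int(y[train].mean() >= 0.5) if train.any() else 0
            scores[test] = float(y[train].mean()) if train.any() else 0.5
            preds[test] = majority
        fold_acc.append(float((preds[test] == y[test]).mean()))
    auc = roc_curve(scores, y)[2]
    acc = float((preds == y).mean())
    cm = confusion(y, preds)
    return ModelEvaluation(
        model=model, cv=cv, scores=scores, predictions=preds, y_true=y,
        auc=auc, accuracy=acc, confusion_matrix=cm, fold_accuracy=fold_acc,
        features=list(feats), fold_errors=fold_errors,
    )


def roc_curve(scores, y_true) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical ROC (fpr, tpr) and trapezoidal AUC with midrank ties.

    The AUC equals the normalized Mann-Whitney U statistic of the scores.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise LabelError("ROC needs both classes present")
    if np.unique(scores).size == 1:
        # all scores tied: one operating point, chance diagonal
        return np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
    fpr, tpr, _ = _metrics.roc_curve(y_true, scores)
    return fpr, tpr, float(_metrics.auc(fpr, tpr))


def confusion(y_true, preds) -> np.ndarray:
    """2x2 confusion counts (rows = true class 0/1, cols = predicted)."""
    return _metrics.confusion_matrix(y_true, preds, labels=[0, 1])


#: Analysis units of the case-study grid: the pooled multi-organ unit
#: first, then each region on its own.
CASE_STUDY_UNITS = (
    "all_masks_except_all_fish",
    "all_fish",
    "eye",
    "head",
    "heart",
    "length",
    "yolk",
)


def _pooled_table(table: FeatureTable, exclude: str = "all_fish") -> FeatureTable:
    """One row per specimen with region-prefixed feature columns."""
    regions = sorted(r for r in table.data["region"].unique() if r != exclude)
    pieces = []
    for region in regions:
        sub = table.data[table.data["region"] == region]
        sub = sub.set_index("specimen")
        renamed = sub[[c for c in sub.columns if c not in ("region", "label")]]
        renamed = renamed.rename(columns=lambda c: f"{region}__{c}")
        pieces.append(renamed)
    labels = (
        table.data[["specimen", "label"]]
        .drop_duplicates()
        .set_index("specimen")["label"]
    )
    wide = pd.concat(pieces, axis=1, join="inner")
    wide.insert(0, "label", labels.loc[wide.index])
    wide = wide.reset_index().rename(columns={"index": "specimen"})
    wide.insert(1, "region", "pooled")
    return FeatureTable(wide, dict(table.settings))


def run_case_study(
    table: FeatureTable,
    models: list[ModelSpec] | None = None,
    cv: CVSpec | None = None,
    selection_method: str = "pbc",
    selection_params: dict | None = None,
    units: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Selection + cross-validated evaluation over the analysis grid.

    For each analysis unit (the pooled multi-organ table and each region
    on its own), features are selected on that unit's table and every
    classifier is evaluated; the result grid has one row per
    (unit, model) with AUC, accuracy, the selected features and the
    confusion matrix.
    """
    if units is None:
        regions = sorted(table.data["region"].unique())
        units = ("all_masks_except_all_fish", *regions)
    if not units:
        raise ValueError("need at least one analysis unit")
    models = models or [ModelSpec("lda"), ModelSpec("knn"), ModelSpec("svm")]
    cv = cv or CVSpec()
    selection_params = selection_params or {}
    rows = []
    for unit in units:
        if unit == "all_masks_except_all_fish":
            unit_table = _pooled_table(table)
        else:
            unit_table = table.region(unit)
            if unit_table.n_rows == 0:
                raise ValueError(f"no rows for analysis unit {unit!r}")
        labels = unit_table.data["label"].to_numpy()
        sel = select_features(unit_table, labels, selection_method, **selection_params)
        feats = sel.selected or sel.scores.abs().nlargest(1).index.tolist()
        for model in models:
            ev = train_eval(unit_table, labels, model, cv, features=feats)
            logger.info("%s / %s: AUC %.3f acc %.3f (features: %s)",
                        unit, model.kind, ev.auc, ev.accuracy, ", ".join(feats))
            rows.append({
                "unit": unit,
                "model": model.kind,
                "auc": ev.auc,
                "accuracy": ev.accuracy,
                "n_samples": len(ev.y_true),
                "selected_features": ";".join(feats),
                "tn": int(ev.confusion_matrix[0, 0]),
                "fp": int(ev.confusion_matrix[0, 1]),
                "fn": int(ev.confusion_matrix[1, 0]),
                "tp": int(ev.confusion_matrix[1, 1]),
            })
    return pd.DataFrame(rows)
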