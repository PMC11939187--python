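"""Classifier benchmarking: eight standard models under stratified splitting
and 5-fold stratified cross-validation.

Models: KNN, SVM, Gaussian naive Bayes, decision tree, random forest,
XGBoost, AdaBoost and LightGBM, all at library-default hyperparameters
(frozen here; the benchmark compares model families, not tunings). The two
scale-sensitive models (KNN, SVM) train behind a fold-fitted standardiser.
Evaluation reports per-class one-vs-rest ROC/AUC per fold, mean +/- SD and
macro AUC, plus a pooled out-of-fold confusion matrix at the 0.5 probability
operating point with accuracy / precision / recall / F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .peaks import FeatureMatrix

__all__ = ["MODEL_NAMES", "CVEvaluation", "make_model", "stratified_split",
           "crossval_evaluate", "compute_metrics"]

MODEL_NAMES = ("knn", "svm", "gaussian_nb", "decision_tree", "random_forest",
               "xgboost", "adaboost", "lgbm")
POSITIVE = "cancer"


def make_model(name: str, seed: int = 0):
    """Instantiate one of the eight benchmark classifiers (default settings)."""
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    if name == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(probability=True, random_state=seed))
    if name == "gaussian_nb":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "lgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1)
    raise ValueError(f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}")


@dataclass
class CVEvaluation:
    """Cross-validated quality summary for one model."""

    model_name: str
    classes: list[str]
    fold_auc: dict[str, list[float]]          # per class, one AUC per fold
    mean_auc: dict[str, float]
    sd_auc: dict[str, float]
    macro_mean_auc: float
    macro_sd_auc: float
    confusion: dict[str, int]                 # pooled TP/FP/TN/FN at p>=0.5
    metrics: dict[str, float]
    roc_points: dict[str, list[tuple[np.ndarray, np.ndarray]]] = field(default_factory=dict)
    oof_proba: np.ndarray | None = None       # out-of-fold P(positive) per sample
    oof_fold: np.ndarray | None = None        # fold index per sample
    y_true: np.ndarray | None = None


def stratified_split(fm: FeatureMatrix, test_frac: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test row-index split preserving class proportions."""
    y = np.asarray(fm.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for a stratified split")
    idx = np.arange(len(y))
    if test_frac == 0:
        return idx, np.array([], dtype=int)
    tr, te = train_test_split(idx, test_size=test_frac, stratify=y,
                              random_state=seed)
    return np.sort(tr), np.sort(te)


def compute_metrics(confusion: dict[str, int]) -> dict[str, float]:
    """Accuracy / precision / recall / F1 from TP/FP/TN/FN counts.

    Undefined ratios (zero denominator) are reported as 0 with a warning."""
    tp, fp = confusion["TP"], confusion["FP"]
    tn, fn = confusion["TN"], confusion["FN"]
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0")
            return 0.0
        return num / den

    acc = (tp + tn) / n
    prec = _ratio(tp, tp + fp, "precision")
    rec = _ratio(tp, tp + fn, "recall")
    f1 = _ratio(2 * prec * rec, prec + rec, "f1") if (prec + rec) > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def crossval_evaluate(fm: FeatureMatrix, model_name: str, k: int = 5,
                      seed: int = 0) -> CVEvaluation:
    """k-fold stratified CV with out-of-fold probabilities.

    Per fold and per class, a one-vs-rest ROC/AUC is computed from the
    validation-fold probabilities; the macro AUC averages the per-class AUCs.
    The pooled confusion matrix thresholds P(cancer) at 0.5.
    """
    X = fm.values
    y = np.asarray(fm.labels)
    classes = sorted(np.unique(y))
    if len(classes) != 2:
        raise ValueError(f"binary benchmark expects 2 classes, got {classes}")
    for c in classes:
        if (y == c).sum() < k:
            raise ValueError(f"class {c!r} has fewer than k={k} samples")
    positive = POSITIVE if POSITIVE in classes else classes[0]

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    oof_fold = np.full(len(y), -1)
    fold_auc: dict[str, list[float]] = {c: [] for c in classes}
    roc_points: dict[str, list] = {c: [] for c in classes}
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        model = make_model(model_name, seed=seed)
        model.fit(X[tr], (y[tr] == positive).astype(int))
        proba = model.predict_proba(X[va])[:, 1]
        oof[va] = proba
        oof_fold[va] = fold
        for c in classes:
            score = proba if c == positive else 1.0 - proba
            truth = (y[va] == c).astype(int)
            fold_auc[c].append(float(roc_auc_score(truth, score)))
            fpr, tpr, _ = roc_curve(truth, score)
            roc_points[c].append((fpr, tpr))

    mean_auc = {c: float(np.mean(v)) for c, v in fold_auc.items()}
    sd_auc = {c: float(np.std(v)) for c, v in fold_auc.items()}
    per_fold_macro = np.mean([fold_auc[c] for c in classes], axis=0)
    pred_pos = oof >= 0.5
    is_pos = y == positive
    confusion = {
        "TP": int(np.sum(pred_pos & is_pos)),
        "FP": int(np.sum(pred_pos & ~is_pos)),
        "TN": int(np.sum(~pred_pos & ~is_pos)),
        "FN": int(np.sum(~pred_pos & is_pos)),
    }
    return CVEvaluation(
        model_name=model_name,
        classes=classes,
        fold_auc=fold_auc,
        mean_auc=mean_auc,
        sd_auc=sd_auc,
        macro_mean_auc=float(np.mean(per_fold_macro)),
        macro_sd_auc=float(np.std(per_fold_macro)),
        confusion=confusion,
        metrics=compute_metrics(confusion),
        roc_points=roc_points,
        oof_proba=oof,
        oof_fold=oof_fold,
        y_true=is_pos.astype(int),
    )
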