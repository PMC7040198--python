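"""Feature selection and cross-validated group classification.

The full selection chain — standardisation, significance prefilter, L1
(lasso) logistic selection — is refit inside every training fold, so no
information from a test fold leaks into feature choice or scaling.
Performance is reported from the pooled out-of-fold predictions: accuracy,
sensitivity and specificity from the pooled confusion matrix (patient =
positive class) and AUC from the pooled decision scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import EmptySelectionError, ParameterError, StructureError
from .stats import fdr_adjust, group_test

POSITIVE = "patient"

CLASSIFIERS = ("svm_rbf", "svm_linear", "knn", "naive_bayes", "fda")


def prefilter_significant(
    features: list[str], p_adj: dict[str, float], q: float = 0.05
) -> list[str]:
    """Keep features whose FDR-adjusted p-value is below ``q``."""
    missing = [f for f in features if f not in p_adj]
    if missing:
        raise StructureError(f"no statistics available for features: {missing[:5]}")
    kept = [f for f in features if p_adj[f] < q]
    if not kept:
        raise EmptySelectionError("no feature passes the significance prefilter")
    return kept


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    Cs: int | list[float] = 8,
) -> list[str]:
    """L1-penalised logistic regression selection; the penalty is chosen by
    inner cross-validation and features with non-zero coefficients are
    preserved.  Features are standardised internally.  If every coefficient
    shrinks to zero the full input set is returned with a warning."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("lasso selection needs two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ParameterError("need at least 2 samples per class")
    Xs = StandardScaler().fit_transform(np.asarray(X, dtype=float))
    cv = min(3, min((y == c).sum() for c in classes))
    model = LogisticRegressionCV(
        l1_ratios=(1,), solver="liblinear", Cs=Cs, cv=cv, random_state=seed,
        max_iter=2000, scoring="accuracy", use_legacy_attributes=False,
    )
    model.fit(Xs, y)
    mask = np.abs(model.coef_).ravel() > 1e-10
    if not mask.any():
        warnings.warn("lasso shrank all coefficients to zero; keeping the full set", stacklevel=2)
        return list(feature_names)
    return [f for f, m in zip(feature_names, mask) if m]


def _make_classifier(name: str, seed: int, n_train: int):
    if name == "svm_rbf":
        grid = {"C": [0.1, 1.0, 10.0, 100.0]}
        inner = min(3, max(2, n_train // 4))
        return GridSearchCV(SVC(kernel="rbf", gamma="scale"), grid, cv=inner)
    if name == "svm_linear":
        grid = {"C": [0.1, 1.0, 10.0, 100.0]}
        inner = min(3, max(2, n_train // 4))
        return GridSearchCV(SVC(kernel="linear"), grid, cv=inner)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=max(1, min(5, n_train)))
    if name == "naive_bayes":
        return GaussianNB()
    if name == "fda":
        return LinearDiscriminantAnalysis()
    raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class ClassificationReport:
    classifier: str
    accuracy: float           # percent
    sensitivity: float        # percent, patient = positive
    specificity: float        # percent
    auc: float
    roc: np.ndarray           # (n_points, 2): FPR, TPR
    confusion: dict[str, int]  # tn, fp, fn, tp pooled over folds
    selected_features: list[str]  # union over folds
    per_fold: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "confusion": self.confusion,
            "selected_features": self.selected_features,
            "per_fold": self.per_fold,
            "roc": self.roc.tolist(),
        }
        return json.dumps(d, indent=2)


def _select_in_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    names: list[str],
    seed: int,
    q: float,
) -> list[int]:
    """Prefilter + lasso on the training fold only; falls back to the full
    feature set when nothing is significant (keeps the evaluation honest on
    null data instead of failing)."""
    p = np.array(
        [group_test(X_tr[:, j], y_tr).p for j in range(X_tr.shape[1])]
    )
    p_adj, _ = fdr_adjust(p, q=q)
    kept = [j for j in range(len(names)) if p_adj[j] < q]
    if not kept:
        kept = list(range(len(names)))
    sub_names = [names[j] for j in kept]
    chosen = lasso_select(X_tr[:, kept], y_tr, sub_names, seed=seed)
    idx = [kept[sub_names.index(f)] for f in chosen]
    return idx


def evaluate(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm_rbf",
    folds: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
    groups: np.ndarray | None = None,
    select: bool = True,
    q: float = 0.05,
) -> ClassificationReport:
    """Stratified k-fold evaluation with in-fold feature selection.

    ``groups`` (e.g. subject ids when rows are epochs) keeps all rows of a
    group in the same fold; without it rows are stratified independently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ParameterError("binary classification only")
    if POSITIVE not in classes:
        raise ParameterError(f"labels must include the positive class {POSITIVE!r}")
    n_units = counts.min() if groups is None else min(
        len(np.unique(groups[y == c])) for c in classes
    )
    if folds < 2 or folds > n_units:
        raise ParameterError(f"folds must be in [2, {n_units}], got {folds}")
    y_bin = (y == POSITIVE).astype(int)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y_bin, groups=groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y_bin)

    scores = np.empty(len(y))
    preds = np.empty(len(y), dtype=int)
    selected_union: list[str] = []
    per_fold = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold_idx, (tr, te) in enumerate(split_iter):
            if select and X.shape[1] > 1:
                idx = _select_in_fold(X[tr], y[tr], feature_names, seed, q)
            else:
                idx = list(range(X.shape[1]))
            scaler = StandardScaler().fit(X[tr][:, idx])
            X_tr, X_te = scaler.transform(X[tr][:, idx]), scaler.transform(X[te][:, idx])
            clf = _make_classifier(classifier, seed, len(tr))
            clf.fit(X_tr, y_bin[tr])
            if hasattr(clf, "decision_function"):
                s = clf.decision_function(X_te)
            else:
                s = clf.predict_proba(X_te)[:, 1]
            scores[te] = s
            preds[te] = clf.predict(X_te)
            names_here = [feature_names[j] for j in idx]
            selected_union.extend(f for f in names_here if f not in selected_union)
            per_fold.append(
                {
                    "fold": fold_idx,
                    "n_test": int(len(te)),
                    "n_features": len(idx),
                    "accuracy": float((preds[te] == y_bin[te]).mean()),
                }
            )
    tp = int(((preds == 1) & (y_bin == 1)).sum())
    tn = int(((preds == 0) & (y_bin == 0)).sum())
    fp = int(((preds == 1) & (y_bin == 0)).sum())
    fn = int(((preds == 0) & (y_bin == 1)).sum())
    accuracy = 100.0 * (tp + tn) / len(y)
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    specificity = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    fpr, tpr, _ = roc_curve(y_bin, scores)
    return ClassificationReport(
        classifier=classifier,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=float(sk_auc(fpr, tpr)),
        roc=np.column_stack([fpr, tpr]),
        confusion={"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        selected_features=selected_union,
        per_fold=per_fold,
    )


def mahalanobis_scatter(
    X: np.ndarray, y: np.ndarray, covariance: str = "lw"
) -> pd.DataFrame:
    """Per-sample Mahalanobis distance to each class distribution (class
    mean plus per-class covariance; Ledoit-Wolf shrinkage by default,
    ``covariance='empirical'`` for the plain sample covariance).  Samples
    closer to the patient class than to the control class fall below the
    equal-distance line in a scatter plot."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    out = {}
    for cls in np.unique(y):
        Xc = X[y == cls]
        if Xc.shape[0] < 2:
            raise ParameterError(f"class {cls!r} needs at least 2 samples")
        if covariance == "lw":
            cov = LedoitWolf().fit(Xc).covariance_
        elif covariance == "empirical":
            cov = np.atleast_2d(np.cov(Xc, rowvar=False, bias=True))
        else:
            raise ParameterError("covariance must be 'lw' or 'empirical'")
        diff = X - Xc.mean(axis=0)
        vi = np.linalg.pinv(cov)
        out[f"d_{cls}"] = np.sqrt(np.einsum("ij,jk,ik->i", diff, vi, diff))
    df = pd.DataFrame(out)
    df["group"] = y
    return df
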