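"""Logistic-regression classification of imaging features with LOOCV and
permutation validation.

The feature table holds per-subject mean statistic values over significant
clusters (ReHo and Fisher-z FC). Collinear features are pruned at an absolute
correlation cutoff (dropping, within each offending pair, the member with the
larger mean absolute correlation to all other features), hyperparameters are
selected by grid search over the regularization strength with leave-one-out
accuracy, performance is evaluated by LOOCV, and the whole procedure is
validated by a label-permutation test.

The two estimators follow scikit-learn conventions (get_params/set_params,
fitted attributes with trailing underscores) and compose with sklearn
pipelines and model selection; the module-level functions are thin wrappers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ClassifierReport", "CollinearityPruner", "PrunedLogisticClassifier",
    "assemble_features", "prune_collinear", "grid_search_logistic",
    "loocv_evaluate", "compute_metrics", "permutation_test",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = tuple(np.logspace(-2, 1, 7))


@dataclass
class ClassifierReport:
    """Confusion-derived metrics of a binary classifier evaluation."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    tp: int
    fp: int
    tn: int
    fn: int
    roc_points: np.ndarray = field(repr=False)   # (n_thresholds, 2) of (FPR, TPR)
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {"auc": self.auc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "kappa": self.kappa, "permutation_p": self.permutation_p,
                "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}}


# ---------------------------------------------------------------------------
# estimators

class CollinearityPruner(TransformerMixin, BaseEstimator):
    """Iteratively drop features until no pair exceeds |r| > threshold.

    For the pair with the largest |r| above the threshold, the member with the
    larger mean absolute correlation to all other features is dropped (ties
    broken toward keeping the earlier column, so output order is
    deterministic). Label-independent: ``y`` is ignored.
    """

    def __init__(self, threshold: float = 0.75):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        n_features = X.shape[1]
        keep = list(range(n_features))
        if n_features >= 2:
            corr = np.corrcoef(X, rowvar=False)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 0.0)
            corr = np.abs(corr)
            while len(keep) >= 2:
                sub = corr[np.ix_(keep, keep)]
                i, j = np.unravel_index(np.argmax(sub), sub.shape)
                if sub[i, j] <= self.threshold:
                    break
                mean_i = sub[i].sum() / (len(keep) - 1)
                mean_j = sub[j].sum() / (len(keep) - 1)
                # drop the larger mean |r|; on a tie drop the later column
                drop = j if (mean_j > mean_i or (mean_j == mean_i and keep[j] > keep[i])) else i
                keep.pop(drop)
        self.kept_columns_ = np.array(keep, dtype=int)
        self.n_features_in_ = n_features
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_columns_")
        X = np.asarray(X, dtype=float)
        return X[:, self.kept_columns_]


class PrunedLogisticClassifier(ClassifierMixin, BaseEstimator):
    """Collinearity pruning + standardized L2 logistic regression with
    LOOCV grid search over the regularization strength.

    ``fit`` prunes collinear features, selects C from ``c_grid`` by
    leave-one-out accuracy on the training data (ties broken toward stronger
    regularization, i.e. the smallest C), and refits on all data.
    """

    def __init__(self, threshold: float = 0.75, c_grid=DEFAULT_C_GRID,
                 max_iter: int = 1000):
        self.threshold = threshold
        self.c_grid = c_grid
        self.max_iter = max_iter

    def _make_pipeline(self, C: float) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(C=C, solver="lbfgs", max_iter=self.max_iter)),
        ])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need two classes to fit the classifier")
        if len(self.c_grid) == 0:
            raise ValueError("hyperparameter grid is empty")
        self.pruner_ = CollinearityPruner(self.threshold).fit(X)
        Xp = self.pruner_.transform(X)
        grid = sorted(float(c) for c in self.c_grid)
        best_acc, best_c = -1.0, grid[0]
        for C in grid:
            acc = _loocv_accuracy(Xp, y, C)
            if acc > best_acc:  # ties keep the earlier (smaller) C
                best_acc, best_c = acc, C
        self.best_c_, self.cv_accuracy_ = best_c, best_acc
        self.model_ = self._make_pipeline(self.best_c_).fit(Xp, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(self.pruner_.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.pruner_.transform(np.asarray(X, dtype=float)))

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.decision_function(self.pruner_.transform(np.asarray(X, dtype=float)))


def _logistic_irls(X: np.ndarray, y01: np.ndarray, C: float,
                   max_iter: int = 60, tol: float = 1e-9) -> np.ndarray:
    """L2-penalized logistic regression by Newton-IRLS.

    Minimizes sum log-loss + ||w||^2 / (2C) with an unpenalized intercept —
    the same objective as scikit-learn's LogisticRegression (agreement is
    asserted in the test suite). Returns the (d+1,) coefficient vector with
    the intercept last. Kept deliberately lean: the LOOCV and permutation
    loops refit this model tens of thousands of times.
    """
    n, d = X.shape
    Xb = np.column_stack([X, np.ones(n)])
    w = np.zeros(d + 1)
    reg = np.concatenate([np.full(d, 1.0 / C), [0.0]])
    reg_mat = np.diag(reg) + 1e-10 * np.eye(d + 1)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(Xb @ w)))
        g = Xb.T @ (p - y01) + reg * w
        H = (Xb * (p * (1.0 - p))[:, None]).T @ Xb + reg_mat
        step = np.linalg.solve(H, g)
        w -= step
        if np.abs(step).max() < tol:
            break
    return w


def _irls_predict_proba(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(X @ w[:-1] + w[-1])))


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def _loocv_accuracy(X: np.ndarray, y: np.ndarray, C: float) -> float:
    """LOOCV accuracy of the standardized L2 logistic model (IRLS core)."""
    y01 = (y == np.unique(y)[0]).astype(float)
    correct = 0
    for i in range(len(y)):
        tr = np.arange(len(y)) != i
        if np.unique(y01[tr]).size < 2:
            continue
        Xtr, Xte = _standardize(X[tr], X[i:i + 1])
        w = _logistic_irls(Xtr, y01[tr], C)
        pred = _irls_predict_proba(Xte, w)[0] >= 0.5
        correct += int(pred == bool(y01[i]))
    return correct / len(y)


# ---------------------------------------------------------------------------
# functional surface

def assemble_features(subject_maps, cluster_masks, cluster_names=None,
                      subject_ids=None) -> pd.DataFrame:
    """Per-subject mean map value over each cluster.

    ``subject_maps`` is a sequence (one per subject) of dicts
    {map_name: 3D array or StatMap} or plain sequences aligned with
    ``cluster_masks``; here the simple aligned form is used: element s is a
    list of 3D arrays, one per cluster (the map the cluster was defined on).
    """
    cluster_masks = [np.asarray(m, dtype=bool) for m in cluster_masks]
    if len(cluster_masks) == 0:
        raise ValueError("cluster list is empty")
    if cluster_names is None:
        cluster_names = [f"cluster{i + 1}" for i in range(len(cluster_masks))]
    rows = []
    for s, maps in enumerate(subject_maps):
        row = []
        for m, cmask in zip(maps, cluster_masks):
            vals = m.values if hasattr(m, "values") else np.asarray(m)
            if vals.shape != cmask.shape:
                raise ValueError(f"subject {s}: map grid does not match cluster grid")
            row.append(float(vals[cmask].mean()))
        rows.append(row)
    return pd.DataFrame(rows, columns=cluster_names,
                        index=subject_ids if subject_ids is not None else range(len(rows)))


def prune_collinear(features: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Functional wrapper over :class:`CollinearityPruner` keeping column names."""
    if features.shape[1] < 2:
        return features.copy()
    pruner = CollinearityPruner(threshold).fit(features.to_numpy())
    return features.iloc[:, pruner.kept_columns_].copy()


def grid_search_logistic(features, labels, grid=DEFAULT_C_GRID, threshold: float = 0.75):
    """Select the regularization strength maximizing LOOCV accuracy.

    Returns (best_C, loocv_accuracy). Ties break toward stronger
    regularization (smaller C).
    """
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features, dtype=float)
    clf = PrunedLogisticClassifier(threshold=threshold, c_grid=grid).fit(X, np.asarray(labels))
    return clf.best_c_, clf.cv_accuracy_


def loocv_evaluate(features, labels, C: float = 1.0, threshold: float = 0.75,
                   honest: bool = False, c_grid=DEFAULT_C_GRID):
    """Leave-one-out evaluation: per-subject held-out predictions and scores.

    With ``honest=False`` the hyperparameter C is fixed (selected upstream, as
    when feature selection and tuning precede CV); with ``honest=True`` the
    pruning and grid search are re-run inside every training fold, nesting
    model selection within the cross-validation. Predictions are
    order-invariant: each subject's prediction depends only on the other
    subjects' data. A fold whose training labels collapse to one class is
    flagged with NaN score and the majority prediction.
    """
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    pos = classes[0]
    y01 = (y == pos).astype(float)
    if not honest:
        # pruning is label-independent; in the selection-before-CV design it
        # is applied once to the full table
        X = CollinearityPruner(threshold).fit(X).transform(X)
    preds = np.empty(n, dtype=y.dtype)
    scores = np.full(n, np.nan)
    for i in range(n):
        tr = np.arange(n) != i
        if np.unique(y[tr]).size < 2:
            vals, counts = np.unique(y[tr], return_counts=True)
            preds[i] = vals[np.argmax(counts)]
            continue
        if honest:
            model = PrunedLogisticClassifier(threshold=threshold, c_grid=c_grid).fit(X[tr], y[tr])
            preds[i] = model.predict(X[i:i + 1])[0]
            proba = model.predict_proba(X[i:i + 1])[0]
            scores[i] = proba[int(np.nonzero(model.classes_ == pos)[0][0])]
        else:
            Xtr, Xte = _standardize(X[tr], X[i:i + 1])
            w = _logistic_irls(Xtr, y01[tr], C)
            p = float(_irls_predict_proba(Xte, w)[0])
            preds[i] = pos if p >= 0.5 else classes[1]
            scores[i] = p
    return preds, scores


def compute_metrics(predictions, scores, labels, positive_label=None) -> ClassifierReport:
    """Confusion-derived metrics, trapezoidal ROC AUC and Cohen's kappa.

    ``scores`` must be oriented so larger means more likely positive. The
    positive class defaults to the first unique label.
    """
    y = np.asarray(labels)
    preds = np.asarray(predictions)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    pos = classes[0] if positive_label is None else positive_label
    yt = (y == pos)
    yp = (preds == pos)
    tp = int(np.sum(yt & yp)); fn = int(np.sum(yt & ~yp))
    tn = int(np.sum(~yt & ~yp)); fp = int(np.sum(~yt & yp))
    n = len(y)
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn else np.nan
    specificity = tn / (tn + fp) if tn + fp else np.nan
    po = accuracy
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n ** 2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    fpr, tpr = _roc_points(yt, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassifierReport(auc=auc, accuracy=accuracy, sensitivity=sensitivity,
                            specificity=specificity, kappa=kappa,
                            tp=tp, fp=fp, tn=tn, fn=fn,
                            roc_points=np.column_stack([fpr, tpr]))


def _roc_points(y_true_bool: np.ndarray, scores: np.ndarray):
    """ROC curve over unique score thresholds (ties handled jointly)."""
    ok = np.isfinite(scores)
    y, s = y_true_bool[ok], scores[ok]
    order = np.argsort(-s, kind="stable")
    y = y[order]; s = s[order]
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(~y)[idx]
    P, N = y.sum(), (~y).sum()
    tpr = np.r_[0.0, tps / P] if P else np.r_[0.0, np.zeros(len(idx))]
    fpr = np.r_[0.0, fps / N] if N else np.r_[0.0, np.zeros(len(idx))]
    return fpr, tpr


def permutation_test(features, labels, n_perm: int = 5000, seed: int = 0,
                     threshold: float = 0.75, c_grid=DEFAULT_C_GRID,
                     statistic: str = "accuracy") -> float:
    """Label-permutation p-value for the full classification procedure.

    The observed statistic is the LOOCV accuracy (or AUC) of the complete
    prune + grid-search + LOOCV pipeline; each permutation re-runs the whole
    procedure on shuffled labels. p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = features.to_numpy() if hasattr(features, "to_numpy") else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def run(yy) -> float:
        best_c, _ = grid_search_logistic(X, yy, grid=c_grid, threshold=threshold)
        preds, scores = loocv_evaluate(X, yy, C=best_c, threshold=threshold)
        rep = compute_metrics(preds, scores, yy)
        return rep.accuracy if statistic == "accuracy" else rep.auc

    observed = run(y)
    count = 0
    for _ in range(n_perm):
        if run(rng.permutation(y)) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)
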