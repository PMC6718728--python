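"""Class-weighted SVM failure detector with nested cross-validation.

The detector is a binary RBF-SVM over windowed count features.  Class
imbalance (failure windows are usually the minority) is handled by
per-class regularization weights: the success class keeps weight 1 and the
failure class is up-weighted by ``n0 / n1`` (success count over failure
count) of the training labels.

Model selection and evaluation follow a nested 10-fold cross-validation:
the inner loop grid-searches (C, gamma) by mean inner balanced error rate,
the outer loop evaluates the winning model on a held-out fold.  Folds are
stratified and seeded, so a run is fully reproducible.

Evaluation conventions: a *myocontrol success* is the positive condition, a
*failure* the negative one, giving the confusion matrix

    M_conf = [[N_TP, N_FP], [N_FN, N_TN]]

with rate matrix M_rate = [[TPR, FPR], [FNR, TNR]] (rows normalized by
condition) and balanced error rate BER = 100/2 * (FNR + FPR) percent.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector

#: Default hyperparameter grid: powers of four, the customary coarse RBF grid.
DEFAULT_GRID_C = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GRID_GAMMA = tuple(float(2.0**e) for e in range(-15, 4, 2))

N_FOLDS = 10


class DegenerateDatasetError(ValueError):
    """Dataset cannot support the requested operation (single class, too few
    instances per class, empty condition)."""


@dataclasses.dataclass(frozen=True)
class WeightSpec:
    """Per-class SVM regularization weights, C_success = 1, C_failure = n0/n1."""

    c_success: float
    c_failure: float
    n0: int  # success count
    n1: int  # failure count


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with SUCCESS as the positive condition, FAILURE as negative."""

    n_tp: int
    n_fp: int
    n_fn: int
    n_tn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn, self.n_tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_fn + self.n_tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.n_tp + other.n_tp,
            self.n_fp + other.n_fp,
            self.n_fn + other.n_fn,
            self.n_tn + other.n_tn,
        )


@dataclasses.dataclass(frozen=True)
class RateMatrix:
    tpr: float
    fpr: float
    fnr: float
    tnr: float


@dataclasses.dataclass
class FoldResult:
    confusion: ConfusionMatrix
    c: float
    gamma: float
    scores: np.ndarray  # decision values oriented toward success
    labels: np.ndarray  # true labels, 0 success / 1 failure


@dataclasses.dataclass
class CVResult:
    folds: list[FoldResult]
    pooled: ConfusionMatrix
    ber: float  # percent
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float

    @property
    def scores(self) -> np.ndarray:
        return np.concatenate([f.scores for f in self.folds])

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([f.labels for f in self.folds])


def class_weights(labels: Sequence[int]) -> WeightSpec:
    """Imbalance weights from the training labels (0 success, 1 failure)."""
    labels = np.asarray(labels)
    n0 = int(np.sum(labels == 0))
    n1 = int(np.sum(labels == 1))
    if n0 == 0 or n1 == 0:
        raise DegenerateDatasetError(
            f"both classes required, got n0={n0} successes, n1={n1} failures"
        )
    return WeightSpec(c_success=1.0, c_failure=n0 / n1, n0=n0, n1=n1)


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionMatrix:
    """Confusion counts; labels are 0 = success (positive), 1 = failure."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionMatrix(
        n_tp=int(np.sum((y_true == 0) & (y_pred == 0))),
        n_fp=int(np.sum((y_true == 1) & (y_pred == 0))),
        n_fn=int(np.sum((y_true == 0) & (y_pred == 1))),
        n_tn=int(np.sum((y_true == 1) & (y_pred == 1))),
    )


def rate_matrix(m: ConfusionMatrix) -> RateMatrix:
    """Occurrence rates, rows normalized by true condition."""
    p = m.n_tp + m.n_fn
    n = m.n_fp + m.n_tn
    if p == 0:
        raise DegenerateDatasetError("no positive (success) instances")
    if n == 0:
        raise DegenerateDatasetError("no negative (failure) instances")
    return RateMatrix(
        tpr=m.n_tp / p, fpr=m.n_fp / n, fnr=m.n_fn / p, tnr=m.n_tn / n
    )


def ber(m: ConfusionMatrix) -> float:
    """Balanced error rate in percent: 100/2 * (FNR + FPR)."""
    r = rate_matrix(m)
    return 100.0 / 2.0 * (r.fnr + r.fpr)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and AUC from success-oriented decision scores.

    ``scores`` must be larger for windows more likely to be successes (the
    positive condition).  Ties contribute half, so the AUC equals the
    normalized Mann-Whitney U statistic.
    Returns (fpr, tpr, auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DegenerateDatasetError("ROC needs both classes present")
    y_pos = (labels == 0).astype(int)  # success is the positive condition
    fpr, tpr, _ = _sk_roc_curve(y_pos, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def mean_roc(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_points: int = 101
) -> tuple[np.ndarray, np.ndarray]:
    """Vertically average ROC curves on a fixed FPR grid in [0, 1]."""
    if not curves:
        raise ValueError("at least one ROC curve required")
    grid = np.linspace(0.0, 1.0, n_points)
    tprs = []
    for fpr, tpr in curves:
        fpr = np.concatenate(([0.0], np.asarray(fpr, float), [1.0]))
        tpr = np.concatenate(([0.0], np.asarray(tpr, float), [1.0]))
        tprs.append(np.interp(grid, fpr, tpr))
    return grid, np.mean(tprs, axis=0)


def _dataset_arrays(dataset: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([fv.counts for fv in dataset], dtype=float)
    y = np.array([fv.label for fv in dataset], dtype=int)
    return X, y


def _fit_svm(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float
) -> SVC:
    w = class_weights(y)
    clf = SVC(
        C=c,
        gamma=gamma,
        kernel="rbf",
        class_weight={0: w.c_success, 1: w.c_failure},
    )
    clf.fit(X, y)
    return clf

def _success_scores(clf: SVC, X: np.ndarray) -> np.ndarray:
    # sklearn orients decision_function toward the larger class label (1 =
    # failure); negate so larger means more success-like.
    return -clf.decision_function(X)


def _fold_ber(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    # Inner-loop selection metric; a fold missing one class contributes the
    # worst case so it can never win the grid search.
    m = confusion_from_predictions(y_true, y_pred)
    try:
        return ber(m)
    except DegenerateDatasetError:
        return 100.0


def nested_cv(
    dataset: Sequence[FeatureVector],
    grid_c: Sequence[float] = DEFAULT_GRID_C,
    grid_gamma: Sequence[float] = DEFAULT_GRID_GAMMA,
    seed: int = 0,
) -> CVResult:
    """Nested stratified 10-fold cross-validation of the weighted SVM.

    The inner 10-fold grid search selects the (C, gamma) pair minimizing
    mean inner BER (ties broken toward smaller C, then smaller gamma); the
    winner is refit on the full outer training set, with class weights from
    the outer-training labels, and applied to the held-out fold.  Features
    are standardized with outer-training statistics only.
    """
    X, y = _dataset_arrays(dataset)
    counts = np.bincount(y, minlength=2)
    if counts.min() < N_FOLDS:
        raise DegenerateDatasetError(
            f"need at least {N_FOLDS} instances of each class for stratified "
            f"{N_FOLDS}-fold CV, got {counts.tolist()}"
        )

    outer = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    inner = StratifiedKFold(
        n_splits=N_FOLDS, shuffle=True, random_state=seed + 1
    )

    folds: list[FoldResult] = []
    for train_idx, test_idx in outer.split(X, y):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        scaler = StandardScaler().fit(X_tr)
        Z_tr = scaler.transform(X_tr)
        Z_te = scaler.transform(X_te)

        best = (np.inf, np.inf, np.inf)  # (mean BER, C, gamma)
        for c in sorted(grid_c):
            for gamma in sorted(grid_gamma):
                bers = []
                for itr, ival in inner.split(Z_tr, y_tr):
                    clf = _fit_svm(Z_tr[itr], y_tr[itr], c, gamma)
                    bers.append(_fold_ber(y_tr[ival], clf.predict(Z_tr[ival])))
                cand = (float(np.mean(bers)), c, gamma)
                if cand < best:
                    best = cand
        _, c_star, gamma_star = best

        clf = _fit_svm(Z_tr, y_tr, c_star, gamma_star)
        y_pred = clf.predict(Z_te)
        folds.append(
            FoldResult(
                confusion=confusion_from_predictions(y_te, y_pred),
                c=c_star,
                gamma=gamma_star,
                scores=_success_scores(clf, Z_te),
                labels=y_te,
            )
        )

    pooled = folds[0].confusion
    for f in folds[1:]:
        pooled = pooled + f.confusion
    all_scores = np.concatenate([f.scores for f in folds])
    all_labels = np.concatenate([f.labels for f in folds])
    fpr, tpr, auc_val = roc_auc(all_scores, all_labels)
    return CVResult(
        folds=folds,
        pooled=pooled,
        ber=ber(pooled),
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc_val,
    )
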