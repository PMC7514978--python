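"""Evaluation protocol: losses, ROC, repeated CV, bias-variance, comparisons.

The protocol mirrors common BNC benchmarking practice: 20 rounds of
stratified 10-fold cross-validation with mode imputation and minority-class
oversampling applied to the training portion of each fold only; zero-one
loss, F1 on the minority ("positive") class, and a threshold-sweep ROC/AUC.
Cross-classifier comparisons use Win/Draw/Loss with a one-tailed binomial
sign test, the Friedman rank test in its Iman–Davenport F form, and the
goal-difference (wins minus losses) summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone

from .data import DiscreteDataset
from .preprocess import (
    ParameterError,
    impute_training,
    make_folds,
    oversample as _oversample,
)


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def zero_one_loss(truth, predicted) -> float:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ParameterError("length mismatch")
    return float(np.mean(truth != predicted))


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 (with no positives at all) by convention."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        import warnings

        warnings.warn("F1 undefined (no positive instances or predictions); returning 0")
        return 0.0
    return 2 * tp / denom


def confusion(truth, predicted, positive) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) with the given positive label."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    tp = int(np.sum((truth == positive) & (predicted == positive)))
    fp = int(np.sum((truth != positive) & (predicted == positive)))
    fn = int(np.sum((truth == positive) & (predicted != positive)))
    tn = int(np.sum((truth != positive) & (predicted != positive)))
    return tp, fp, fn, tn


def roc_curve(scores, truth, positive) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-sweep ROC points (FPR, TPR), tied scores grouped.

    Starts at (0, 0) and ends at (1, 1); FPR is nondecreasing.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive
    n_pos = int(pos.sum())
    n_neg = int(pos.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC undefined for single-class truth")
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], pos[order]
    tps = np.cumsum(p)
    fps = np.cumsum(~p)
    # keep only the last index of each tied-score group
    last = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    return fpr, tpr


def roc_auc(scores, truth, positive) -> float:
    """Area under the ROC curve by the trapezoid rule."""
    fpr, tpr = roc_curve(scores, truth, positive)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Aggregated repeated-CV results for one classifier on one dataset."""

    fold_losses: np.ndarray
    mean_loss: float
    std_loss: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    roc_points: tuple[np.ndarray, np.ndarray]
    auc: float
    m_test: int
    positive_class: object
    bias: float | None = None
    variance: float | None = None

    def to_dict(self) -> dict:
        return {
            "mean_loss": self.mean_loss,
            "std_loss": self.std_loss,
            "f1": self.f1,
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "auc": self.auc,
            "m_test": self.m_test,
            "positive_class": str(self.positive_class),
            "n_folds": int(self.fold_losses.size),
        }


def cross_validate(
    ds: DiscreteDataset,
    estimator,
    folds: int = 10,
    rounds: int = 20,
    seed: int = 0,
    balance: bool = True,
    positive_class=None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation with leakage-free preprocessing.

    Per fold the training portion is mode/mean-imputed and (optionally)
    oversampled to class balance before fitting a clone of ``estimator``;
    test rows are passed through as-is (the estimators impute internally
    with training statistics where their model requires it).  The positive
    class for F1/ROC defaults to the minority class of the full dataset.
    """
    counts = ds.class_counts()
    if positive_class is None:
        positive_class = ds.class_domain[int(np.argmin(counts))]
    pairs = make_folds(ds, folds=folds, rounds=rounds, seed=seed)
    losses = []
    all_truth, all_pred, all_scores = [], [], []
    pos_code = list(ds.class_domain).index(positive_class)
    for f, (tr, te) in enumerate(pairs):
        train = impute_training(ds.take(tr))
        if balance:
            train = _oversample(train, seed=seed * 100003 + f)
        est = clone(estimator)
        est.fit(train.codes(), train.labels)
        test = ds.take(te)
        Xte = np.where(np.isnan(test.rows), -1, test.rows)
        proba = est.predict_proba(Xte)
        pred = est.classes_[np.argmax(proba, axis=1)]
        losses.append(zero_one_loss(test.labels, pred))
        all_truth.append(test.labels)
        all_pred.append(pred)
        col = list(est.classes_).index(pos_code) if pos_code in est.classes_ else None
        all_scores.append(proba[:, col] if col is not None else np.zeros(len(te)))
    truth = np.concatenate(all_truth)
    pred = np.concatenate(all_pred)
    scores = np.concatenate(all_scores)
    tp, fp, fn, tn = confusion(truth, pred, pos_code)
    fl = np.asarray(losses)
    try:
        points = roc_curve(scores, truth, pos_code)
        auc = float(np.trapezoid(points[1], points[0]))
    except ParameterError:
        points, auc = (np.array([0.0, 1.0]), np.array([0.0, 1.0])), float("nan")
    return EvalReport(
        fold_losses=fl,
        mean_loss=float(fl.mean()),
        std_loss=float(fl.std()),
        f1=f1_score(tp, fp, fn),
        tp=tp, fp=fp, fn=fn, tn=tn,
        roc_points=points,
        auc=auc,
        m_test=int(truth.size),
        positive_class=positive_class,
    )


# ---------------------------------------------------------------------------
# bias-variance decomposition (zero-one loss)
# ---------------------------------------------------------------------------

def bias_variance(
    ds: DiscreteDataset,
    estimator,
    repeats: int = 10,
    holdout: float = 0.5,
    seed: int = 0,
) -> tuple[float, float]:
    """Kohavi–Wolpert decomposition of zero-one loss over random splits.

    With deterministic labels the irreducible term is zero, so for each
    instance x with empirical prediction distribution p over classes and
    true class y:  bias(x) = 1/2 * sum_c (1[c=y] - p_c)^2 and
    var(x) = 1/2 * (1 - sum_c p_c^2); their test-weighted means satisfy
    bias + variance = mean zero-one loss exactly.
    """
    if repeats < 2:
        raise ParameterError("bias-variance needs repeats >= 2")
    rng = np.random.default_rng(seed)
    n = ds.n_rows
    m = ds.n_classes
    pred_counts = np.zeros((n, m))
    tested = np.zeros(n)
    n_train = max(1, int(round(n * holdout)))
    for _ in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        train = impute_training(ds.take(tr))
        est = clone(estimator)
        est.fit(train.codes(), train.labels)
        Xte = np.where(np.isnan(ds.rows[te]), -1, ds.rows[te])
        pred = est.predict(Xte)
        pred_counts[te, np.asarray(pred, dtype=int)] += 1
        tested[te] += 1
    mask = tested > 0
    p = pred_counts[mask] / tested[mask, None]
    w = tested[mask] / tested[mask].sum()
    onehot = np.zeros_like(p)
    onehot[np.arange(mask.sum()), ds.labels[mask]] = 1.0
    bias = float((w * 0.5 * ((onehot - p) ** 2).sum(axis=1)).sum())
    var = float((w * 0.5 * (1.0 - (p ** 2).sum(axis=1))).sum())
    return bias, var


# ---------------------------------------------------------------------------
# cross-classifier comparison statistics
# ---------------------------------------------------------------------------

def win_draw_loss(
    scores: np.ndarray, alpha: float = 0.05, lower_is_better: bool = True
) -> tuple[int, int, int, bool, float]:
    """Per-dataset Win/Draw/Loss of column 0 vs column 1 with a one-tailed
    binomial sign test (draws excluded).

    Returns ``(win, draw, loss, significant, p_value)``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0 or scores.ndim != 2 or scores.shape[1] != 2:
        raise ParameterError("expected a non-empty (datasets x 2) score table")
    a, b = scores[:, 0], scores[:, 1]
    if lower_is_better:
        win = int(np.sum(a < b)); loss = int(np.sum(a > b))
    else:
        win = int(np.sum(a > b)); loss = int(np.sum(a < b))
    draw = scores.shape[0] - win - loss
    n = win + loss
    if n == 0:
        return win, draw, loss, False, 1.0
    p = float(stats.binomtest(max(win, loss), n, 0.5, alternative="greater").pvalue)
    return win, draw, loss, p < alpha, p


@dataclass
class FriedmanResult:
    ranks: np.ndarray
    statistic: float
    critical_value: float
    reject: bool
    df: tuple[int, int]
    p_value: float


def friedman_critical_value(n_classifiers: int, n_datasets: int,
                            alpha: float = 0.05) -> float:
    """0.95 (by default) quantile of F with ((k-1), (k-1)(N-1)) df."""
    d1 = n_classifiers - 1
    d2 = d1 * (n_datasets - 1)
    return float(stats.f.ppf(1 - alpha, d1, d2))


def friedman_test(scores: np.ndarray, alpha: float = 0.05,
                  lower_is_better: bool = True) -> FriedmanResult:
    """Friedman rank test in Iman–Davenport F form.

    ``scores`` is a (datasets x classifiers) table; lower scores get better
    (smaller) ranks by default, ties receive the mean rank.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ParameterError("need at least 2 datasets and 2 classifiers")
    N, k = scores.shape
    mat = scores if lower_is_better else -scores
    ranks = np.vstack([stats.rankdata(row) for row in mat])
    R = ranks.mean(axis=0)
    chi2 = 12.0 * N / (k * (k + 1)) * (np.sum(R ** 2) - k * (k + 1) ** 2 / 4.0)
    denom = N * (k - 1) - chi2
    stat = np.inf if denom <= 0 else (N - 1) * chi2 / denom
    d1, d2 = k - 1, (k - 1) * (N - 1)
    crit = friedman_critical_value(k, N, alpha)
    p = float(stats.f.sf(stat, d1, d2)) if np.isfinite(stat) else 0.0
    return FriedmanResult(R, float(stat), crit, bool(stat > crit), (d1, d2), p)


def nemenyi_cd(n_classifiers: int, n_datasets: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference of average ranks."""
    q = stats.studentized_range.ppf(1 - alpha, n_classifiers, np.inf) / np.sqrt(2)
    return float(q * np.sqrt(n_classifiers * (n_classifiers + 1) / (6.0 * n_datasets)))


def goal_difference(wins: int, losses: int) -> int:
    """GD = |win| - |loss|."""
    return int(wins) - int(losses)


def goal_difference_curve(
    scores: np.ndarray, order_key: np.ndarray, lower_is_better: bool = True
) -> np.ndarray:
    """Cumulative GD of classifier 0 over classifier 1 across datasets
    ordered by ``order_key`` (e.g. dataset size or attribute count)."""
    scores = np.asarray(scores, dtype=float)
    idx = np.argsort(np.asarray(order_key), kind="stable")
    a, b = scores[idx, 0], scores[idx, 1]
    step = np.where(a < b, 1, np.where(a > b, -1, 0))
    if not lower_is_better:
        step = -step
    return np.cumsum(step)
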