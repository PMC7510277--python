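"""Classifier-in-the-loop evaluation of gene subsets.

Provides the kNN classifier with deterministic tie handling, the metric suite
(accuracy, sensitivity, specificity, F-score, Matthews correlation, Cohen's
kappa), repeated stratified k-fold cross-validation, nested-prefix selection
over a ranking, exhaustive best-subset search, per-gene two-sample t-tests,
and the p-value filter that turns hub genes into key genes.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import ExpressionDataset, GeneRanking

logger = logging.getLogger(__name__)

__all__ = [
    "KNNClassifier",
    "MajorityClassifier",
    "MetricSet",
    "EvaluationReport",
    "SubsetSearchResult",
    "make_classifier",
    "knn_predict",
    "compute_metrics",
    "repeated_cv",
    "best_prefix",
    "exhaustive_search",
    "ttest_genes",
    "filter_key_genes",
]

P_SIGNIFICANT = 0.05  # significance threshold used throughout the workflow


class KNNClassifier:
    """k-nearest-neighbor classifier with fixed, deterministic tie rules.

    Euclidean distance; equal distances are broken by lower training-sample
    index; vote ties among top classes are broken by the class of the nearest
    neighbor belonging to one of the tied classes.
    """

    def __init__(self, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self._X: np.ndarray | None = None
        self._y: list[str] | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "KNNClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("training matrix must be 2-D with >= 1 feature")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self._X = X
        self._y = [str(v) for v in y]
        return self

    def predict(self, X: np.ndarray) -> list[str]:
        if self._X is None or self._y is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        dists = np.sqrt(((X[:, None, :] - self._X[None, :, :]) ** 2).sum(axis=2))
        out = []
        for row in dists:
            # stable sort: equal distances keep ascending training index
            order = np.argsort(row, kind="stable")[: self.k]
            votes: dict[str, int] = {}
            for idx in order:
                votes[self._y[idx]] = votes.get(self._y[idx], 0) + 1
            best = max(votes.values())
            tied = {c for c, v in votes.items() if v == best}
            if len(tied) == 1:
                out.append(next(iter(tied)))
            else:
                # nearest neighbor whose class is among the tied classes
                out.append(next(self._y[i] for i in order if self._y[i] in tied))
        return out


class MajorityClassifier:
    """Predicts the most frequent training label (ties: first appearance)."""

    def fit(self, X, y) -> "MajorityClassifier":
        counts: dict[str, int] = {}
        for v in y:
            counts[str(v)] = counts.get(str(v), 0) + 1
        self._label = max(counts, key=lambda c: counts[c])
        return self

    def predict(self, X) -> list[str]:
        return [self._label] * len(np.asarray(X))


class _SVMWrapper:
    """RBF-kernel support-vector classifier behind the fit/predict contract."""

    def __init__(self) -> None:
        self._svc = SVC(kernel="rbf")

    def fit(self, X, y) -> "_SVMWrapper":
        self._svc.fit(np.asarray(X, dtype=float), [str(v) for v in y])
        return self

    def predict(self, X) -> list[str]:
        return [str(v) for v in self._svc.predict(np.asarray(X, dtype=float))]


def make_classifier(descriptor, k: int = 5):
    """Resolve a classifier descriptor ('knn', 'svm-rbf', 'majority', or any
    object with fit/predict) to a fresh classifier instance."""
    if not isinstance(descriptor, str):
        if hasattr(descriptor, "fit") and hasattr(descriptor, "predict"):
            return descriptor
        raise TypeError("classifier must expose fit() and predict()")
    if descriptor == "knn":
        return KNNClassifier(k=k)
    if descriptor == "svm-rbf":
        return _SVMWrapper()
    if descriptor == "majority":
        return MajorityClassifier()
    raise ValueError(f"unknown classifier {descriptor!r}")


def knn_predict(
    train: ExpressionDataset,
    genes: Sequence[str],
    test_values: np.ndarray,
    k: int = 5,
) -> list[str]:
    """Predict labels for test rows (restricted to ``genes``) with kNN."""
    if len(genes) == 0:
        raise ValueError("empty gene subset")
    sub = train.subset_genes(genes)
    clf = KNNClassifier(k=k).fit(sub.values, sub.labels)
    return clf.predict(np.asarray(test_values, dtype=float))


@dataclass
class MetricSet:
    """Classification metrics for one evaluation.

    Binary-only fields (sn, sp, f_score, mcc) are None for > 2 classes.
    ``confusion`` rows are true classes, columns predicted, in ``class_order``.
    """

    acc: float
    kappa: float
    confusion: np.ndarray
    class_order: list[str]
    sn: float | None = None
    sp: float | None = None
    f_score: float | None = None
    mcc: float | None = None
    positive_label: str | None = None

    def as_dict(self) -> dict[str, float]:
        out = {"acc": self.acc, "kappa": self.kappa}
        for name in ("sn", "sp", "f_score", "mcc"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; returning 0", what)
        return 0.0
    return num / den


def compute_metrics(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    positive_label: str | None = None,
) -> MetricSet:
    """Confusion-matrix metrics.

    For binary problems: Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    F = 2*Prec*Sn/(Prec+Sn), MCC = (TP*TN - FP*FN)/sqrt(prod of marginals).
    For any number of classes: accuracy and Cohen's kappa
    (p_o - p_e)/(1 - p_e). Zero denominators yield 0 with a warning.
    The positive class defaults to the lexicographically larger label.
    """
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("y_true and y_pred must have equal, non-zero length")
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    n = len(y_true)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1

    acc = conf.trace() / n
    p_o = acc
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    kappa = _safe_div(p_o - p_e, 1.0 - p_e, "kappa") if p_e != 1.0 else 0.0
    if p_e == 1.0:
        logger.warning("kappa undefined (p_e = 1); returning 0")

    ms = MetricSet(acc=float(acc), kappa=float(kappa), confusion=conf,
                   class_order=classes)
    true_classes = sorted(set(y_true))
    if len(true_classes) == 2:
        if positive_label is None:
            positive_label = max(true_classes)
        elif positive_label not in classes:
            raise ValueError(f"unknown positive label {positive_label!r}")
        pos = idx[positive_label]
        tp = int(conf[pos, pos])
        fn = int(conf[pos].sum() - tp)
        fp = int(conf[:, pos].sum() - tp)
        tn = int(n - tp - fn - fp)
        sn = _safe_div(tp, tp + fn, "sensitivity")
        sp = _safe_div(tn, tn + fp, "specificity")
        prec = _safe_div(tp, tp + fp, "precision")
        f = _safe_div(2 * prec * sn, prec + sn, "f-score")
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = _safe_div(tp * tn - fp * fn, denom, "mcc")
        ms.sn, ms.sp, ms.f_score, ms.mcc = sn, sp, f, mcc
        ms.positive_label = positive_label
    return ms


@dataclass
class EvaluationReport:
    """Per-fold metrics plus their mean/SD for one gene subset."""

    per_fold: list[MetricSet]
    means: dict[str, float]
    sds: dict[str, float]
    gene_subset: list[str]
    classifier: str
    folds: int
    repeats: int
    seed: int


def _aggregate(per_fold: list[MetricSet]) -> tuple[dict, dict]:
    keys = per_fold[0].as_dict().keys()
    means, sds = {}, {}
    for k in keys:
        vals = np.array([f.as_dict()[k] for f in per_fold], dtype=float)
        means[k] = float(vals.mean())
        sds[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return means, sds


def repeated_cv(
    data: ExpressionDataset,
    genes: Sequence[str],
    classifier="knn",
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    k: int = 5,
    positive_label: str | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold cross-validation of a fixed gene subset.

    Folds are stratified and reshuffled each repeat from a seeded generator.
    If the smallest class has fewer samples than ``folds`` the fold count is
    reduced (with a warning). The gene subset is fixed up front; nothing is
    re-fit on test folds.
    """
    sub = data.subset_genes(genes)
    class_counts = {c: sub.labels.count(c) for c in sub.classes}
    min_count = min(class_counts.values())
    eff_folds = folds
    if min_count < folds:
        eff_folds = max(2, min_count)
        logger.warning("reducing folds from %d to %d (smallest class has %d samples)",
                       folds, eff_folds, min_count)
    y = np.array(sub.labels)
    per_fold: list[MetricSet] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=eff_folds, shuffle=True,
                              random_state=seed + rep)
        for train_idx, test_idx in skf.split(sub.values, y):
            clf = make_classifier(classifier, k=k)
            eff_k = getattr(clf, "k", None)
            if eff_k is not None and eff_k > len(train_idx):
                clf = KNNClassifier(k=len(train_idx))
            clf.fit(sub.values[train_idx], list(y[train_idx]))
            pred = clf.predict(sub.values[test_idx])
            per_fold.append(
                compute_metrics(list(y[test_idx]), pred, positive_label)
            )
    means, sds = _aggregate(per_fold)
    return EvaluationReport(
        per_fold=per_fold, means=means, sds=sds, gene_subset=list(genes),
        classifier=str(classifier), folds=eff_folds, repeats=repeats, seed=seed,
    )


def best_prefix(
    data: ExpressionDataset,
    ranking: GeneRanking,
    max_k: int = 100,
    classifier="knn",
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    k: int = 5,
    positive_label: str | None = None,
) -> tuple[int, EvaluationReport]:
    """Evaluate nested prefixes top-1..top-max_k of a ranking by repeated CV.

    The best-ranked gene seeds the subsets; each subsequent subset adds the
    next-ranked gene. Returns the prefix length with the highest mean
    accuracy (ties go to the smaller prefix) and its report.
    """
    if not 1 <= max_k <= len(ranking):
        raise ValueError(f"max_k={max_k} out of range [1, {len(ranking)}]")
    best_k, best_report = None, None
    for kk in range(1, max_k + 1):
        rep = repeated_cv(data, ranking.gene_ids[:kk], classifier, folds,
                          repeats, seed, k, positive_label)
        if best_report is None or rep.means["acc"] > best_report.means["acc"]:
            best_k, best_report = kk, rep
    assert best_k is not None and best_report is not None
    return best_k, best_report


@dataclass
class SubsetSearchResult:
    evaluated: int
    best_subset: list[str]
    best_metrics: MetricSet
    table: pd.DataFrame = field(repr=False)


def exhaustive_search(
    train: ExpressionDataset,
    test: ExpressionDataset,
    candidates: Sequence[str],
    classifier="knn",
    k: int = 5,
    positive_label: str | None = None,
    criterion: str = "acc",
) -> SubsetSearchResult:
    """Exhaustive best-subset search over all 2^g - 1 non-empty subsets.

    Each subset trains on ``train`` and is scored on the independent ``test``
    set. The best subset maximizes the criterion (accuracy by default, MCC
    selectable); ties prefer smaller subsets, then lexicographic gene order.
    """
    candidates = [str(g) for g in candidates]
    if not candidates:
        raise ValueError("no candidate genes")
    if len(candidates) > 15:
        raise ValueError(
            f"{len(candidates)} candidates would need {2**len(candidates)-1} "
            "evaluations; use prefix search for larger candidate sets"
        )
    if criterion not in ("acc", "mcc"):
        raise ValueError("criterion must be 'acc' or 'mcc'")
    rows = []
    best = None  # (negated score, size, sorted subset, metrics, subset)
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            tr = train.subset_genes(combo)
            te = test.subset_genes(combo)
            clf = make_classifier(classifier, k=k)
            clf.fit(tr.values, tr.labels)
            pred = clf.predict(te.values)
            ms = compute_metrics(te.labels, pred, positive_label)
            score = ms.as_dict()[criterion]
            rows.append({"subset": ",".join(combo), "size": size,
                         **ms.as_dict()})
            key = (-score, size, tuple(sorted(combo)))
            if best is None or key < best[0]:
                best = (key, list(combo), ms)
    assert best is not None
    return SubsetSearchResult(
        evaluated=len(rows),
        best_subset=best[1],
        best_metrics=best[2],
        table=pd.DataFrame(rows),
    )


def ttest_genes(
    data: ExpressionDataset,
    genes: Sequence[str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test per gene between the two classes.

    Welch's unequal-variance test by default (pooled-variance selectable).
    Returns a DataFrame indexed by gene with columns t, p, significant
    (p <= 0.05, uncorrected). Genes with zero variance in both groups are
    flagged undefined (NaN t/p, significant False) with a warning.
    """
    classes = data.classes
    if len(classes) != 2:
        raise ValueError("t-test requires exactly 2 classes")
    sub = data.subset_genes(genes) if genes is not None else data
    idx = sub.class_indices
    a = sub.values[idx == 0]
    b = sub.values[idx == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) genes are flagged below; silence scipy's
        # precision warning about them
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if degenerate.any():
        bad = [g for g, d in zip(sub.gene_ids, degenerate) if d]
        logger.warning("t-test undefined (zero variance in both groups) for %s",
                       bad[:5])
        t[degenerate] = np.nan
        p[degenerate] = np.nan
    sig = np.where(np.isnan(p), False, p <= P_SIGNIFICANT)
    return pd.DataFrame(
        {"t": t, "p": p, "significant": sig}, index=list(sub.gene_ids)
    )


def filter_key_genes(
    hubs: Sequence[str], pvalues: Mapping[str, float]
) -> list[str]:
    """Keep hub genes with p < 0.05, ordered ascending by p (stable ties).

    The p-values come from an external survival analysis; a missing p-value
    for any hub is an error.
    """
    missing = [g for g in hubs if g not in pvalues]
    if missing:
        raise KeyError(f"missing p-values for hub genes: {missing}")
    kept = [g for g in hubs if pvalues[g] < P_SIGNIFICANT]
    return sorted(kept, key=lambda g: pvalues[g])
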