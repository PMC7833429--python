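"""Fold construction, quality metrics, cross-dataset evaluation and the
learning-curve experiment.

Clean (+1) is the positive class throughout: sensitivity is the fraction
of clean segments detected, specificity the fraction of noisy segments
detected, and the balanced accuracy bAcc = (Se + Sp)/2 compensates for
the strong class imbalance of ECG quality datasets.  Cross-dataset
evaluation applies each of the k source fold-models to each of the k
target test folds (k x k reports); the learning-curve experiment adapts
the fold-models with balanced subsets of growing size drawn either at
random or by entropy-maximising fixed-size sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .entropy import balanced_fixed_size_select, median_bandwidth
from .svm import SvmModel, fit_svm, predict
from .transfer import adapt, balanced_random_subset

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "ComparisonResult",
    "stratified_kfold",
    "compute_metrics",
    "fit_fold_models",
    "cross_dataset_eval",
    "aggregate_reports",
    "paired_ttest",
    "learning_curve",
]


@dataclass
class FoldPlan:
    """Fold index per sample; folds partition the data, stratified by class."""

    fold_of: np.ndarray
    k: int
    seed: int
    stratified: bool = True

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class MetricsReport:
    """Acc/Se/Sp/bAcc in percent; bacc == (se + sp)/2 by construction."""

    acc: float
    se: float
    sp: float

    @property
    def bacc(self) -> float:
        return (self.se + self.sp) / 2.0

    def rounded(self, ndigits: int = 1) -> dict:
        # display helper: half-up rounding to one decimal, raw values kept
        from decimal import ROUND_HALF_UP, Decimal

        q = Decimal(10) ** -ndigits
        return {k: float(Decimal(v).quantize(q, rounding=ROUND_HALF_UP))
                for k, v in [("acc", self.acc), ("se", self.se),
                             ("sp", self.sp), ("bacc", self.bacc)]}


@dataclass
class ComparisonResult:
    t: float
    df: int
    p: float
    significant: bool


def stratified_kfold(y: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan; every class must hold >= k members."""
    y = np.asarray(y, dtype=float).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if np.min(counts) < k:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small:+.0f} has {np.min(counts)} members, fewer than "
            f"k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(y.size, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        fold_of[test] = fold
    return FoldPlan(fold_of=fold_of, k=k, seed=seed)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy, sensitivity (clean = +1) and specificity in percent."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("prediction and truth lengths differ")
    pos = y_true == 1
    neg = y_true == -1
    if not pos.any() or not neg.any():
        missing = "+1 (clean)" if not pos.any() else "-1 (noisy)"
        raise ValueError(f"class {missing} absent from y_true: "
                         "sensitivity/specificity undefined")
    se = 100.0 * np.mean(y_pred[pos] == 1)
    sp = 100.0 * np.mean(y_pred[neg] == -1)
    acc = 100.0 * np.mean(y_pred == y_true)
    return MetricsReport(acc=float(acc), se=float(se), sp=float(sp))


def fit_fold_models(X: np.ndarray, y: np.ndarray, plan: FoldPlan,
                    C: float, gamma: float) -> list[SvmModel]:
    """One SVM per fold, trained on that fold's training split."""
    return [fit_svm(X[plan.train_indices(f)], y[plan.train_indices(f)],
                    C=C, gamma=gamma) for f in range(plan.k)]


def cross_dataset_eval(models: list, X_target: np.ndarray,
                       y_target: np.ndarray,
                       plan: FoldPlan) -> list[MetricsReport]:
    """Evaluate every source fold-model on every target test fold.

    Returns k_source x k_target reports ordered by (source fold, target
    fold); models may be base or adapted classifiers (anything exposing
    the prediction interface).
    """
    reports = []
    for model in models:
        for fold in range(plan.k):
            idx = plan.test_indices(fold)
            if hasattr(model, "predict"):
                _, pred = model.predict(X_target[idx])
            else:
                _, pred = predict(model, X_target[idx])
            reports.append(compute_metrics(y_target[idx], pred))
    return reports


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean and standard deviation per metric over a report list."""
    out = {}
    for name in ("acc", "se", "sp", "bacc"):
        vals = np.array([getattr(r, name) for r in reports])
        out[name] = (float(vals.mean()), float(vals.std(ddof=1))
                     if vals.size > 1 else 0.0)
    return out


def paired_ttest(a: np.ndarray, b: np.ndarray,
                 alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired t-test on metric vectors.

    Identical vectors give t = 0, p = 1; zero-variance differences with a
    non-zero mean are degenerate (infinite t) and raise instead.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return ComparisonResult(t=0.0, df=a.size - 1, p=1.0,
                                    significant=False)
        raise ValueError("all paired differences are equal and non-zero: "
                         "t statistic is undefined (zero variance)")
    res = stats.ttest_rel(a, b)
    return ComparisonResult(t=float(res.statistic), df=a.size - 1,
                            p=float(res.pvalue),
                            significant=bool(res.pvalue < alpha))


def learning_curve(base_models: list[SvmModel], X_pool: np.ndarray,
                   y_pool: np.ndarray, X_target: np.ndarray,
                   y_target: np.ndarray, target_plan: FoldPlan,
                   sizes: tuple[int, ...] = (20, 50, 100, 200, 500),
                   repeats: int = 10,
                   methods: tuple[str, ...] = ("random", "fixed_size"),
                   D: float = 100.0, max_iter: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Adaptation learning curve over subset sizes and sampling methods.

    For every (size, method, repeat): draw a balanced subset of the pool,
    adapt each base fold-model with it, and evaluate on every target test
    fold — ``len(base_models) * k`` reports per draw, all rows collected
    in a tidy frame.  A single master seed drives every subset draw, so
    the whole grid is reproducible; fixed-size sampling uses the median
    heuristic bandwidth of the standardized pool.
    """
    y_pool = np.asarray(y_pool, dtype=float).ravel()
    per_class = min(np.sum(y_pool == 1), np.sum(y_pool == -1))
    if per_class < max(sizes) // 2:
        raise ValueError(
            f"pool holds only {per_class} samples in the smaller class; "
            f"largest subset size {max(sizes)} needs {max(sizes) // 2}")
    scaler = base_models[0].scaler
    pool_std = scaler.transform(X_pool)
    sigma = median_bandwidth(pool_std)
    rows = []
    method_code = {"random": 1, "fixed_size": 2}
    for size in sizes:
        for method in methods:
            for repeat in range(repeats):
                child = np.random.SeedSequence(
                    entropy=seed, spawn_key=(size, method_code.get(method, 0),
                                             repeat))
                sub_seed = int(child.generate_state(1)[0] % 2**31)
                if method == "random":
                    idx = balanced_random_subset(y_pool, size, seed=sub_seed)
                elif method == "fixed_size":
                    sel = balanced_fixed_size_select(
                        pool_std, y_pool, size, max_iter=max_iter,
                        seed=sub_seed, sigma=sigma)
                    idx = sel.indices
                else:
                    raise ValueError(f"unknown sampling method {method!r}")
                for m, model in enumerate(base_models):
                    adapted = adapt(model, X_pool[idx], y_pool[idx], D=D)
                    for fold in range(target_plan.k):
                        te = target_plan.test_indices(fold)
                        _, pred = adapted.predict(X_target[te])
                        rep = compute_metrics(y_target[te], pred)
                        rows.append((size, method, repeat, m, fold, rep.acc,
                                     rep.se, rep.sp, rep.bacc))
    return pd.DataFrame(rows, columns=["size", "method", "repeat",
                                       "train_fold", "test_fold", "acc",
                                       "se", "sp", "bacc"])
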