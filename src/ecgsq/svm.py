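"""Base RBF-kernel soft-margin SVM for clean/noisy ECG segment classification.

The classifier separates 3-D feature vectors (FMin, MAmp, Sim) with the
usual soft-margin primal

    min_{w,b,xi}  1/2 ||w||^2 + C sum_i xi_i
    s.t.          y_i (w' phi(x_i) + b) >= 1 - xi_i,  xi_i >= 0,

solved in the dual (see :mod:`ecgsq._qp`).  Features are z-scored with
training-set statistics stored inside the model: the raw features mix
milliseconds with unitless amplitudes, and an isotropic RBF kernel is only
meaningful after the axes are put on a common scale.  The same scaler is
reused when the model is later adapted to a new recording modality, so
that the base and adapted weight vectors live in the same feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc
from sklearn.model_selection import StratifiedKFold

from ._qp import solve_svm_dual

__all__ = [
    "ScalerParams",
    "SvmModel",
    "rbf_kernel",
    "fit_svm",
    "tune_hyperparams",
    "predict",
]

MODEL_SCHEMA_VERSION = 1


@dataclass
class ScalerParams:
    """Per-feature standardisation statistics estimated on a training set."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        if np.any(self.std <= 0):
            raise ValueError("feature standard deviations must be positive")

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalerParams":
        X = np.asarray(X, dtype=float)
        return cls(mean=X.mean(axis=0), std=X.std(axis=0, ddof=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) / self.std


@dataclass
class SvmModel:
    """Fitted kernel-expansion classifier.

    ``decision(x) = sum_i alpha_i y_i k(x_i, x) + b`` with training points
    stored in standardized coordinates.
    """

    gamma: float
    C: float
    alphas: np.ndarray
    train_labels: np.ndarray
    support_points: np.ndarray
    bias: float
    scaler: ScalerParams
    kkt_gap: float = field(default=0.0, repr=False)

    @classmethod
    def zero(cls, scaler: ScalerParams, gamma: float = 1.0) -> "SvmModel":
        """The trivial model with empty expansion and zero bias (w = 0)."""
        d = scaler.mean.size
        return cls(gamma=gamma, C=1.0, alphas=np.empty(0),
                   train_labels=np.empty(0), support_points=np.empty((0, d)),
                   bias=0.0, scaler=scaler)

    def decision_function(self, X: np.ndarray, *, standardized: bool = False,
                          include_bias: bool = True) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(X, dtype=float))
        if not standardized:
            Xs = self.scaler.transform(Xs)
        if self.support_points.size == 0:
            s = np.zeros(Xs.shape[0])
        else:
            Kx = rbf_kernel(self.support_points, Xs, self.gamma)
            s = (self.alphas * self.train_labels) @ Kx
        return s + self.bias if include_bias else s

    def to_json(self) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "svm",
            "gamma": self.gamma,
            "C": self.C,
            "alphas": self.alphas.tolist(),
            "train_labels": self.train_labels.tolist(),
            "support_points": self.support_points.tolist(),
            "bias": self.bias,
            "scaler": {"mean": self.scaler.mean.tolist(),
                       "std": self.scaler.std.tolist()},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SvmModel":
        d = json.loads(text)
        if d.get("kind") != "svm":
            raise ValueError(f"not a base SVM model file (kind={d.get('kind')!r})")
        scaler = ScalerParams(np.array(d["scaler"]["mean"]),
                              np.array(d["scaler"]["std"]))
        nfeat = scaler.mean.size
        return cls(gamma=float(d["gamma"]), C=float(d["C"]),
                   alphas=np.array(d["alphas"], dtype=float),
                   train_labels=np.array(d["train_labels"], dtype=float),
                   support_points=np.array(d["support_points"],
                                           dtype=float).reshape(-1, nfeat),
                   bias=float(d["bias"]), scaler=scaler)


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-gamma ||a_i - b_j||^2)``."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}")
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 (clean) or -1 (noisy)")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the training labels")
    return y


def fit_svm(X: np.ndarray, y: np.ndarray, C: float, gamma: float) -> SvmModel:
    """Train the soft-margin RBF SVM on raw features.

    Raises ``ValueError`` on single-class input and ``QPError`` if the dual
    solve does not converge.
    """
    if C <= 0:
        raise ValueError("C must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    scaler = ScalerParams.fit(X)
    Xs = scaler.transform(X)
    K = rbf_kernel(Xs, Xs, gamma)
    res = solve_svm_dual(K, y, p=np.ones_like(y), upper=np.full_like(y, C))
    return SvmModel(gamma=gamma, C=C, alphas=res.alpha, train_labels=y,
                    support_points=Xs, bias=res.bias, scaler=scaler,
                    kkt_gap=res.kkt_gap)


def predict(model: SvmModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and hard labels; a score of exactly 0 maps to +1."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0), np.empty(0)
    scores = model.decision_function(X)
    labels = np.where(scores >= 0, 1.0, -1.0)
    return scores, labels


def _cv_bacc(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
             seed: int, k: int = 5) -> float:
    from .evaluate import compute_metrics  # local import avoids a cycle

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    baccs = []
    for tr, te in skf.split(X, y):
        model = fit_svm(X[tr], y[tr], C=C, gamma=gamma)
        _, pred = predict(model, X[te])
        baccs.append(compute_metrics(y[te], pred).bacc)
    return float(np.mean(baccs))


def tune_hyperparams(X: np.ndarray, y: np.ndarray, budget: int = 30,
                     seed: int = 0) -> tuple[float, float, float]:
    """Seeded, budgeted search for (C, gamma) maximising 5-fold CV bAcc.

    Candidates are drawn from a scrambled Sobol sequence on the log-uniform
    box [1e-3, 1e3]^2 — a quasi-random space-filling design whose best point
    is returned together with its cross-validated balanced accuracy (in
    percent).  Deterministic for a fixed seed.
    """
    if budget < 5:
        raise ValueError("hyperparameter search budget must be at least 5")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_labels(y)
    counts = [np.sum(y == c) for c in (-1.0, 1.0)]
    if min(counts) < 10:
        raise ValueError("need at least 10 samples per class for tuning")
    sampler = qmc.Sobol(d=2, scramble=True, rng=np.random.default_rng(seed))
    m = int(np.ceil(np.log2(budget)))
    u = sampler.random_base2(m)[:budget]
    log_lo, log_hi = -3.0, 3.0
    grid = 10.0 ** (log_lo + (log_hi - log_lo) * u)
    best = (np.nan, np.nan, -np.inf)
    for C, gamma in grid:
        score = _cv_bacc(X, y, C, gamma, seed=seed)
        if score > best[2]:
            best = (float(C), float(gamma), score)
    return best
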