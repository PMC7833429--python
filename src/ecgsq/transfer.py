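"""Transfer-learning adaptation of a fitted SVM to a new recording modality.

Given a base classifier with weight vector ``w`` (trained on contact ECG)
and a small labelled set from the target modality (e.g. capacitively
coupled ECG), the adapted classifier minimises

    1/2 ||w~ - w||^2 + D sum_k c_k xi_k
    s.t. y_k (w~' phi(x_k) + b~) >= 1 - xi_k,   xi_k >= 0,

i.e. hinge loss on the new data plus the discrepancy from the base weight
vector.  Writing ``w~ = w + v`` and dualising gives a standard SVM box QP
for ``v = sum_k alpha_k y_k phi(x_k)`` whose linear term is shifted by the
base decision values: ``p_k = 1 - y_k f_base(x_k)`` with box ``[0, D c_k]``.
The trade-off constant ``D`` plays the role of C; following the few-shot
regime studied here it defaults to 100, and the per-sample weights ``c_k``
default to 1 because adaptation subsets are drawn class-balanced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_svm_dual
from .svm import MODEL_SCHEMA_VERSION, ScalerParams, SvmModel, rbf_kernel

__all__ = ["AdaptedSvmModel", "adapt", "balanced_random_subset"]


@dataclass
class AdaptedSvmModel:
    """Base kernel expansion plus an adaptation expansion and a new bias."""

    base: SvmModel
    adapt_alphas: np.ndarray
    adapt_labels: np.ndarray
    adapt_points: np.ndarray        # standardized with the base scaler
    new_bias: float
    D: float
    weights: np.ndarray
    kkt_gap: float = field(default=0.0, repr=False)

    def decision_function(self, X: np.ndarray, *,
                          standardized: bool = False) -> np.ndarray:
        Xs = np.atleast_2d(np.asarray(X, dtype=float))
        if not standardized:
            Xs = self.base.scaler.transform(Xs)
        s = self.base.decision_function(Xs, standardized=True,
                                        include_bias=False)
        if self.adapt_points.size:
            Kx = rbf_kernel(self.adapt_points, Xs, self.base.gamma)
            s = s + (self.adapt_alphas * self.adapt_labels) @ Kx
        return s + self.new_bias

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.empty(0), np.empty(0)
        scores = self.decision_function(X)
        return scores, np.where(scores >= 0, 1.0, -1.0)

    def discrepancy(self) -> float:
        """``||w~ - w||^2`` evaluated through the adaptation expansion."""
        if not self.adapt_points.size:
            return 0.0
        K = rbf_kernel(self.adapt_points, self.adapt_points, self.base.gamma)
        v = self.adapt_alphas * self.adapt_labels
        return float(v @ K @ v)

    def to_json(self) -> str:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "adapted_svm",
            "base": json.loads(self.base.to_json()),
            "adapt_alphas": self.adapt_alphas.tolist(),
            "adapt_labels": self.adapt_labels.tolist(),
            "adapt_points": self.adapt_points.tolist(),
            "new_bias": self.new_bias,
            "D": self.D,
            "weights": self.weights.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "AdaptedSvmModel":
        d = json.loads(text)
        if d.get("kind") != "adapted_svm":
            raise ValueError(
                f"not an adapted SVM model file (kind={d.get('kind')!r})")
        base = SvmModel.from_json(json.dumps(d["base"]))
        nfeat = base.scaler.mean.size
        return cls(base=base,
                   adapt_alphas=np.array(d["adapt_alphas"], dtype=float),
                   adapt_labels=np.array(d["adapt_labels"], dtype=float),
                   adapt_points=np.array(d["adapt_points"],
                                         dtype=float).reshape(-1, nfeat),
                   new_bias=float(d["new_bias"]), D=float(d["D"]),
                   weights=np.array(d["weights"], dtype=float))


def adapt(base: SvmModel, X_new: np.ndarray, y_new: np.ndarray,
          D: float = 100.0, weights: np.ndarray | None = None) -> AdaptedSvmModel:
    """Fit the adapted classifier on raw target-modality features.

    ``X_new`` is standardized internally with the *base* model's scaler so
    that the discrepancy ``||w~ - w||`` is measured in the space the base
    classifier was trained in.  The new bias is recovered from free
    adaptation support vectors; when none exist (e.g. in the D -> 0 limit,
    where the adapted model degenerates to the base model) it falls back to
    the base bias.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    y = np.asarray(y_new, dtype=float).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present in the adaptation set")
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X_new and y_new lengths differ")
    if weights is None:
        weights = np.ones_like(y)
    else:
        weights = np.asarray(weights, dtype=float).ravel()
        if np.any(weights <= 0):
            raise ValueError("sample weights must be positive")

    Xs = base.scaler.transform(X)
    s_base = base.decision_function(Xs, standardized=True, include_bias=False)
    K = rbf_kernel(Xs, Xs, base.gamma)
    res = solve_svm_dual(K, y, p=1.0 - y * s_base, upper=D * weights)

    free = (res.alpha > 1e-8 * D * weights) & (res.alpha < D * weights * (1 - 1e-8))
    if free.any():
        new_bias = res.bias
    else:
        new_bias = base.bias
    return AdaptedSvmModel(base=base, adapt_alphas=res.alpha, adapt_labels=y,
                           adapt_points=Xs, new_bias=new_bias, D=D,
                           weights=weights, kkt_gap=res.kkt_gap)


def balanced_random_subset(y: np.ndarray, P: int,
                           seed: int | np.random.Generator = 0) -> np.ndarray:
    """Indices of a class-balanced uniform subsample (P/2 per class).

    Sampling is without replacement within each class and deterministic
    for a fixed seed; indices are returned sorted.
    """
    if P % 2:
        raise ValueError("subset size P must be even for class balance")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    half = P // 2
    picked = []
    for cls in (1.0, -1.0):
        members = np.flatnonzero(y == cls)
        if members.size < half:
            raise ValueError(
                f"class {cls:+.0f} has {members.size} samples, needs {half}")
        picked.append(rng.choice(members, size=half, replace=False))
    return np.sort(np.concatenate(picked))
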