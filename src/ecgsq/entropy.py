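"""Quadratic Renyi entropy and fixed-size (entropy-maximising) sampling.

The quadratic Renyi entropy of a point set, estimated with a Gaussian
kernel density surrogate, is

    Hr = -log( (1/N^2) * sum_ij K_sigma(x_i, x_j) ),

with ``K_sigma(a, b) = exp(-||a-b||^2 / (2 sigma^2))``.  Identical points
give Hr = 0 and well-separated points approach log N, so Hr acts as a
diversity measure of the set.

Fixed-size sampling greedily grows the entropy of a size-P subset: start
from a uniform random subset, propose swapping a random member with a
random non-member, and accept iff the entropy strictly increases.  The
loop stops after ``max_iter`` proposals (default 1000) or once a run of
consecutive rejections as long as the distinct-swap count signals
stagnation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "EntropyEstimate",
    "SubsetSelection",
    "median_bandwidth",
    "renyi_quadratic_entropy",
    "fixed_size_select",
    "balanced_fixed_size_select",
]


@dataclass
class EntropyEstimate:
    value: float            # nats, in [0, log N]
    sigma: float            # kernel bandwidth used


@dataclass
class SubsetSelection:
    indices: np.ndarray
    entropy_trace: np.ndarray       # accepted-entropy sequence, non-decreasing
    method: str
    seed: int | None = None
    class_traces: dict = field(default_factory=dict)


def median_bandwidth(X: np.ndarray) -> float:
    """Median pairwise Euclidean distance of the pool (median heuristic)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(X)))
    return med if med > 0 else 1.0


def _gram(X: np.ndarray, sigma: float) -> np.ndarray:
    sq = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(X * X, axis=1)[None, :]
        - 2.0 * X @ X.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma * sigma))


def renyi_quadratic_entropy(X: np.ndarray, sigma: float | None = None) -> EntropyEstimate:
    """Hr of a point set; ``sigma`` defaults to the median heuristic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    if sigma is None:
        sigma = median_bandwidth(X)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mean_k = float(np.mean(_gram(X, sigma)))
    return EntropyEstimate(value=float(-np.log(mean_k)), sigma=float(sigma))


def _kernel_row(X: np.ndarray, i: int, idx: np.ndarray, sigma: float) -> np.ndarray:
    d = X[idx] - X[i]
    return np.exp(-np.sum(d * d, axis=1) / (2.0 * sigma * sigma))


def fixed_size_select(pool: np.ndarray, P: int, max_iter: int = 1000,
                      seed: int | np.random.Generator = 0,
                      sigma: float | None = None) -> SubsetSelection:
    """Swap-based entropy-maximising selection of a size-P subset.

    The kernel sum of the current subset is maintained incrementally, so
    each proposal costs O(P) kernel evaluations.  Deterministic for a
    fixed seed; the pool is never mutated.
    """
    X = np.atleast_2d(np.asarray(pool, dtype=float))
    n = X.shape[0]
    if P > n:
        raise ValueError(f"subset size {P} exceeds pool size {n}")
    if P < 1:
        raise ValueError("subset size must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if sigma is None:
        sigma = median_bandwidth(X)

    subset = rng.choice(n, size=P, replace=False)
    in_subset = np.zeros(n, dtype=bool)
    in_subset[subset] = True
    Ksub = _gram(X[subset], sigma)
    total = float(Ksub.sum())

    def entropy(tot: float) -> float:
        return float(-np.log(tot / (P * P)))

    trace = [entropy(total)]
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    if P == n:
        return SubsetSelection(indices=np.sort(subset),
                               entropy_trace=np.array(trace),
                               method="fixed_size", seed=seed_val)

    outside = np.flatnonzero(~in_subset)
    # stagnation: stop only after a run of rejections comparable to the
    # number of distinct exchange moves, so "no more increase" is not
    # declared before the move space has plausibly been covered
    patience = max(n, min(P * (n - P), max_iter))
    rejections = 0
    for _ in range(max_iter):
        pos = rng.integers(P)              # member slot to swap out
        out_pos = rng.integers(outside.size)
        new = outside[out_pos]
        old = subset[pos]
        # kernel sums of old/new against the subset without the old member
        row_old = Ksub[pos].copy()
        row_old[pos] = 0.0
        row_new = _kernel_row(X, new, subset, sigma)
        row_new[pos] = 0.0
        new_total = total - 2.0 * row_old.sum() - Ksub[pos, pos] \
            + 2.0 * row_new.sum() + 1.0
        if new_total < total:              # entropy strictly increases
            subset[pos] = new
            outside[out_pos] = old
            row_new[pos] = 1.0
            Ksub[pos, :] = row_new
            Ksub[:, pos] = row_new
            total = new_total
            trace.append(entropy(total))
            rejections = 0
        else:
            rejections += 1
            if rejections >= patience:
                break
    return SubsetSelection(indices=np.sort(subset),
                           entropy_trace=np.array(trace),
                           method="fixed_size", seed=seed_val)


def balanced_fixed_size_select(X: np.ndarray, y: np.ndarray, P: int,
                               max_iter: int = 1000,
                               seed: int = 0,
                               sigma: float | None = None) -> SubsetSelection:
    """Fixed-size selection run independently per class, P/2 points each."""
    if P % 2:
        raise ValueError("subset size P must be even for class balance")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    half = P // 2
    rng = np.random.default_rng(seed)
    picked, traces = [], {}
    for cls in (1.0, -1.0):
        members = np.flatnonzero(y == cls)
        if members.size < half:
            raise ValueError(
                f"class {cls:+.0f} has {members.size} samples, needs {half}")
        sel = fixed_size_select(X[members], half, max_iter=max_iter,
                                seed=rng, sigma=sigma)
        picked.append(members[sel.indices])
        traces[int(cls)] = sel.entropy_trace
    return SubsetSelection(indices=np.sort(np.concatenate(picked)),
                           entropy_trace=np.empty(0),
                           method="fixed_size_balanced", seed=seed,
                           class_traces=traces)
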