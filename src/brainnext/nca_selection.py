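"""Neighborhood component analysis (NCA) feature weighting and selection.

This is the feature-selection variant of NCA: each feature r carries a
non-negative weight v_r, the distance between samples is the weighted
Manhattan (L1) distance d_ij = sum_r v_r |x_ir - x_jr| / sigma, and
stochastic-neighbour probabilities p_ij ∝ exp(-d_ij) (j != i) define the
expected leave-one-out classification objective

    f(v) = sum_i sum_{j: y_j = y_i} p_ij  -  lambda * sum_r v_r .

sigma is a global length-scale (the mean pairwise distance at unit weights)
that keeps initial distances O(1) so the softmax spreads over many
neighbours and gradients stay informative.  The objective is maximised by
projected gradient ascent (weights clipped at zero after each step), which
keeps every weight's gradient alive at the boundary; reported weights are
the v_r themselves, hence non-negative, and features are ranked by
decreasing weight with ties broken by ascending index.  Full-batch mode
(default) uses a backtracking step control that keeps the objective
non-decreasing and is fully deterministic; a seeded stochastic mode performs
shuffled per-sample updates.

``iterative_sweep`` evaluates a downstream classifier's cross-validated
accuracy over a range of top-k subset sizes (the default range 100..1000
yields 901 entries) and reports the best k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from brainnext.errors import ConfigurationError


@dataclass
class NCAConfig:
    regularization: float | None = None   # lambda; default 1/n at fit time
    learning_rate: float = 0.5
    epochs: int = 30
    batch_mode: str = "full"              # "full" | "stochastic"
    seed: int = 0
    standardize: bool = True
    feature_chunk: int = 256              # gradient chunking over features
    max_samples: int = 2000               # seeded subsample threshold

    def validate(self) -> None:
        if self.regularization is not None and self.regularization < 0:
            raise ConfigurationError("regularization must be >= 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_mode not in ("full", "stochastic"):
            raise ConfigurationError(f"unknown batch_mode {self.batch_mode!r}")


@dataclass
class NCAResult:
    weights: np.ndarray            # w_r^2, non-negative, length d
    index: np.ndarray              # 0-based feature indices, decreasing weight
    objective_trace: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        rank = np.empty(len(self.index), dtype=int)
        rank[self.index] = np.arange(1, len(self.index) + 1)
        pd.DataFrame({
            "feature_index": np.arange(1, len(self.weights) + 1),
            "weight": self.weights,
            "rank": rank,
        }).to_csv(path, index=False)


@dataclass
class SweepResult:
    k_values: np.ndarray
    accuracies: np.ndarray
    best_k: int

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"k": self.k_values, "accuracy": self.accuracies}
                     ).to_csv(path, index=False)


def _as_matrix(F) -> np.ndarray:
    X = F.values if hasattr(F, "values") else np.asarray(F)
    return np.asarray(X, dtype=np.float64)


def _objective_and_grad(X, same, lam, v, sigma, chunk):
    """Objective f(v) and gradient df/dv for the weighted-L1 NCA objective.

    same[i, j] = 1 where y_i == y_j (diagonal excluded).  Distances and the
    gradient are accumulated in feature chunks so the n x n x d tensor is
    never materialised.
    """
    n, d = X.shape
    # keep the n x n x chunk difference tensor under ~200 MB
    chunk = max(1, min(chunk, int(2.5e7 / max(n * n, 1))))
    dist = np.zeros((n, n))
    for s in range(0, d, chunk):
        diff = np.abs(X[:, None, s:s + chunk] - X[None, :, s:s + chunk])
        dist += diff @ v[s:s + chunk]
    dist /= sigma
    np.fill_diagonal(dist, np.inf)
    dist -= dist.min(axis=1, keepdims=True)
    P = np.exp(-dist)
    P /= P.sum(axis=1, keepdims=True)
    p_in = (P * same).sum(axis=1)
    f = float(p_in.sum() - lam * v.sum())

    # dF/d(dist_ij) assembled as M_ij = p_i * P_ij - P_ij * same_ij,
    # then df/dv_r = sum_ij M_ij |x_ir - x_jr| / sigma - lam
    M = P * p_in[:, None] - P * same
    grad = np.empty(d)
    for s in range(0, d, chunk):
        diff = np.abs(X[:, None, s:s + chunk] - X[None, :, s:s + chunk])
        grad[s:s + chunk] = np.einsum("ij,ijr->r", M, diff)
    grad = grad / sigma - lam
    return f, grad


def _length_scale(X, chunk=256) -> float:
    """Mean pairwise L1 distance at unit weights (the softmax length-scale)."""
    n, d = X.shape
    chunk = max(1, min(chunk, int(2.5e7 / max(n * n, 1))))
    total = 0.0
    for s in range(0, d, chunk):
        total += np.abs(X[:, None, s:s + chunk]
                        - X[None, :, s:s + chunk]).sum()
    mean = total / (n * (n - 1)) if n > 1 else 1.0
    return float(mean) if mean > 0 else 1.0


def nca_fit(F, y, cfg: NCAConfig | None = None) -> NCAResult:
    """Fit NCA feature weights; returns non-negative weights, the ranking
    index (ties by ascending feature index) and the objective trace."""
    cfg = cfg or NCAConfig()
    cfg.validate()
    X = _as_matrix(F)
    y = np.asarray(y)
    n, d = X.shape
    if d == 0:
        raise ConfigurationError("feature matrix has zero columns")
    if len(np.unique(y)) < 2:
        raise ConfigurationError("need at least two classes")
    if y.shape[0] != n:
        raise ConfigurationError("labels length does not match rows")
    bad = ~np.all(np.isfinite(X), axis=0)
    if bad.any():
        raise ConfigurationError(
            f"non-finite values in feature column {int(np.where(bad)[0][0])}")
    if n > cfg.max_samples:
        keep = np.random.default_rng(cfg.seed).choice(n, cfg.max_samples,
                                                      replace=False)
        X, y = X[keep], y[keep]
        n = cfg.max_samples
    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    lam = cfg.regularization if cfg.regularization is not None else 1.0 / n
    same = (y[:, None] == y[None, :]).astype(np.float64)
    np.fill_diagonal(same, 0.0)

    sigma = _length_scale(X, cfg.feature_chunk)
    v = np.ones(d)
    trace: list[float] = []
    if cfg.batch_mode == "full":
        lr = cfg.learning_rate
        f, grad = _objective_and_grad(X, same, lam, v, sigma,
                                      cfg.feature_chunk)
        trace.append(f)
        for _ in range(cfg.epochs):
            gnorm = np.linalg.norm(grad)
            if gnorm < 1e-12:
                break
            step = grad / max(gnorm, 1e-12)
            # backtracking: never accept a step that lowers the objective
            while lr > 1e-8:
                v_new = np.maximum(v + lr * step, 0.0)
                f_new, g_new = _objective_and_grad(X, same, lam, v_new,
                                                   sigma, cfg.feature_chunk)
                if f_new >= f:
                    v = v_new
                    f, grad = f_new, g_new
                    lr *= 1.05
                    break
                lr *= 0.5
            trace.append(f)
    else:
        rng = np.random.default_rng(cfg.seed)
        lr = cfg.learning_rate / n
        for _ in range(cfg.epochs):
            for i in rng.permutation(n):
                diff = np.abs(X - X[i])              # n x d
                dist = (diff @ v) / sigma
                dist[i] = np.inf
                dist -= dist.min()
                p = np.exp(-dist)
                p /= p.sum()
                p_in = float(p @ same[i])
                g = ((p_in * p - p * same[i]) @ diff) / sigma - lam / n
                v = np.maximum(v + lr * g, 0.0)
            f, _ = _objective_and_grad(X, same, lam, v, sigma,
                                       cfg.feature_chunk)
            trace.append(f)

    index = np.argsort(-v, kind="stable")
    return NCAResult(weights=v, index=index, objective_trace=trace)


def select_top_k(result: NCAResult, F, k: int):
    """Columns of F at the k highest-weight feature indices, in rank order.

    Returns (selected n x k matrix, 0-based indices used).
    """
    X = _as_matrix(F)
    d = X.shape[1]
    if not 1 <= k <= d:
        raise ConfigurationError(f"k={k} out of range 1..{d}")
    idx = result.index[:k]
    return X[:, idx], idx


def iterative_sweep(result: NCAResult, F, y, k_min: int = 100,
                    k_max: int = 1000, classifier_cfg=None) -> SweepResult:
    """Cross-validated accuracy of the harness classifier for every top-k
    subset size in k_min..k_max (inclusive); best k is the first maximiser."""
    from brainnext.evaluation import ClassifierConfig, cross_validate

    X = _as_matrix(F)
    y = np.asarray(y)
    if k_min > k_max:
        raise ConfigurationError("k_min must be <= k_max")
    if k_max > X.shape[1]:
        raise ConfigurationError(
            f"k_max={k_max} exceeds feature count {X.shape[1]}")
    cfg = classifier_cfg or ClassifierConfig()
    ks = np.arange(k_min, k_max + 1)
    accs = np.empty(len(ks))
    cols = X[:, result.index[:k_max]]      # rank-ordered once, sliced per k
    for i, k in enumerate(ks):
        accs[i] = cross_validate(cols[:, :k], y, cfg).accuracy
    best = int(ks[int(np.argmax(accs))])
    return SweepResult(k_values=ks, accuracies=accs, best_k=best)
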