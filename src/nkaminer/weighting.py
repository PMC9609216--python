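"""Ten attribute-weighting algorithms and threshold-based dataset selection.

Each algorithm produces a raw relevance score per attribute which is then
min-max normalized to [0, 1]; attributes scoring at or above an
algorithm- and task-specific threshold form a "selected dataset".  The
eleven analysis datasets are the FCD plus one selected dataset per
algorithm.

Shared conventions: discretizations (chi-square, symmetrical uncertainty)
use 10 equal-frequency bins; entropies are in bits; an attribute with zero
range scores 0 raw for every algorithm; SVM and PCA and relief operate on
z-scored attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2_contingency

from .config import SELECTION_THRESHOLDS
from .io import AttributeTable
from .trees import best_split

ALGORITHMS = (
    "chi_square", "deviation", "gini_index", "info_gain", "info_gain_ratio",
    "pca", "relief", "rule", "svm", "uncertainty",
)


@dataclass
class WeightVector:
    algorithm: str
    weights: pd.Series  # attribute -> score in [0, 1]

    def top(self, k: int) -> list[str]:
        return list(self.weights.sort_values(ascending=False).index[:k])


@dataclass
class SelectedDataset:
    algorithm: str
    threshold: float
    attributes: list[str]
    table: AttributeTable


def _check_classes(y: np.ndarray) -> np.ndarray:
    classes, codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("weighting needs at least two classes")
    return codes


def _normalize(raw: pd.Series) -> pd.Series:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return pd.Series(np.where(hi > 0, 1.0, 0.0), index=raw.index)
    return (raw - lo) / (hi - lo)


def _discretize(v: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning; duplicate quantile edges are merged."""
    edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, v, side="right")


def _entropy(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / len(codes)
    return float(-(p * np.log2(p)).sum())


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    return _entropy(a) + _entropy(b) - _entropy(a * (b.max() + 1) + b)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


# --- the ten raw scorers ---------------------------------------------------


def _raw_chi_square(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        b = _discretize(X[:, j])
        if b.max() == 0:
            continue
        table = pd.crosstab(b, y).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        out[j] = chi2_contingency(table, correction=False).statistic
    return out


def _raw_deviation(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    mean = X.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), 0.0)
    return np.where(sd > 0, cv, 0.0)


def _raw_best_split(X: np.ndarray, y: np.ndarray, criterion: str) -> np.ndarray:
    k = int(y.max()) + 1
    return np.array(
        [best_split(X[:, j], y, criterion, k)[1] for j in range(X.shape[1])]
    )


def _raw_pca(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Aggregate |loading| weighted by variance share over the components
    covering 95% cumulative variance."""
    Z = _zscore(X)
    Z = Z - Z.mean(axis=0)
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    if var.sum() == 0:
        return np.zeros(X.shape[1])
    share = var / var.sum()
    k = int(np.searchsorted(np.cumsum(share), 0.95)) + 1
    return np.abs(vt[:k]).T @ share[:k]


def _raw_relief(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """ReliefF with every row as a sampling target.

    Manhattan nearest neighbours on z-scored attributes; numeric diff
    |a-b| / range; miss terms weighted by class prior / (1 - prior of the
    target's class).
    """
    Z = _zscore(X)
    rng_ = Z.max(axis=0) - Z.min(axis=0)
    rng_ = np.where(rng_ > 0, rng_, 1.0)
    n, p = Z.shape
    dist = cdist(Z, Z, metric="cityblock")
    np.fill_diagonal(dist, np.inf)
    classes = np.unique(y)
    priors = {c: float((y == c).sum()) / n for c in classes}
    idx_by_class = {c: np.nonzero(y == c)[0] for c in classes}
    W = np.zeros(p)
    for i in range(n):
        ci = y[i]
        hits = idx_by_class[ci]
        k_h = min(k, len(hits) - 1)
        if k_h > 0:
            order = hits[np.argsort(dist[i, hits], kind="stable")][:k_h]
            W -= (np.abs(Z[order] - Z[i]) / rng_).sum(axis=0) / (n * k_h)
        for c in classes:
            if c == ci:
                continue
            misses = idx_by_class[c]
            k_m = min(k, len(misses))
            if k_m == 0:
                continue
            order = misses[np.argsort(dist[i, misses], kind="stable")][:k_m]
            w_c = priors[c] / (1.0 - priors[ci])
            W += w_c * (np.abs(Z[order] - Z[i]) / rng_).sum(axis=0) / (n * k_m)
    return W


def _raw_rule(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Training accuracy of the best one-attribute threshold rule."""
    n = len(y)
    k = int(y.max()) + 1
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        v = X[:, j]
        order = np.argsort(v, kind="stable")
        sv = v[order]
        cum = np.cumsum(onehot[order], axis=0)
        boundary = np.nonzero(sv[:-1] < sv[1:])[0]
        if boundary.size == 0:
            continue
        left = cum[boundary]
        right = cum[-1][None, :] - left
        acc = (left.max(axis=1) + right.max(axis=1)) / n
        out[j] = float(acc.max())
    return out


def _raw_svm(X: np.ndarray, y: np.ndarray, epochs: int = 200, C: float = 1.0) -> np.ndarray:
    """Coefficient norms of one-vs-rest linear SVMs.

    Deterministic full-batch subgradient descent on the hinge loss for a
    fixed epoch count (row-order invariant by construction); the weight
    only needs coefficient magnitudes, not a converged margin.
    """
    Z = _zscore(X)
    n, p = Z.shape
    lam = 1.0 / (C * n)
    coefs = []
    for c in np.unique(y):
        t_ = (y == c).astype(float) * 2 - 1
        w = np.zeros(p)
        b = 0.0
        for t in range(1, epochs + 1):
            eta = 1.0 / (lam * t * n)
            viol = t_ * (Z @ w + b) < 1
            w = (1.0 - eta * lam * n) * w + eta * (t_[viol] @ Z[viol])
            b = b + eta * t_[viol].sum()
        coefs.append(w)
    return np.sqrt((np.stack(coefs) ** 2).sum(axis=0))


def _raw_uncertainty(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    h_y = _entropy(y)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        b = _discretize(X[:, j])
        h_b = _entropy(b)
        denom = h_b + h_y
        if denom > 0:
            out[j] = 2.0 * _mutual_information(b, y) / denom
    return out


_RAW = {
    "chi_square": _raw_chi_square,
    "deviation": _raw_deviation,
    "gini_index": lambda X, y: _raw_best_split(X, y, "gini_index"),
    "info_gain": lambda X, y: _raw_best_split(X, y, "information_gain"),
    "info_gain_ratio": lambda X, y: _raw_best_split(X, y, "gain_ratio"),
    "pca": _raw_pca,
    "relief": _raw_relief,
    "rule": _raw_rule,
    "svm": _raw_svm,
    "uncertainty": _raw_uncertainty,
}


def weight_attributes(table: AttributeTable, label_col: str, algorithm: str) -> WeightVector:
    """Score every attribute of ``table`` against the given class label."""
    if algorithm not in _RAW:
        raise ValueError(f"unknown weighting algorithm {algorithm!r}")
    X = table.data.to_numpy(dtype=float)
    y = _check_classes(table.labels[label_col].to_numpy())
    raw = pd.Series(_RAW[algorithm](X, y), index=table.attributes)
    return WeightVector(algorithm=algorithm, weights=_normalize(raw))


def weight_all(table: AttributeTable, label_col: str) -> dict[str, WeightVector]:
    return {alg: weight_attributes(table, label_col, alg) for alg in ALGORITHMS}


def select_attributes(
    wv: WeightVector, threshold: float, table: AttributeTable
) -> SelectedDataset:
    """Project the table onto {attribute : weight >= threshold}."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"selection threshold must lie in [0, 1], got {threshold}")
    chosen = [a for a in table.attributes if wv.weights[a] >= threshold]
    sub = table.subset(chosen)
    sub.provenance["dataset"] = wv.algorithm
    sub.provenance["threshold"] = repr(threshold)
    return SelectedDataset(wv.algorithm, threshold, chosen, sub)


def task_threshold(task: str, algorithm: str) -> float:
    spec = SELECTION_THRESHOLDS[task]
    return spec.get(algorithm, spec["default"])


def make_all_datasets(
    fcd: AttributeTable, label_col: str, task: str,
    weights: dict[str, WeightVector] | None = None,
) -> dict[str, AttributeTable]:
    """The 11 analysis datasets: FCD plus one per weighting algorithm."""
    if task not in SELECTION_THRESHOLDS:
        raise ValueError(f"unknown task {task!r}")
    weights = weights or weight_all(fcd, label_col)
    out: dict[str, AttributeTable] = {"fcd": fcd}
    for alg in ALGORITHMS:
        sel = select_attributes(weights[alg], task_threshold(task, alg), fcd)
        out[alg] = sel.table
    return out
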