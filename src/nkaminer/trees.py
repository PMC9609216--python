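"""Decision-tree induction, cross-validated evaluation and the model sweep.

Four model flavors (decision tree, random forest, decision stump, random
tree) crossed with four binary-split criteria (gain ratio, information
gain, Gini index, accuracy) over a collection of datasets; "performance"
is stratified k-fold cross-validation accuracy in percent.

All splits are binary thresholds on numeric attributes.  Candidate
thresholds are midpoints between consecutive distinct sorted values.
Tie-breaking is deterministic: attribute ties go to the earlier attribute
in inventory order (scores compared with a 1e-12 relative tolerance, since
mathematically tied scores can differ by ulps), threshold ties within an
attribute go to the smaller threshold, and vote ties in ensembles go to
the earlier class in sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import TreeParams, fork_seed
from .io import AttributeTable

CRITERIA = ("gain_ratio", "information_gain", "gini_index", "accuracy")
MODELS = ("decision_tree", "random_forest", "decision_stump", "random_tree")

_TIE_TOL = 1e-12


def _entropy_rows(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Entropy in bits for each row of class counts."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -terms.sum(axis=1)


def _gini_rows(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    p = counts / totals[:, None]
    return 1.0 - (p * p).sum(axis=1)


def split_scores(
    values: np.ndarray, y: np.ndarray, n_classes: int, criterion: str
) -> tuple[np.ndarray, np.ndarray]:
    """Score every candidate threshold of one attribute.

    Returns (thresholds, scores) in ascending threshold order; empty
    arrays when the attribute is constant.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    sv = values[order]
    sy = y[order]
    boundary = np.nonzero(sv[:-1] < sv[1:])[0]  # split after index k
    if boundary.size == 0:
        return np.empty(0), np.empty(0)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), sy] = 1.0
    cum = np.cumsum(onehot, axis=0)
    left = cum[boundary]  # class counts on the <= side
    total = cum[-1]
    right = total[None, :] - left
    nl = left.sum(axis=1)
    nr = n - nl
    thresholds = 0.5 * (sv[boundary] + sv[boundary + 1])

    if criterion in ("information_gain", "gain_ratio"):
        h_parent = _entropy_rows(total[None, :], np.array([float(n)]))[0]
        ig = h_parent - (nl / n) * _entropy_rows(left, nl) - (nr / n) * _entropy_rows(right, nr)
        if criterion == "information_gain":
            scores = ig
        else:
            pl, pr = nl / n, nr / n
            split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(split_info > 0, ig / split_info, 0.0)
            scores = np.where(ig > 0, scores, 0.0)
    elif criterion == "gini_index":
        g_parent = _gini_rows(total[None, :], np.array([float(n)]))[0]
        scores = g_parent - (nl / n) * _gini_rows(left, nl) - (nr / n) * _gini_rows(right, nr)
    elif criterion == "accuracy":
        scores = (left.max(axis=1) + right.max(axis=1)) / n - total.max() / n
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return thresholds, np.maximum(scores, 0.0)


def best_split(
    values: np.ndarray, y: np.ndarray, criterion: str, n_classes: int | None = None
) -> tuple[Optional[float], float]:
    """Best threshold for one attribute: (threshold, score).

    A constant attribute yields (None, 0.0), signalling "no split".
    Threshold ties go to the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind not in "iu":
        _, y = np.unique(y, return_inverse=True)
    k = int(n_classes) if n_classes is not None else int(y.max()) + 1
    thresholds, scores = split_scores(values, y, k, criterion)
    if thresholds.size == 0:
        return None, 0.0
    # ties (within float tolerance) go to the smaller threshold
    top = float(scores.max())
    i = int(np.argmax(scores >= top - _TIE_TOL * max(1.0, abs(top))))
    return float(thresholds[i]), float(scores[i])


# ---------------------------------------------------------------------------
# Tree structures


@dataclass
class Node:
    # internal node
    attribute: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["Node"] = None   # values <= threshold
    right: Optional["Node"] = None  # values > threshold
    # leaf
    klass: Optional[int] = None
    distribution: Optional[np.ndarray] = None
    n_rows: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None


@dataclass
class TrainedTree:
    root: Node
    flavor: str
    criterion: str
    attribute_names: list[str]
    classes: list[str]
    metadata: dict = field(default_factory=dict)

    def predict_row(self, x: np.ndarray) -> int:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.attribute] <= node.threshold else node.right
        return node.klass

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.array([self.predict_row(row) for row in X])

    def predict_labels(self, X: np.ndarray) -> list[str]:
        return [self.classes[i] for i in self.predict(X)]

    @property
    def root_attribute(self) -> Optional[str]:
        if self.root.is_leaf:
            return None
        return self.attribute_names[self.root.attribute]

    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(node: Node, indent: str) -> None:
            if node.is_leaf:
                lines.append(f"{indent}-> {self.classes[node.klass]} (n={node.n_rows})")
            else:
                name = self.attribute_names[node.attribute]
                lines.append(f"{indent}{name} <= {node.threshold:.6g}")
                rec(node.left, indent + "  ")
                lines.append(f"{indent}{name} > {node.threshold:.6g}")
                rec(node.right, indent + "  ")

        rec(self.root, "")
        return "\n".join(lines)


@dataclass
class TrainedForest:
    trees: list[TrainedTree]
    classes: list[str]
    flavor: str = "random_forest"

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.stack([t.predict(X) for t in self.trees])
        n_classes = len(self.classes)
        out = np.empty(votes.shape[1], dtype=int)
        for j in range(votes.shape[1]):
            counts = np.bincount(votes[:, j], minlength=n_classes)
            out[j] = int(np.argmax(counts))  # tie -> earlier class
        return out

    def predict_labels(self, X: np.ndarray) -> list[str]:
        return [self.classes[i] for i in self.predict(X)]


def _choose_split(
    X: np.ndarray, y: np.ndarray, n_classes: int, attrs: Sequence[int], criterion: str
) -> tuple[Optional[int], Optional[float], float]:
    best_attr, best_thr, best_score = None, None, 0.0
    for j in attrs:
        thr, score = best_split(X[:, j], y, criterion, n_classes)
        if thr is None:
            continue
        if score > best_score + _TIE_TOL * max(1.0, abs(best_score)):
            best_attr, best_thr, best_score = j, thr, score
    return best_attr, best_thr, best_score


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    criterion: str,
    params: TreeParams,
    depth: int,
    rng: Optional[np.random.Generator],
    n_attrs_subset: Optional[int],
) -> Node:
    counts = np.bincount(y, minlength=n_classes)
    leaf = Node(klass=int(np.argmax(counts)), distribution=counts, n_rows=len(y))
    if counts.max() == len(y):  # pure
        return leaf
    if params.max_depth is not None and depth >= params.max_depth:
        return leaf
    if len(y) < params.min_leaf:
        return leaf
    p = X.shape[1]
    if n_attrs_subset is not None and rng is not None and n_attrs_subset < p:
        attrs = np.sort(rng.choice(p, size=n_attrs_subset, replace=False))
    else:
        attrs = np.arange(p)
    attr, thr, score = _choose_split(X, y, n_classes, attrs, criterion)
    min_gain = params.minimal_gain
    if attr is None or (min_gain is not None and score < min_gain) or score <= 0.0:
        return leaf
    mask = X[:, attr] <= thr
    node = Node(attribute=int(attr), threshold=float(thr), n_rows=len(y), distribution=counts)
    node.left = _grow(X[mask], y[mask], n_classes, criterion, params, depth + 1, rng, n_attrs_subset)
    node.right = _grow(X[~mask], y[~mask], n_classes, criterion, params, depth + 1, rng, n_attrs_subset)
    return node


def _as_xy(X, y, attribute_names=None):
    if isinstance(X, pd.DataFrame):
        attribute_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if attribute_names is None:
            attribute_names = [f"attr_{j}" for j in range(X.shape[1])]
    classes, y_codes = np.unique(np.asarray(y), return_inverse=True)
    return X, y_codes, attribute_names, [str(c) for c in classes]


def induce_tree(
    X, y, criterion: str = "information_gain",
    params: TreeParams | None = None, attribute_names=None, flavor: str = "decision_tree",
) -> TrainedTree:
    """Greedy top-down induction of a single binary decision tree."""
    params = params or TreeParams()
    X, y_codes, names, classes = _as_xy(X, y, attribute_names)
    root = _grow(X, y_codes, len(classes), criterion, params, 0, None, None)
    return TrainedTree(root=root, flavor=flavor, criterion=criterion,
                       attribute_names=names, classes=classes)


def induce_stump(X, y, criterion: str = "information_gain",
                 params: TreeParams | None = None, attribute_names=None) -> TrainedTree:
    """Depth-1 tree (decision stump)."""
    base = params or TreeParams()
    stump_params = TreeParams(max_depth=1, minimal_gain=base.minimal_gain,
                              min_leaf=base.min_leaf)
    return induce_tree(X, y, criterion, stump_params, attribute_names, flavor="decision_stump")


def induce_random_tree(
    X, y, criterion: str = "information_gain", params: TreeParams | None = None,
    seed: int = 0, attribute_names=None, flavor: str = "random_tree",
) -> TrainedTree:
    """Single tree considering a random ceil(sqrt(p)) attribute subset per node."""
    params = params or TreeParams()
    X, y_codes, names, classes = _as_xy(X, y, attribute_names)
    p = X.shape[1]
    subset = params.subset_size or int(np.ceil(np.sqrt(p)))
    rng = np.random.default_rng(seed)
    root = _grow(X, y_codes, len(classes), criterion, params, 0, rng, subset)
    tree = TrainedTree(root=root, flavor=flavor, criterion=criterion,
                       attribute_names=names, classes=classes)
    tree.metadata["seed"] = seed
    return tree


def induce_forest(
    X, y, criterion: str = "information_gain", params: TreeParams | None = None,
    seed: int = 0, attribute_names=None,
) -> TrainedForest:
    """Bootstrap ensemble of random trees with majority voting."""
    params = params or TreeParams()
    Xa, y_codes, names, classes = _as_xy(X, y, attribute_names)
    n = Xa.shape[0]
    rng = np.random.default_rng(seed)
    trees = []
    for b in range(params.forest_size):
        idx = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        p = Xa.shape[1]
        subset = params.subset_size or int(np.ceil(np.sqrt(p)))
        t_rng = np.random.default_rng(tree_seed)
        root = _grow(Xa[idx], y_codes[idx], len(classes), criterion, params, 0, t_rng, subset)
        trees.append(TrainedTree(root=root, flavor="random_tree", criterion=criterion,
                                 attribute_names=names, classes=classes))
    return TrainedForest(trees=trees, classes=classes)


def fit_model(model: str, X, y, criterion: str, params: TreeParams, seed: int,
              attribute_names=None):
    if model == "decision_tree":
        return induce_tree(X, y, criterion, params, attribute_names)
    if model == "decision_stump":
        return induce_stump(X, y, criterion, params, attribute_names)
    if model == "random_tree":
        return induce_random_tree(X, y, criterion, params, seed, attribute_names)
    if model == "random_forest":
        return induce_forest(X, y, criterion, params, seed, attribute_names)
    raise ValueError(f"unknown model flavor {model!r}")


def evaluate(model: str, X, y, criterion: str = "information_gain",
             folds: int = 10, seed: int = 0, params: TreeParams | None = None) -> float:
    """Stratified k-fold cross-validation accuracy, in percent."""
    params = params or TreeParams()
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        names = None
        Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    _, class_counts = np.unique(ya, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; use folds <= that"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    correct = 0
    for k, (train, test) in enumerate(skf.split(Xa, ya)):
        fitted = fit_model(model, Xa[train], ya[train], criterion, params,
                           fork_seed(seed, f"fold{k}"), attribute_names=names)
        pred = fitted.predict_labels(Xa[test])
        correct += sum(p == t for p, t in zip(pred, ya[test]))
    return 100.0 * correct / len(ya)


# ---------------------------------------------------------------------------
# Sweep


@dataclass
class Route:
    conjuncts: list[tuple[str, str, float]]  # (attribute, "<=" or ">", threshold)
    klass: str
    n_rows: int

    def __str__(self) -> str:
        conds = " and ".join(f"{a} {op} {t:.6g}" for a, op, t in self.conjuncts)
        return f"[{conds or 'always'}] -> {self.klass} (n={self.n_rows})"


def extract_routes(tree: TrainedTree) -> list[Route]:
    """One route per leaf, ordered by leaf training-row coverage descending."""
    routes: list[Route] = []

    def rec(node: Node, path: list[tuple[str, str, float]]) -> None:
        if node.is_leaf:
            routes.append(Route(list(path), tree.classes[node.klass], node.n_rows))
            return
        name = tree.attribute_names[node.attribute]
        rec(node.left, path + [(name, "<=", node.threshold)])
        rec(node.right, path + [(name, ">", node.threshold)])

    rec(tree.root, [])
    routes.sort(key=lambda r: -r.n_rows)
    return routes


@dataclass
class SweepResult:
    """Performance matrix over model x criterion x dataset plus summaries."""

    performance: pd.DataFrame  # MultiIndex (model, criterion) x dataset columns
    best_cells: list[tuple[str, str, str]]
    best_value: float
    root_attributes: dict[tuple[str, str, str], Optional[str]]
    best_tree_cell: tuple[str, str, str]
    best_tree: TrainedTree
    routes: list[Route]

    @property
    def n_cells(self) -> int:
        return int(self.performance.notna().to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.performance.to_csv(path, sep="\t", float_format="%.12g")


def run_sweep(
    datasets: dict[str, AttributeTable], label_col: str,
    models: Sequence[str] = MODELS, criteria: Sequence[str] = CRITERIA,
    folds: int = 10, seed: int = 0, params: TreeParams | None = None,
) -> SweepResult:
    """Evaluate every model x criterion x dataset cell.

    Also trains one full-data decision tree per (criterion, dataset) so the
    best single tree's root attribute and routes can be inspected; the best
    single tree is the highest-performing ``decision_tree`` cell (ties
    prefer the information-gain criterion, then earlier datasets).
    """
    if not datasets:
        raise ValueError("empty dataset list")
    params = params or TreeParams()
    index = pd.MultiIndex.from_product([models, criteria], names=["model", "criterion"])
    perf = pd.DataFrame(np.nan, index=index, columns=list(datasets))
    root_attrs: dict[tuple[str, str, str], Optional[str]] = {}
    for ds_name, table in datasets.items():
        y = table.labels[label_col].to_numpy()
        X = table.data
        for model in models:
            for criterion in criteria:
                cell_seed = fork_seed(seed, f"{model}:{criterion}:{ds_name}")
                acc = evaluate(model, X, y, criterion, folds, cell_seed, params)
                perf.loc[(model, criterion), ds_name] = acc
                if model in ("decision_tree", "decision_stump", "random_tree"):
                    fitted = fit_model(model, X, y, criterion, params, cell_seed,
                                       attribute_names=list(X.columns))
                    root_attrs[(model, criterion, ds_name)] = fitted.root_attribute

    best_value = float(np.nanmax(perf.to_numpy()))
    best_cells = [
        (m, c, d)
        for (m, c) in perf.index
        for d in perf.columns
        if perf.loc[(m, c), d] == best_value
    ]
    # Best single decision tree (for route inspection).  Performance ties
    # are common on cleanly separable data; among tied cells prefer the
    # information-gain criterion (the conventional best-model choice for
    # this analysis — gain ratio degenerates to 1.0 for every clean
    # class-grouping split, making its in-tree attribute ties arbitrary),
    # then earlier datasets in listed order (FCD first).
    preference = [c for c in ("information_gain", "gain_ratio", "gini_index",
                              "accuracy") if c in criteria]
    preference += [c for c in criteria if c not in preference]
    dt = perf.loc["decision_tree"]
    best_dt_value = float(np.nanmax(dt.to_numpy()))
    best_tree_cell = next(
        ("decision_tree", c, d)
        for c in preference
        for d in dt.columns
        if dt.loc[c, d] == best_dt_value
    )
    _, crit, ds = best_tree_cell
    table = datasets[ds]
    tree = induce_tree(table.data, table.labels[label_col].to_numpy(), crit, params)
    return SweepResult(
        performance=perf, best_cells=best_cells, best_value=best_value,
        root_attributes=root_attrs, best_tree_cell=best_tree_cell,
        best_tree=tree, routes=extract_routes(tree),
    )
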