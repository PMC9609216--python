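"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is written with naive loops and textbook formulas,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def naive_entropy(labels) -> float:
    n = len(labels)
    return -sum(
        (c / n) * math.log2(c / n) for c in Counter(labels).values()
    )


def naive_gini(labels) -> float:
    n = len(labels)
    return 1.0 - sum((c / n) ** 2 for c in Counter(labels).values())


def naive_chi_square(categories, labels) -> float:
    """Pearson chi-square of the category x label contingency table."""
    cats = sorted(set(categories))
    labs = sorted(set(labels))
    n = len(labels)
    obs = {(c, l): 0 for c in cats for l in labs}
    for c, l in zip(categories, labels):
        obs[(c, l)] += 1
    row = {c: sum(obs[(c, l)] for l in labs) for c in cats}
    col = {l: sum(obs[(c, l)] for c in cats) for l in labs}
    stat = 0.0
    for c in cats:
        for l in labs:
            e = row[c] * col[l] / n
            if e > 0:
                stat += (obs[(c, l)] - e) ** 2 / e
    return stat


def naive_mutual_information(a, b) -> float:
    joint = [f"{x}|{y}" for x, y in zip(a, b)]
    return naive_entropy(a) + naive_entropy(b) - naive_entropy(joint)


def naive_symmetrical_uncertainty(a, labels) -> float:
    denom = naive_entropy(a) + naive_entropy(labels)
    if denom == 0:
        return 0.0
    return 2.0 * naive_mutual_information(a, labels) / denom


def enumerate_splits(values, labels, criterion: str):
    """Exhaustive midpoint enumeration for one attribute.

    Returns (best_threshold, best_score); ties keep the smaller threshold.
    Criteria: information_gain (bits), gain_ratio, gini_index (impurity
    decrease), accuracy (majority-accuracy gain).
    """
    values = list(values)
    labels = list(labels)
    n = len(values)
    distinct = sorted(set(values))
    best_thr, best_score = None, 0.0
    parent_majority = max(Counter(labels).values()) / n
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2.0
        left = [l for v, l in zip(values, labels) if v <= thr]
        right = [l for v, l in zip(values, labels) if v > thr]
        pl, pr = len(left) / n, len(right) / n
        if criterion == "information_gain":
            score = naive_entropy(labels) - pl * naive_entropy(left) - pr * naive_entropy(right)
        elif criterion == "gain_ratio":
            ig = naive_entropy(labels) - pl * naive_entropy(left) - pr * naive_entropy(right)
            split_info = -(pl * math.log2(pl) + pr * math.log2(pr))
            score = ig / split_info if (ig > 0 and split_info > 0) else 0.0
        elif criterion == "gini_index":
            score = naive_gini(labels) - pl * naive_gini(left) - pr * naive_gini(right)
        elif criterion == "accuracy":
            acc = (max(Counter(left).values()) + max(Counter(right).values())) / n
            score = acc - parent_majority
        else:
            raise ValueError(criterion)
        if score > best_score + 1e-15:
            best_thr, best_score = thr, score
    return best_thr, max(best_score, 0.0)


def biopython_global_score(a: str, b: str, gap_open: float = 10.0,
                           gap_extend: float = 1.0) -> float:
    """Independent affine-gap global alignment score via Biopython."""
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(a, b))
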