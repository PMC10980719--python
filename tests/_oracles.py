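"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's code paths: naive Lance-Williams
agglomeration for the Ward (ward.D2) splits, exhaustive pair enumeration
for the confusion metrics, and rank recomputation for gene selection.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_distance_naive(X: np.ndarray) -> np.ndarray:
    """1 - Pearson between columns, via np.corrcoef (zero-variance-free)."""
    R = np.corrcoef(X, rowvar=False)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    return D


def ward_two_split(D: np.ndarray) -> list[list[int]]:
    """Greedy ward.D2 agglomeration down to two clusters.

    Lance-Williams update on squared dissimilarities; among equal-cost
    merges the lexicographically smallest pair of cluster creation indices
    is merged first.
    """
    n = D.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(members) > 2:
        (a, b) = min(dist, key=lambda k: (dist[k], k))
        na, nb = len(members[a]), len(members[b])
        dab = dist[(a, b)]
        new_dist = {}
        for c in members:
            if c in (a, b):
                continue
            nc = len(members[c])
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            d2 = (
                (na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dab**2
            ) / (na + nb + nc)
            new_dist[(c, next_id)] = math.sqrt(max(d2, 0.0))
        members[next_id] = members.pop(a) + members.pop(b)
        dist = {
            k: v for k, v in dist.items() if a not in k and b not in k
        }
        dist.update(new_dist)
        next_id += 1
    return [sorted(m) for m in members.values()]


def recursive_ward_pairs(
    X: np.ndarray, cell_idx: np.ndarray, size_max: int
) -> set[tuple[int, int]]:
    """All within-terminal-cluster pairs under recursive 2-way Ward splits.

    ``X`` is genes x cells; distances are recomputed per recursion level
    over the member cells only.
    """
    n = len(cell_idx)
    if n <= size_max:
        return {
            (int(cell_idx[a]), int(cell_idx[b]))
            for a in range(n)
            for b in range(a + 1, n)
        } if n >= 2 else set()
    D = pearson_distance_naive(X[:, cell_idx])
    pairs: set[tuple[int, int]] = set()
    for group in ward_two_split(D):
        pairs |= recursive_ward_pairs(X, cell_idx[np.asarray(group)], size_max)
    return pairs


def confusion_oracle(
    counts: np.ndarray, cell_ids, truth: dict, threshold: float
) -> tuple[int, int, int, int]:
    """TP/FP/FN/TN over annotated-cell pairs by exhaustive enumeration."""
    tp = fp = fn = tn = 0
    n = len(cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cell_ids[i], cell_ids[j]
            if a not in truth or b not in truth:
                continue
            same = truth[a] == truth[b]
            pred = counts[i, j] >= threshold
            if pred and same:
                tp += 1
            elif pred:
                fp += 1
            elif same:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def percentile_rank_naive(values: np.ndarray) -> np.ndarray:
    """100 * (mean rank - 0.5) / n, gene-by-gene with explicit tie counting."""
    n = len(values)
    out = np.empty(n)
    for i, v in enumerate(values):
        below = int(np.sum(values < v))
        ties = int(np.sum(values == v))
        mean_rank = below + (ties + 1) / 2.0
        out[i] = 100.0 * (mean_rank - 0.5) / n
    return out


def select_oracle(mean_q, var_q, thresholds) -> np.ndarray:
    """Boolean selection by evaluating the gate disjunction per gene."""
    picked = np.zeros(len(mean_q), dtype=bool)
    for g in range(len(mean_q)):
        if np.isnan(mean_q[g]):
            continue
        for a, b in thresholds:
            if mean_q[g] >= a and var_q[g] >= b:
                picked[g] = True
                break
    return picked


def group_mean_cv2_naive(X: np.ndarray, groups: list[list[int]]) -> np.ndarray:
    """CV² of unweighted group means per gene, straight from the formula."""
    means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    mu = means.mean(axis=1)
    var = means.var(axis=1, ddof=1)
    out = np.zeros(X.shape[0])
    pos = mu > 0
    out[pos] = var[pos] / mu[pos] ** 2
    return out
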