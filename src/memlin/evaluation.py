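"""Pair-level scoring of predicted lineages against ground truth.

Predictions are scored as unordered cell pairs: a pair is truth-positive
when both cells share a ground-truth lineage and predicted-positive at
confidence level X when its confidence is >= X.  Precision = TP/(TP+FP),
sensitivity = TP/(TP+FN), FPR = FP/(FP+TN), each per threshold; AUC is the
rank-based (Mann-Whitney) ROC area using the confidence level as the
ranking score, computed once per evaluation.

Only cells with a ground-truth annotation enter the scoring — barcode-style
ground truths are partial, and counting unannotated cells as negatives
would penalize correct novel predictions.  Stratified variants score pairs
by cell-type symmetry (both members same type = symmetric) or by
ground-truth lineage size (a pair belongs to size stratum s when one or
both cells are members of a truth lineage of size s).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from memlin.data_io import (
    CellTypeAnnotation,
    LineagePartition,
    MemlinError,
    ParameterError,
)
from memlin.lineage_inference import ConfidenceMatrix

__all__ = [
    "PairConfusion",
    "evaluate",
    "classify_symmetry",
    "stratified_evaluate",
    "pair_type_counts",
    "confusion_frame",
]


@dataclass
class PairConfusion:
    """Pair-level confusion counts and metrics at one confidence threshold.

    ``precision`` is NaN when nothing is predicted positive (TP+FP = 0);
    ``auc`` is the threshold-free ROC area shared by all thresholds of the
    same evaluation (NaN when a class is empty).
    """

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    auc: float

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def fpr(self) -> float:
        denom = self.fp + self.tn
        return self.fp / denom if denom else float("nan")


def _pair_arrays(cm: ConfidenceMatrix, truth: LineagePartition):
    """Confidence and truth-co-membership vectors over annotated-cell pairs."""
    annotated = [
        i for i, c in enumerate(cm.cell_ids) if c in truth.assignments
    ]
    if len(annotated) < 2:
        raise MemlinError("need >= 2 cells with ground-truth annotation")
    idx = np.asarray(annotated, dtype=int)
    sub = cm.counts[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    conf = sub[iu, ju].astype(float)
    labels = np.array([truth.assignments[cm.cell_ids[i]] for i in idx], dtype=object)
    same = labels[iu] == labels[ju]
    return conf, same, idx, iu, ju


def _rank_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """ROC area via the Mann-Whitney rank statistic, ties mid-ranked."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = scipy.stats.rankdata(scores, method="average")
    return (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def _confusions(conf, same, thresholds, auc) -> list[PairConfusion]:
    out = []
    n_pos = int(same.sum())
    n_pairs = len(same)
    for x in thresholds:
        pred = conf >= x
        tp = int((pred & same).sum())
        fp = int(pred.sum()) - tp
        fn = n_pos - tp
        tn = n_pairs - tp - fp - fn
        out.append(PairConfusion(float(x), tp, fp, fn, tn, auc))
    return out


def evaluate(
    cm: ConfidenceMatrix,
    truth: LineagePartition,
    thresholds=None,
) -> list[PairConfusion]:
    """Score a confidence matrix against a ground-truth partition.

    Returns one :class:`PairConfusion` per threshold (default: 0..R in
    steps of 10), all sharing the same rank-based AUC.
    """
    if thresholds is None:
        thresholds = list(range(0, cm.n_repetitions + 1, 10))
    conf, same, *_ = _pair_arrays(cm, truth)
    auc = _rank_auc(conf, same)
    return _confusions(conf, same, thresholds, auc)


def confusion_frame(results: dict | list) -> pd.DataFrame:
    """Tabulate PairConfusion lists (optionally per stratum) as a DataFrame."""
    if isinstance(results, list):
        results = {"all": results}
    rows = []
    for stratum, confs in results.items():
        for c in confs:
            rows.append(
                {
                    "stratum": stratum,
                    "threshold": c.threshold,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "tn": c.tn,
                    "precision": c.precision,
                    "sensitivity": c.sensitivity,
                    "fpr": c.fpr,
                    "auc": c.auc,
                }
            )
    return pd.DataFrame(rows)


def classify_symmetry(
    lp: LineagePartition,
    ct: CellTypeAnnotation,
    mode: str = "lineage",
):
    """Label lineages (or within-lineage pairs) symmetric vs asymmetric.

    ``lineage`` mode: a lineage is symmetric iff all members share one cell
    type; lineages with a member lacking a type annotation are labeled
    ``"unknown"`` (callers should exclude them).  ``pair`` mode labels each
    unordered within-lineage pair by whether its two members share a type.
    """
    if mode == "lineage":
        out: dict[str, str] = {}
        for lin, members in lp.lineages().items():
            types = [ct.types.get(c) for c in members]
            if any(t is None for t in types):
                out[lin] = "unknown"
            elif len(set(types)) == 1:
                out[lin] = "symmetric"
            else:
                out[lin] = "asymmetric"
        return out
    if mode == "pair":
        out_pairs: dict[tuple[str, str], str] = {}
        for _, members in lp.lineages().items():
            for a, b in combinations(members, 2):
                ta, tb = ct.types.get(a), ct.types.get(b)
                if ta is None or tb is None:
                    out_pairs[(a, b)] = "unknown"
                else:
                    out_pairs[(a, b)] = "symmetric" if ta == tb else "asymmetric"
        return out_pairs
    raise ParameterError(f"unknown symmetry mode {mode!r}")


def stratified_evaluate(
    cm: ConfidenceMatrix,
    truth: LineagePartition,
    celltypes: CellTypeAnnotation | None = None,
    size_strata=None,
    thresholds=None,
) -> dict[str, list[PairConfusion]]:
    """Per-stratum pair scoring.

    With ``celltypes``, pairs of the entire prediction matrix are split
    into ``symmetric`` (both cells the same type) and ``asymmetric``
    strata; pairs with an untyped member are dropped.  With
    ``size_strata`` (iterable of ints), the stratum for size s keeps pairs
    in which one or both cells belong to a ground-truth lineage of size s.
    Empty strata are reported as empty lists.
    """
    if (celltypes is None) == (size_strata is None):
        raise ParameterError("provide exactly one of celltypes or size_strata")
    if thresholds is None:
        thresholds = list(range(0, cm.n_repetitions + 1, 10))
    conf, same, idx, iu, ju = _pair_arrays(cm, truth)
    out: dict[str, list[PairConfusion]] = {}
    if celltypes is not None:
        types = np.array(
            [celltypes.types.get(cm.cell_ids[i]) for i in idx], dtype=object
        )
        known = (types[iu] != None) & (types[ju] != None)  # noqa: E711
        sym = known & (types[iu] == types[ju])
        asym = known & ~sym
        for name, mask in (("symmetric", sym), ("asymmetric", asym)):
            if mask.any():
                out[name] = _confusions(
                    conf[mask], same[mask], thresholds,
                    _rank_auc(conf[mask], same[mask]),
                )
            else:
                out[name] = []
    else:
        sizes = truth.sizes()
        cell_size = np.array(
            [sizes[truth.assignments[cm.cell_ids[i]]] for i in idx], dtype=int
        )
        for s in size_strata:
            mask = (cell_size[iu] == s) | (cell_size[ju] == s)
            if mask.any():
                out[f"size_{s}"] = _confusions(
                    conf[mask], same[mask], thresholds,
                    _rank_auc(conf[mask], same[mask]),
                )
            else:
                out[f"size_{s}"] = []
    return out


def pair_type_counts(
    lp: LineagePartition, ct: CellTypeAnnotation
) -> pd.DataFrame:
    """Count within-lineage cell pairs per unordered cell-type combination.

    Entry (t1, t2) is the number of unordered within-lineage pairs whose
    member types are {t1, t2}; the returned matrix is symmetric and its
    total equals sum over lineages of C(size, 2) (pairs with an untyped
    member are excluded).
    """
    labels = sorted(set(ct.types.values()))
    pos = {t: i for i, t in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for _, members in lp.lineages().items():
        for a, b in combinations(members, 2):
            ta, tb = ct.types.get(a), ct.types.get(b)
            if ta is None or tb is None:
                continue
            i, j = pos[ta], pos[tb]
            counts[i, j] += 1
            if i != j:
                counts[j, i] += 1
    return pd.DataFrame(counts, index=labels, columns=labels)
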