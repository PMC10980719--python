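import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from _oracles import confusion_oracle
from memlin import (
    ConfidenceMatrix,
    classify_symmetry,
    evaluate,
    pair_type_counts,
    stratified_evaluate,
)
from memlin.data_io import CellTypeAnnotation, LineagePartition, MemlinError


def _cm(counts, reps=100):
    counts = np.asarray(counts)
    ids = [f"c{i}" for i in range(counts.shape[0])]
    counts = counts + counts.T
    np.fill_diagonal(counts, reps)
    return ConfidenceMatrix(counts, reps, ids)


class TestEvaluate:
    def test_perfect_prediction(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 90  # the only true pair, predicted
        cm = _cm(counts)
        truth = LineagePartition({"c0": "A", "c1": "A", "c2": "B", "c3": "C"})
        (res,) = evaluate(cm, truth, [50])
        assert (res.tp, res.fp, res.fn, res.tn) == (1, 0, 0, 5)
        assert res.precision == 1.0 and res.sensitivity == 1.0 and res.fpr == 0.0

    def test_worked_four_cell_example(self):
        # truth {A,B}; predicted-positive pairs {(A,B), (A,C)}
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 80
        counts[0, 2] = 80
        cm = _cm(counts)
        truth = LineagePartition({"c0": "X", "c1": "X", "c2": "Y", "c3": "Z"})
        (res,) = evaluate(cm, truth, [50])
        assert (res.tp, res.fp, res.fn, res.tn) == (1, 1, 0, 4)
        assert res.precision == 0.5
        assert res.sensitivity == 1.0
        assert res.fpr == pytest.approx(0.2)

    def test_auc_of_perfectly_ranked_pair(self):
        # one true pair scored 90, five true negatives scored 10 -> AUC 1
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 1] = 90
        counts[0, 2] = counts[0, 3] = counts[1, 2] = counts[1, 3] = counts[2, 3] = 10
        cm = _cm(counts)
        truth = LineagePartition({"c0": "A", "c1": "A", "c2": "B", "c3": "C"})
        (res,) = evaluate(cm, truth, [50])
        assert res.auc == 1.0

    def test_matches_exhaustive_oracle_and_sklearn_auc(self):
        rng = np.random.default_rng(0)
        n = 40
        counts = np.triu(rng.integers(0, 101, size=(n, n)), k=1)
        cm = _cm(counts)
        truth = LineagePartition(
            {f"c{i}": f"L{i // 3}" for i in range(n) if i % 5 != 0}
        )
        thresholds = [0, 25, 50, 75, 100]
        results = evaluate(cm, truth, thresholds)
        annotated = [i for i in range(n) if f"c{i}" in truth.assignments]
        conf, same = [], []
        for ai, i in enumerate(annotated):
            for j in annotated[ai + 1:]:
                conf.append(cm.counts[i, j])
                same.append(truth.assignments[f"c{i}"] == truth.assignments[f"c{j}"])
        for res, t in zip(results, thresholds):
            expect = confusion_oracle(cm.counts, cm.cell_ids, truth.assignments, t)
            assert (res.tp, res.fp, res.fn, res.tn) == expect
        assert results[0].auc == pytest.approx(roc_auc_score(same, conf))

    def test_monotone_traces_and_conservation(self):
        rng = np.random.default_rng(1)
        counts = np.triu(rng.integers(0, 101, size=(20, 20)), k=1)
        cm = _cm(counts)
        truth = LineagePartition({f"c{i}": f"L{i // 4}" for i in range(20)})
        results = evaluate(cm, truth, list(range(0, 101, 10)))
        n_truth_pairs = results[0].tp + results[0].fn
        prev_pred = np.inf
        for res in results:
            assert res.tp + res.fn == n_truth_pairs
            pred = res.tp + res.fp
            assert pred <= prev_pred
            prev_pred = pred

    def test_no_annotated_cells_raises(self):
        cm = _cm(np.zeros((3, 3), dtype=int))
        with pytest.raises(MemlinError):
            evaluate(cm, LineagePartition({}), [50])


class TestSymmetry:
    def test_lineage_mode(self):
        lp = LineagePartition({"c1": "L1", "c2": "L1", "c3": "L2",
                               "c4": "L2", "c5": "L2", "c6": "L3"})
        ct = CellTypeAnnotation(
            {"c1": "A", "c2": "A", "c3": "A", "c4": "B", "c5": "A"}
        )
        labels = classify_symmetry(lp, ct, mode="lineage")
        assert labels["L1"] == "symmetric"
        assert labels["L2"] == "asymmetric"
        assert labels["L3"] == "unknown"  # c6 untyped

    def test_pair_mode(self):
        lp = LineagePartition({"c1": "L", "c2": "L", "c3": "L"})
        ct = CellTypeAnnotation({"c1": "A", "c2": "B", "c3": "A"})
        labels = classify_symmetry(lp, ct, mode="pair")
        assert labels[("c1", "c3")] == "symmetric"
        assert labels[("c1", "c2")] == "asymmetric"
        assert labels[("c2", "c3")] == "asymmetric"


class TestStratified:
    def _setup(self):
        rng = np.random.default_rng(2)
        n = 12
        counts = np.triu(rng.integers(0, 101, size=(n, n)), k=1)
        cm = _cm(counts)
        truth = LineagePartition({f"c{i}": f"L{i // 3}" for i in range(n)})
        return cm, truth

    def test_single_type_puts_everything_in_symmetric_stratum(self):
        cm, truth = self._setup()
        ct = CellTypeAnnotation({c: "onlytype" for c in cm.cell_ids})
        strata = stratified_evaluate(cm, truth, celltypes=ct, thresholds=[50])
        assert strata["asymmetric"] == []
        (sym,) = strata["symmetric"]
        (overall,) = evaluate(cm, truth, [50])
        assert (sym.tp, sym.fp, sym.fn, sym.tn) == (
            overall.tp, overall.fp, overall.fn, overall.tn,
        )

    def test_per_stratum_truth_pair_conservation(self):
        cm, truth = self._setup()
        types = {f"c{i}": ("A" if i % 2 else "B") for i in range(12)}
        ct = CellTypeAnnotation(types)
        strata = stratified_evaluate(cm, truth, celltypes=ct,
                                     thresholds=[0, 50, 100])
        for name, confs in strata.items():
            truth_pairs = {c.tp + c.fn for c in confs}
            assert len(truth_pairs) == 1  # conserved across thresholds
        # the two strata partition all annotated pairs
        total = sum(c.tp + c.fp + c.fn + c.tn
                    for s in strata.values() for c in s if c.threshold == 50)
        assert total == 12 * 11 // 2

    def test_absent_size_stratum_is_empty(self):
        cm, truth = self._setup()  # all truth lineages have size 3
        strata = stratified_evaluate(cm, truth, size_strata=[2, 3],
                                     thresholds=[50])
        assert strata["size_2"] == []
        assert len(strata["size_3"]) == 1


class TestPairTypeCounts:
    def test_two_cell_lineage(self):
        lp = LineagePartition({"c1": "L", "c2": "L"})
        ct = CellTypeAnnotation({"c1": "A", "c2": "B"})
        counts = pair_type_counts(lp, ct)
        assert counts.loc["A", "B"] == 1
        assert counts.loc["B", "A"] == 1
        assert counts.loc["A", "A"] == 0

    def test_triplet_combinatorics(self):
        lp = LineagePartition({"c1": "L", "c2": "L", "c3": "L"})
        ct = CellTypeAnnotation({"c1": "A", "c2": "A", "c3": "B"})
        counts = pair_type_counts(lp, ct)
        assert counts.loc["A", "A"] == 1
        assert counts.loc["A", "B"] == 2

    def test_total_is_sum_of_pairs_per_lineage(self):
        lp = LineagePartition(
            {f"c{i}": f"L{i // 4}" for i in range(12)}  # 3 lineages of 4
        )
        ct = CellTypeAnnotation(
            {f"c{i}": ("A" if i % 3 else "B") for i in range(12)}
        )
        counts = pair_type_counts(lp, ct).to_numpy()
        # upper triangle incl. diagonal counts each unordered combo once
        total = np.triu(counts).sum()
        assert total == 3 * (4 * 3 // 2)
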