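import numpy as np
import pytest
import scipy.stats

from _oracles import group_mean_cv2_naive
from memlin import (
    call_memory_genes,
    categorize,
    similarity_report,
    variance_inflation,
)
from memlin.data_io import ExpressionMatrix, LineagePartition, MemlinError


def _matrix(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
        normalized=True,
    )


def _partition(sizes):
    assignments, c = {}, 0
    for k, s in enumerate(sizes):
        for _ in range(s):
            assignments[f"c{c}"] = f"L{k}"
            c += 1
    return LineagePartition(assignments)


class TestCallMemoryGenes:
    def test_constant_gene_never_memory(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(1, 1, size=(5, 12))
        values[0] = 3.0
        table = call_memory_genes(_matrix(values), _partition([3, 3, 3, 3]))
        assert table.cv2_lineage_means[0] == 0.0
        assert table.p_value[0] == 1.0
        assert not table.is_memory[0]

    def test_planted_gene_hits_permutation_floor(self):
        rng = np.random.default_rng(1)
        values = rng.lognormal(1, 0.1, size=(10, 12))
        lineage_level = np.repeat([1.0, 8.0, 1.0, 20.0], 3)
        values[0] = lineage_level * rng.lognormal(0, 0.02, 12)
        m = _matrix(values)
        lp = _partition([3, 3, 3, 3])
        table = call_memory_genes(m, lp, size_range=(2, 5), n_null=20, seed=3)
        # with 20 nulls the smallest achievable p is 1/21
        assert table.p_value[0] == pytest.approx(1 / 21)
        assert table.is_memory[0]
        # observed statistic equals a naive group-mean CV2 recomputation
        groups = [[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]]
        expect = group_mean_cv2_naive(m.dense(), groups)
        np.testing.assert_allclose(table.cv2_lineage_means, expect, rtol=1e-12)

    def test_invariant_to_lineage_relabeling_and_cell_order(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(1, 0.5, size=(8, 10))
        m = _matrix(values)
        lp = _partition([2, 3, 2, 3])
        relabeled = LineagePartition(
            {c: f"renamed_{l}" for c, l in lp.assignments.items()}
        )
        a = call_memory_genes(m, lp, seed=7)
        b = call_memory_genes(m, relabeled, seed=7)
        np.testing.assert_allclose(a.cv2_lineage_means, b.cv2_lineage_means)
        np.testing.assert_allclose(a.p_value, b.p_value)

    def test_size_range_excluding_all_lineages_raises(self):
        m = _matrix(np.random.default_rng(0).lognormal(1, 1, (4, 6)))
        with pytest.raises(MemlinError, match="size"):
            call_memory_genes(m, _partition([3, 3]), size_range=(4, 9))


class TestCategorize:
    def _table_for(self, values, is_memory):
        m = _matrix(values)
        lp = _partition([2] * (values.shape[1] // 2))
        table = call_memory_genes(m, lp, size_range=(2, 5), seed=0)
        table.is_memory = np.asarray(is_memory)
        return categorize(table, m), m

    def test_symmetric_distribution_is_quantitative(self):
        vals = np.tile([1.0, 2.0, 3.0, 2.0, 1.0, 2.0, 3.0, 2.0], (2, 1))
        vals[1] = np.random.default_rng(0).lognormal(0, 0.1, 8)
        table, _ = self._table_for(vals, [True, False])
        assert abs(table.skewness[0]) < 1e-9
        assert table.category[0] == "quantitative"
        assert table.category[1] == "none"

    def test_rare_on_gene_matches_bernoulli_skewness(self):
        # 1 cell of 100 "on": skewness ~ (1-2p)/sqrt(p(1-p)) ~ 9.8
        n, p = 100, 0.01
        gene = np.zeros(n)
        gene[0] = 1.0
        vals = np.vstack([gene, np.random.default_rng(1).lognormal(0, 0.2, n)])
        table, _ = self._table_for(vals, [True, True])
        expect = (1 - 2 * p) / np.sqrt(p * (1 - p))
        assert table.skewness[0] == pytest.approx(expect, rel=1e-6)
        assert table.category[0] == "qualitative"

    def test_skewness_threshold_is_inclusive_at_three(self):
        # two-point genes straddling sample skewness 3:
        # k on-cells of n: skew = (1-2k/n)/sqrt(k/n*(1-k/n))
        n = 250
        just_below = np.zeros(n)
        just_below[:21] = 1.0  # skew 2.998
        just_above = np.zeros(n)
        just_above[:20] = 1.0  # skew 3.096
        vals = np.vstack([just_below, just_above])
        table, _ = self._table_for(vals, [True, True])
        assert table.skewness[0] < 3 <= table.skewness[1]
        assert table.category[0] == "quantitative"
        assert table.category[1] == "qualitative"

    def test_skewness_matches_biased_moment_formula(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(1, 1, size=(6, 30))
        table, m = self._table_for(vals, [True] * 6)
        X = m.dense()
        m2 = ((X - X.mean(1, keepdims=True)) ** 2).mean(1)
        m3 = ((X - X.mean(1, keepdims=True)) ** 3).mean(1)
        np.testing.assert_allclose(table.skewness, m3 / m2**1.5, rtol=1e-10)


class TestVarianceInflation:
    def _planted(self, sigma_b, seed=0, n_genes=60, n_lineages=24, size=3):
        rng = np.random.default_rng(seed)
        n_cells = n_lineages * size
        lin = np.repeat(np.arange(n_lineages), size)
        base = rng.lognormal(2, 0.5, n_genes)
        lin_eff = rng.normal(0, sigma_b, size=(n_genes, n_lineages))
        noise = rng.normal(0, 0.2, size=(n_genes, n_cells))
        values = base[:, None] * np.exp(lin_eff[:, lin] + noise)
        return _matrix(values), _partition([size] * n_lineages)

    def test_null_labels_give_near_zero_inflation(self):
        m, lp = self._planted(sigma_b=0.0, seed=1)
        res = variance_inflation(m, lp, size_range=(2, 5), n_perm=20, seed=2)
        assert abs(res.inflation_pct) < 5.0

    def test_planted_between_lineage_variance_detected(self):
        m, lp = self._planted(sigma_b=0.8, seed=1)
        res = variance_inflation(m, lp, size_range=(2, 5), n_perm=20, seed=2)
        assert res.inflation_pct > 10.0

    def test_inflation_increases_with_between_lineage_variance(self):
        m1, lp = self._planted(sigma_b=0.4, seed=3)
        m2, _ = self._planted(sigma_b=0.8, seed=3)
        r1 = variance_inflation(m1, lp, size_range=(2, 5), n_perm=20, seed=4)
        r2 = variance_inflation(m2, lp, size_range=(2, 5), n_perm=20, seed=4)
        assert r2.inflation_pct > r1.inflation_pct


class TestSimilarityReport:
    def test_duplicated_lineages_have_zero_within_distance(self):
        rng = np.random.default_rng(0)
        profiles = rng.lognormal(1, 1, size=(20, 5))
        values = np.repeat(profiles, 2, axis=1)  # 5 lineages of twins
        m = _matrix(values)
        report = similarity_report(m, _partition([2] * 5), n_random=20, seed=1)
        assert report["within_lineage"]["median"] == pytest.approx(0.0, abs=1e-12)
        assert report["random_groups"]["median"] > 0.01

    def test_permuted_labels_indistinguishable_from_random(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.lognormal(1, 0.5, size=(30, 20)))
        hits = 0
        for seed in range(10):
            perm = np.random.default_rng(seed).permutation(20)
            lp = LineagePartition(
                {f"c{perm[i]}": f"L{i // 2}" for i in range(20)}
            )
            rep = similarity_report(m, lp, n_random=50, seed=seed)
            stat = scipy.stats.mannwhitneyu(
                rep["within_values"], rep["random_values"]
            )
            hits += stat.pvalue > 0.01
        assert hits >= 8  # calibrated: no real signal in >= 80% of seeds

    def test_single_random_replicate_boundary(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.lognormal(1, 1, size=(10, 6)))
        rep = similarity_report(m, _partition([3, 3]), n_random=1, seed=0)
        assert rep["n_random"] == 1
        assert len(rep["random_values"]) == len(rep["within_values"])
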