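import numpy as np
import pytest
import scipy.stats

from progenet.sc_profiles import (
    SCExpressionMatrix,
    celltype_gene_means,
    expressed_in_cells,
    filter_cells,
    filter_genes,
    program_profile,
    successive_stage_tests,
    zscore_genes,
)


def _matrix(values, stages=None, stage_order=None):
    values = np.asarray(values, float)
    n_genes, n_cells = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{j}" for j in range(n_cells)]
    stages = stages or ["A"] * n_cells
    labels = dict(zip(cells, stages))
    order = stage_order or list(dict.fromkeys(stages))
    return SCExpressionMatrix(values=values, gene_ids=genes, cell_ids=cells,
                              labels=labels, stage_order=order)


class TestFilterCells:
    def test_full_expressor_retained(self):
        mat = _matrix(np.ones((20, 2)))
        assert filter_cells(mat).n_cells == 2

    def test_exactly_at_threshold_retained(self):
        values = np.zeros((20, 1))
        values[0, 0] = 2.0  # 1/20 = 5% of genes at TPM >= 1
        mat = _matrix(values)
        assert filter_cells(mat, min_frac_genes=0.05).n_cells == 1

    def test_below_threshold_removed(self):
        values = np.zeros((40, 2))
        values[0, 0] = 2.0   # cell 0: 1/40 < 5%
        values[:3, 1] = 2.0  # cell 1: 3/40 >= 5%
        out = filter_cells(_matrix(values), min_frac_genes=0.05)
        assert out.cell_ids == ["c1"]

    def test_all_removed_error(self):
        with pytest.raises(ValueError, match="all cells"):
            filter_cells(_matrix(np.zeros((10, 3))))

    def test_random_matrix_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.exponential(1.0, size=(100, 40))
        values[rng.random(values.shape) < 0.6] = 0.0
        mat = _matrix(values)
        out = filter_cells(mat, min_frac_genes=0.05, tpm_min=1.0)
        expected = [j for j in range(40)
                    if sum(values[i, j] >= 1.0 for i in range(100)) / 100 >= 0.05]
        assert out.cell_ids == [f"c{j}" for j in expected]


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        values = np.ones((3, 10))
        values[1] = 0.0
        out = filter_genes(_matrix(values))
        assert out.gene_ids == ["g0", "g2"]

    def test_exactly_at_threshold_retained(self):
        values = np.zeros((2, 20))
        values[0, 0] = 0.5  # nonzero in 1/20 = 5%
        values[1, :] = 1.0
        out = filter_genes(_matrix(values), min_frac_cells=0.05)
        assert "g0" in out.gene_ids

    def test_random_matches_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.exponential(1.0, size=(60, 30))
        values[rng.random(values.shape) < 0.7] = 0.0
        out = filter_genes(_matrix(values), min_frac_cells=0.1)
        expected = [i for i in range(60)
                    if (values[i] > 0).sum() / 30 >= 0.1]
        assert out.gene_ids == [f"g{i}" for i in expected]

    def test_permutation_commutes(self):
        rng = np.random.default_rng(3)
        values = rng.exponential(1.0, size=(20, 15))
        values[rng.random(values.shape) < 0.5] = 0.0
        base = filter_genes(_matrix(values), min_frac_cells=0.2)
        perm = rng.permutation(20)
        shuffled = _matrix(values[perm])
        # rename so ids track the original genes
        shuffled.gene_ids = [f"g{i}" for i in perm]
        out = filter_genes(shuffled, min_frac_cells=0.2)
        assert set(out.gene_ids) == set(base.gene_ids)


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        mat = _matrix(rng.exponential(1.0, size=(10, 50)))
        z = zscore_genes(mat)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1), 1.0, atol=1e-12)

    def test_constant_gene_zero_row_flagged(self):
        values = np.ones((2, 5))
        values[1] = np.arange(5)
        z = zscore_genes(_matrix(values))
        np.testing.assert_allclose(z.values[0], 0.0)
        assert z.constant_genes == {"g0"}

    def test_two_cell_closed_form(self):
        # values (a, b) with a < b: population sd = (b-a)/2 -> (-1, +1)
        z = zscore_genes(_matrix([[2.0, 6.0]]), ddof=0)
        np.testing.assert_allclose(z.values, [[-1.0, 1.0]])
        # ddof=1: sd = (b-a)/sqrt(2) -> (-1/sqrt(2), 1/sqrt(2))
        z1 = zscore_genes(_matrix([[2.0, 6.0]]), ddof=1)
        np.testing.assert_allclose(z1.values,
                                   [[-1 / np.sqrt(2), 1 / np.sqrt(2)]])


class TestCelltypeMeans:
    def test_single_stage_means_zero_after_zscore(self):
        rng = np.random.default_rng(5)
        mat = zscore_genes(_matrix(rng.exponential(1.0, size=(5, 30))))
        means = celltype_gene_means(mat)
        np.testing.assert_allclose(means.values, 0.0, atol=1e-12)

    def test_toy_hand_means(self):
        values = [[1.0, 2.0, 3.0, 4.0],
                  [0.0, 0.0, 10.0, 10.0],
                  [5.0, 1.0, 1.0, 5.0]]
        mat = _matrix(values, stages=["A", "A", "B", "B"],
                      stage_order=["A", "B"])
        means = celltype_gene_means(mat)
        np.testing.assert_allclose(means.values,
                                   [[1.5, 3.5], [0.0, 10.0], [3.0, 3.0]])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(4, 10))
        stages = ["A"] * 5 + ["B"] * 5
        mat = _matrix(values, stages=stages, stage_order=["A", "B"])
        perm = rng.permutation(10)
        permuted = SCExpressionMatrix(
            values=values[:, perm],
            gene_ids=mat.gene_ids,
            cell_ids=[mat.cell_ids[j] for j in perm],
            labels=mat.labels,
            stage_order=["A", "B"],
        )
        np.testing.assert_allclose(celltype_gene_means(mat).values,
                                   celltype_gene_means(permuted).values)

    def test_empty_stage_error(self):
        mat = _matrix(np.ones((2, 3)), stages=["A", "A", "A"],
                      stage_order=["A", "B"])
        with pytest.raises(ValueError, match="'B'"):
            celltype_gene_means(mat)

    def test_global_conservation_weighted_stage_means(self):
        rng = np.random.default_rng(7)
        stages = ["A"] * 10 + ["B"] * 30 + ["C"] * 20
        mat = zscore_genes(_matrix(rng.exponential(1.0, size=(8, 60)),
                                   stages=stages, stage_order=["A", "B", "C"]))
        means = celltype_gene_means(mat)
        weighted = means.values @ np.array([10, 30, 20]) / 60
        np.testing.assert_allclose(weighted, 0.0, atol=1e-10)


class TestProgramProfile:
    def test_identical_profiles_zero_sem(self):
        values = np.tile([[1.0, 2.0, 3.0, 4.0]], (5, 1))
        mat = _matrix(values, stages=["A", "A", "B", "B"],
                      stage_order=["A", "B"])
        means = celltype_gene_means(mat)
        profile = program_profile(means, {f"g{i}" for i in range(5)})
        np.testing.assert_allclose(profile.sem, 0.0, atol=1e-12)
        assert profile.n_genes == 5

    def test_too_few_genes_error(self):
        mat = _matrix(np.ones((5, 4)), stages=["A"] * 4)
        means = celltype_gene_means(mat)
        with pytest.raises(ValueError, match=">= 2"):
            program_profile(means, {"g0"})

    def test_full_program_present(self):
        mat = _matrix(np.random.default_rng(0).normal(size=(6, 4)),
                      stages=["A", "A", "B", "B"], stage_order=["A", "B"])
        means = celltype_gene_means(mat)
        profile = program_profile(means, {"g0", "g1", "g2"})
        assert profile.n_genes == 3


class TestStageTests:
    def _means(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 12
        values = rng.normal(size=(n, 40))
        values[:, 20:] += shift
        stages = ["A"] * 20 + ["B"] * 20
        mat = _matrix(values, stages=stages, stage_order=["A", "B"])
        return celltype_gene_means(mat)

    def test_identical_means_p_one(self):
        means = self._means()
        means.values[:, 1] = means.values[:, 0]
        [res] = successive_stage_tests(means, set(means.gene_ids))
        assert res.t == 0.0 and res.p_raw == 1.0

    def test_paired_closed_form(self):
        means = self._means(seed=1, shift=0.5)
        program = set(means.gene_ids)
        [res] = successive_stage_tests(means, program, paired=True, m=1)
        diff = means.values[:, 0] - means.values[:, 1]
        t_oracle = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        p_oracle = 2 * scipy.stats.t.sf(abs(t_oracle), len(diff) - 1)
        assert res.p_raw == pytest.approx(p_oracle, abs=1e-12)

    def test_bonferroni_default_m_pairs(self):
        rng = np.random.default_rng(3)
        stages = sum(([s] * 10 for s in "ABCD"), [])
        mat = _matrix(rng.normal(size=(10, 40)), stages=stages,
                      stage_order=list("ABCD"))
        means = celltype_gene_means(mat)
        results = successive_stage_tests(means, set(means.gene_ids))
        assert len(results) == 3
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_too_few_genes_error(self):
        means = self._means()
        with pytest.raises(ValueError, match=">= 3"):
            successive_stage_tests(means, {"g0", "g1"})


class TestExpressedInCells:
    def _mat(self):
        values = np.zeros((3, 40))
        values[0, :2] = 2.0        # 2/20 = 10% of stage A at TPM >= 1
        values[1, 20] = 0.5        # nonzero but < 1 TPM, one B cell
        stages = ["A"] * 20 + ["B"] * 20
        return _matrix(values, stages=stages, stage_order=["A", "B"])

    def test_stringent_mode(self):
        mat = self._mat()
        out = expressed_in_cells(mat, ["A", "B"], min_frac=0.05, mode="tpm")
        assert out == {"g0"}

    def test_relaxed_mode(self):
        mat = self._mat()
        out = expressed_in_cells(mat, ["A", "B"], mode="nonzero-any")
        assert out == {"g0", "g1"}

    def test_all_zero_excluded_both_modes(self):
        mat = self._mat()
        for mode in ("tpm", "nonzero-any"):
            assert "g2" not in expressed_in_cells(mat, ["A", "B"], mode=mode)

    def test_empty_stage_subset_error(self):
        with pytest.raises(ValueError, match="empty stage"):
            expressed_in_cells(self._mat(), [])

    def test_unknown_stage_error(self):
        with pytest.raises(ValueError, match="unknown stage"):
            expressed_in_cells(self._mat(), ["Z"])
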