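import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcgnet.diffexpr import (
    bh_adjust,
    call_degs,
    de_table,
    deg_genes,
    gene_wise_test,
    log2_fold_change,
    mutual_degs,
)
from dcgnet.errors import DataError, ParameterError
from dcgnet.simulate import ExpressionStudy, SimulationParams, make_two_condition_study

from oracles import bh_stepup, welch_p


def _study(normal_rows, cancer_rows, genes):
    n_n, n_c = len(normal_rows[0]), len(cancer_rows[0])
    samples = [f"n{i}" for i in range(n_n)] + [f"c{i}" for i in range(n_c)]
    values = pd.DataFrame(
        [list(n) + list(c) for n, c in zip(normal_rows, cancer_rows)],
        index=genes, columns=samples,
    )
    condition = pd.Series(["normal"] * n_n + ["cancer"] * n_c, index=samples)
    return ExpressionStudy(values=values, condition=condition)


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        study = _study([[5.0, 5.0, 5.0]], [[5.0, 5.0, 5.0]], ["g1"])
        assert log2_fold_change(study)["g1"] == 0.0

    def test_arithmetic_on_log_scale(self):
        study = _study([[8.0, 8.0, 8.0]], [[10.0, 10.0, 10.0]], ["g1"])
        l2fc = log2_fold_change(study)["g1"]
        assert l2fc == pytest.approx(2.0)
        assert 2**l2fc == pytest.approx(4.0)

    def test_missing_condition_errors(self, tiny_study):
        with pytest.raises(DataError):
            log2_fold_change(tiny_study, cancer="missing")

    def test_planted_shift_estimated(self):
        params = SimulationParams(
            n_genes=20, n_de_genes=20, de_shift=2.0, de_up_fraction=1.0,
            n_normal=200, n_cancer=200, seed=8,
        )
        study, truth = make_two_condition_study(params)
        l2fc = log2_fold_change(study)
        for gene, shift in truth.de_genes.items():
            assert l2fc[gene] == pytest.approx(shift, abs=0.2)


class TestGeneWiseTest:
    def test_identical_groups_p_one(self):
        study = _study([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]], ["g1"])
        assert gene_wise_test(study)["g1"] == pytest.approx(1.0)

    def test_constant_equal_groups_p_one(self):
        study = _study([[4.0, 4.0, 4.0]], [[4.0, 4.0, 4.0]], ["g1"])
        assert gene_wise_test(study)["g1"] == 1.0

    def test_constant_unequal_groups_p_zero(self):
        study = _study([[4.0, 4.0, 4.0]], [[6.0, 6.0, 6.0]], ["g1"])
        assert gene_wise_test(study)["g1"] == 0.0

    def test_matches_welch_oracle(self):
        normal = [0.0, 0.1, -0.1, 0.05]
        cancer = [3.0, 3.1, 2.9, 3.05]
        study = _study([normal], [cancer], ["g1"])
        assert gene_wise_test(study)["g1"] == pytest.approx(
            welch_p(cancer, normal), abs=1e-10
        )

    def test_matches_scipy_on_random_data(self, rng):
        from scipy.stats import ttest_ind

        normal = rng.normal(size=(30, 9))
        cancer = rng.normal(0.3, 1.4, size=(30, 14))
        study = _study(list(normal), list(cancer), [f"g{i}" for i in range(30)])
        ours = gene_wise_test(study).to_numpy()
        ref = ttest_ind(cancer, normal, axis=1, equal_var=False).pvalue
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_needs_two_samples_per_group(self):
        study = _study([[1.0]], [[2.0, 3.0]], ["g1"])
        with pytest.raises(DataError):
            gene_wise_test(study)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ParameterError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_order_preserved(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # step-up monotonicity: q ordering follows p ordering
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestCallDegs:
    def _table(self, fc, padj):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(fc))],
             "fold_change": fc, "p_adj": padj}
        )

    def test_direct_thresholds(self):
        table = call_degs(self._table([4.0, 1.0, 0.25], [0.001] * 3))
        assert list(table["is_deg"]) == [True, False, True]

    def test_fold_change_boundary_strict(self):
        table = call_degs(self._table([2.0], [0.0001]))
        assert not table["is_deg"].iloc[0]

    def test_alpha_boundary_strict(self):
        table = call_degs(self._table([4.0], [0.01]))
        assert not table["is_deg"].iloc[0]

    def test_threshold_domain(self):
        with pytest.raises(ParameterError):
            call_degs(self._table([1.0], [0.5]), fc_hi=0.5, fc_lo=2.0)
        with pytest.raises(ParameterError):
            call_degs(self._table([1.0], [0.5]), alpha=1.5)

    def test_monotonicity_in_thresholds(self, rng):
        fc = np.exp2(rng.normal(0, 2, size=100))
        padj = rng.uniform(size=100)
        base = deg_genes(call_degs(self._table(fc, padj)))
        tighter_alpha = deg_genes(call_degs(self._table(fc, padj), alpha=0.001))
        wider_fc = deg_genes(call_degs(self._table(fc, padj), fc_hi=4.0, fc_lo=0.25))
        assert tighter_alpha <= base
        assert wider_fc <= base


class TestMutualDegs:
    def _table_for(self, genes, degs):
        return pd.DataFrame(
            {"gene": genes, "fold_change": 1.0, "p_adj": 1.0,
             "is_deg": [g in degs for g in genes]}
        )

    def test_intersection(self):
        universe = ["g1", "g2", "g3"]
        tables = [
            self._table_for(universe, {"g1", "g2"}),
            self._table_for(universe, {"g2", "g3"}),
            self._table_for(universe, {"g2"}),
        ]
        result = mutual_degs(tables, ["a", "b", "c"])
        assert result.genes == {"g2"}
        assert result.per_dataset_counts == {"a": 2, "b": 2, "c": 1}

    def test_idempotence(self):
        universe = ["g1", "g2", "g3"]
        table = self._table_for(universe, {"g1", "g3"})
        result = mutual_degs([table] * 4)
        assert result.genes == {"g1", "g3"}

    def test_empty_list_errors(self):
        with pytest.raises(ParameterError):
            mutual_degs([])

    def test_empty_intersection_is_valid(self, caplog):
        universe = ["g1", "g2"]
        tables = [self._table_for(universe, {"g1"}), self._table_for(universe, {"g2"})]
        assert mutual_degs(tables).genes == frozenset()


class TestPermutationSymmetry:
    def test_gene_order_permutation(self, tiny_study):
        table = de_table(tiny_study)
        perm = ["g3", "g1", "g4", "g2"]
        shuffled = ExpressionStudy(
            values=tiny_study.values.loc[perm],
            condition=tiny_study.condition,
            dataset_id="tiny",
        )
        table_perm = de_table(shuffled).set_index("gene")
        original = table.set_index("gene")
        pd.testing.assert_frame_equal(
            original.loc[perm], table_perm.loc[perm], check_exact=False
        )


def test_multi_dataset_intersection_recovers_planted_degs():
    # 4 independent datasets sharing 30 planted DE genes (|shift| = 2.0,
    # 50 samples per condition each): the mutual-DEG intersection should
    # recover nearly all of them.
    from dcgnet.simulate import make_multi_dataset, plan_truth

    params = SimulationParams(
        n_genes=100, n_shared_hubs=2, n_cancer_hubs=1, hub_degree=6,
        background_edges=30, n_de_genes=30, de_shift=2.0, seed=11,
    )
    truth = plan_truth(params)
    studies = make_multi_dataset(truth, params, [(50, 50)] * 4, [1, 2, 3, 4])
    tables = [de_table(s) for s in studies]
    result = mutual_degs(tables, [s.dataset_id for s in studies])
    planted = set(truth.de_genes)
    assert len(result.genes & planted) >= 27
    assert len(result.per_dataset_counts) == 4


def test_end_to_end_deg_on_tiny_study(tiny_study):
    table = de_table(tiny_study)
    assert deg_genes(table) == {"g3"}
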