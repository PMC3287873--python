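"""Burden-score arithmetic, the pi1 mixture estimator, and the annotation weight."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bndissect.errors import DataError, NumericalError, UndefinedWeightError
from bndissect.fixtures import burden_toy
from bndissect.gene_scores import (
    WEIGHT_FUNCTIONS,
    combine_scores,
    estimate_true_positive_proportion,
    estimate_weight,
    informative_genes,
    score_all_genes,
    weighted_sum_score,
)


def _toy(genotype_rows, mafs, annotations=None):
    m = len(mafs)
    annotations = annotations or ["nonsynonymous"] * m
    variants = pd.DataFrame(
        {
            "variant_id": [f"V{j}" for j in range(m)],
            "gene_id": ["G0"] * m,
            "maf": mafs,
            "annotation": annotations,
        }
    )
    genotypes = pd.DataFrame(
        np.asarray(genotype_rows), columns=variants["variant_id"],
        index=[f"I{i}" for i in range(len(genotype_rows))],
    )
    return genotypes, variants


class TestWeightedSumScore:
    def test_hand_evaluated_madsen_browning_weight(self):
        # one carrier of two minor alleles, q = 0.1, n = 100: 2 / sqrt(100 * 0.09)
        variants, genotypes = burden_toy()
        s = weighted_sum_score(genotypes, variants, "G0", maf_source="table")
        assert s.iloc[0] == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert (s.iloc[1:] == 0.0).all()

    def test_all_zero_genotypes_score_zero(self):
        genotypes, variants = _toy([[0, 0], [0, 0]], [0.05, 0.1])
        s = weighted_sum_score(genotypes, variants, "G0", maf_source="table")
        assert (s == 0.0).all()

    def test_equal_maf_weight_depends_only_on_q(self):
        genotypes, variants = _toy([[1, 1], [2, 0]], [0.05, 0.05])
        s = weighted_sum_score(genotypes, variants, "G0", maf_source="table")
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    def test_unknown_gene_raises(self):
        genotypes, variants = _toy([[1]], [0.1])
        with pytest.raises(DataError):
            weighted_sum_score(genotypes, variants, "NOPE")

    def test_no_variants_passing_filter_is_degenerate_zero(self):
        genotypes, variants = _toy([[1]], [0.1], ["nonsynonymous"])
        s = weighted_sum_score(genotypes, variants, "G0", "synonymous")
        assert (s == 0.0).all()
        assert s.attrs["degenerate"]

    def test_linearity_in_genotypes(self):
        genotypes, variants = _toy([[1, 2], [0, 1], [2, 0]], [0.05, 0.2])
        s1 = weighted_sum_score(genotypes, variants, "G0", maf_source="table")
        s2 = weighted_sum_score(2.0 * genotypes, variants, "G0", maf_source="table")
        assert np.allclose(s2.to_numpy(), 2.0 * s1.to_numpy())

    @given(q=st.floats(min_value=1e-4, max_value=0.499))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weight_strictly_decreasing_in_maf(self, q):
        w = WEIGHT_FUNCTIONS["madsen_browning"]
        assert w(np.array([q]), 100)[0] > w(np.array([q + 1e-3]), 100)[0]


class TestScoreAllGenes:
    def test_columns_sorted_and_complete(self, tiny_replicates):
        m = score_all_genes(tiny_replicates.genotypes, tiny_replicates.variants)
        assert m.genes == sorted(m.genes)
        assert len(m.genes) == 12

    def test_annotation_partition_additivity(self, tiny_replicates):
        rs = tiny_replicates
        syn = score_all_genes(rs.genotypes, rs.variants, "synonymous")
        nonsyn = score_all_genes(rs.genotypes, rs.variants, "nonsynonymous")
        both = score_all_genes(rs.genotypes, rs.variants, "all")
        np.testing.assert_allclose(
            both.data.to_numpy(), syn.data.to_numpy() + nonsyn.data.to_numpy(),
            atol=1e-10,
        )

    def test_row_permutation_equivariance(self, tiny_replicates, rng):
        rs = tiny_replicates
        m = score_all_genes(rs.genotypes, rs.variants)
        perm = rng.permutation(rs.genotypes.index.to_numpy())
        m_perm = score_all_genes(rs.genotypes.loc[perm], rs.variants)
        pd.testing.assert_frame_equal(m.data.loc[perm], m_perm.data)

    def test_informative_genes_drop_constant_columns(self):
        genotypes, variants = _toy([[0], [0], [0]], [0.01])
        m = score_all_genes(genotypes, variants)
        assert informative_genes(m) == []


class TestPi1Estimation:
    def test_null_only_simulation_near_zero(self, rng):
        p = stats.norm.sf(rng.standard_normal(2_000))
        assert estimate_true_positive_proportion(p) <= 0.05

    def test_known_mixture_recovered(self):
        rng = np.random.default_rng(42)
        z = np.concatenate([rng.normal(3, 1, 400), rng.normal(0, 1, 1600)])
        pi1 = estimate_true_positive_proportion(stats.norm.sf(z))
        assert 0.12 <= pi1 <= 0.28

    def test_permutation_invariance(self, rng):
        p = stats.norm.sf(rng.normal(0.5, 1, 500))
        a = estimate_true_positive_proportion(p)
        b = estimate_true_positive_proportion(rng.permutation(p))
        assert a == b

    def test_storey_estimator_agrees_roughly(self):
        rng = np.random.default_rng(7)
        z = np.concatenate([rng.normal(3, 1, 400), rng.normal(0, 1, 1600)])
        p = stats.norm.sf(z)
        a = estimate_true_positive_proportion(p, method="central")
        b = estimate_true_positive_proportion(p, method="storey")
        assert abs(a - b) < 0.1

    def test_too_few_pvalues_refused(self):
        with pytest.raises(DataError):
            estimate_true_positive_proportion(np.linspace(0.1, 0.9, 20))

    def test_degenerate_equal_pvalues_refused(self):
        with pytest.raises(NumericalError):
            estimate_true_positive_proportion(np.full(100, 0.5))


class TestEstimateWeight:
    @pytest.mark.parametrize("formula", ["as_printed", "nonsyn_share"])
    def test_symmetry_gives_half(self, formula):
        assert estimate_weight(0.2, 0.2, formula).w == pytest.approx(0.5)

    def test_both_formulas_arithmetic(self):
        assert estimate_weight(0.1, 0.3, "as_printed").w == pytest.approx(0.25)
        assert estimate_weight(0.1, 0.3, "nonsyn_share").w == pytest.approx(0.75)

    def test_boundary_zero_synonymous(self):
        assert estimate_weight(0.0, 0.3, "as_printed").w == 0.0
        assert estimate_weight(0.0, 0.3, "nonsyn_share").w == 1.0

    def test_undefined_weight_raises(self):
        with pytest.raises(UndefinedWeightError):
            estimate_weight(0.0, 0.0)


class TestCombineScores:
    def _pair(self, tiny_replicates):
        rs = tiny_replicates
        syn = score_all_genes(rs.genotypes, rs.variants, "synonymous")
        nonsyn = score_all_genes(rs.genotypes, rs.variants, "nonsynonymous")
        return syn, nonsyn

    def test_boundary_weights(self, tiny_replicates):
        syn, nonsyn = self._pair(tiny_replicates)
        assert combine_scores(syn, nonsyn, 1.0).data.equals(nonsyn.data)
        assert combine_scores(syn, nonsyn, 0.0).data.equals(syn.data)

    def test_midpoint_cell(self, tiny_replicates):
        syn, nonsyn = self._pair(tiny_replicates)
        c = combine_scores(syn, nonsyn, 0.5)
        cell = 0.5 * (syn.data.iloc[0, 0] + nonsyn.data.iloc[0, 0])
        assert c.data.iloc[0, 0] == pytest.approx(cell)

    def test_shape_mismatch_raises(self, tiny_replicates):
        syn, nonsyn = self._pair(tiny_replicates)
        trimmed = nonsyn
        trimmed.data = nonsyn.data.iloc[:, :-1]
        with pytest.raises(DataError):
            combine_scores(syn, trimmed, 0.5)

    @given(w1=st.floats(0, 1), w2=st.floats(0, 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_w_where_nonsyn_exceeds_syn(self, w1, w2):
        syn = pd.DataFrame([[1.0]], columns=["G"])
        nonsyn = pd.DataFrame([[3.0]], columns=["G"])
        from bndissect.gene_scores import GeneScoreMatrix

        mk = lambda d, k: GeneScoreMatrix(d, k, pd.Series({"G": 1}), frozenset())
        lo, hi = sorted([w1, w2])
        a = combine_scores(mk(syn, "synonymous"), mk(nonsyn, "nonsynonymous"), lo)
        b = combine_scores(mk(syn.copy(), "synonymous"), mk(nonsyn.copy(), "nonsynonymous"), hi)
        assert b.data.iloc[0, 0] >= a.data.iloc[0, 0]
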