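import math

import numpy as np
import pytest

import oracles
from tablesig.exact_lrt import (
    NullDistribution,
    build_null_distribution,
    exact_lrt_pvalue,
    log_h_weight,
)
from tablesig.tables import GenotypeCounts, HypothesisSpec, make_table


class TestHWeights:
    def test_homogeneity_micro_values(self, hom22):
        # margins (1,1): h(1,0) = 1/6, h(1,1) = 1/3
        assert math.exp(
            log_h_weight(make_table([[1, 0], [0, 1]]), hom22)
        ) == pytest.approx(1 / 6, rel=1e-12)
        assert math.exp(
            log_h_weight(make_table([[1, 0], [1, 0]]), hom22)
        ) == pytest.approx(1 / 3, rel=1e-12)

    def test_hwe_micro_value(self, hwe):
        assert math.exp(log_h_weight(GenotypeCounts(1, 0, 0), hwe)) == pytest.approx(
            1 / 3, rel=1e-12
        )

    def test_mismatched_shape_raises(self, hom22):
        with pytest.raises(ValueError):
            log_h_weight(make_table([[1, 0, 0], [0, 1, 0]]), hom22)

    @pytest.mark.parametrize("margins", [(1, 1), (5, 5), (10, 10), (30, 30), (100, 100)])
    def test_homogeneity_weights_sum_to_one(self, hom22, margins):
        # the 2x2 fixed-margin integrated likelihoods are already normalized
        null = build_null_distribution(hom22, margins=margins)
        assert null.h_total() == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_rational_oracle(self, hom22, ind22, hwe):
        for tab in oracles.tables_fixed_margins((3, 4), 2):
            assert math.exp(
                log_h_weight(make_table(tab), hom22)
            ) == pytest.approx(float(oracles.h_homogeneity(tab)), rel=1e-11)
        for tab in oracles.tables_fixed_total(4, 2, 2):
            assert math.exp(
                log_h_weight(make_table(tab), ind22)
            ) == pytest.approx(float(oracles.h_independence(tab)), rel=1e-11)
        for g in oracles.genotypes(6):
            assert math.exp(
                log_h_weight(GenotypeCounts(*g), hwe)
            ) == pytest.approx(float(oracles.h_hwe(g)), rel=1e-11)


class TestNullDistribution:
    def test_micro_probabilities(self, hom22):
        null = build_null_distribution(hom22, margins=(1, 1))
        # enumeration order by (x11, x21): (0,0), (0,1), (1,0), (1,1)
        assert null.probabilities == pytest.approx(
            [1 / 3, 1 / 6, 1 / 6, 1 / 3], rel=1e-12
        )

    def test_probabilities_normalized(self, ind22, hwe):
        for null in (
            build_null_distribution(ind22, n=5),
            build_null_distribution(hwe, n=7),
            build_null_distribution(
                HypothesisSpec.homogeneity(3, 3), margins=(2, 3, 2)
            ),
        ):
            assert null.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
            np.testing.assert_allclose(
                null.log_prob, null.log_h - null.log_h_total, atol=1e-15
            )

    def test_hwe_micro_probabilities(self, hwe):
        null = build_null_distribution(hwe, n=1)
        assert null.probabilities == pytest.approx([1 / 3, 1 / 3, 1 / 3], rel=1e-12)

    def test_scaling_h_leaves_pvalues_unchanged(self, hom22):
        null = build_null_distribution(hom22, margins=(4, 3))
        scaled = NullDistribution(
            hypothesis=null.hypothesis,
            counts=null.counts,
            log_h=null.log_h + math.log(7.3),
            log_h_total=null.log_h_total + math.log(7.3),
            log_lambda=null.log_lambda,
        )
        np.testing.assert_allclose(
            null.pvalues_all(), scaled.pvalues_all(), rtol=0, atol=1e-14
        )


class TestExactPvalue:
    def test_micro_worked_example(self, hom22):
        res = exact_lrt_pvalue(make_table([[1, 0], [0, 1]]), hom22)
        assert res.p == pytest.approx(1 / 3, rel=1e-12)
        assert res.n_tables_in_region == 2
        res = exact_lrt_pvalue(make_table([[1, 0], [1, 0]]), hom22)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_hwe_region_is_tied_pair(self, hwe):
        res = exact_lrt_pvalue(GenotypeCounts(0, 2, 0), hwe)
        # region {(0,2,0), (1,0,1)}: both have lambda = 1/4
        assert res.n_tables_in_region == 2
        assert res.p == pytest.approx(
            float(oracles.h_hwe((0, 2, 0)) + oracles.h_hwe((1, 0, 1))), rel=1e-10
        )

    def test_wrong_hypothesis_type_raises(self, hom22, hwe):
        with pytest.raises(ValueError):
            exact_lrt_pvalue(GenotypeCounts(1, 1, 1), hom22)
        with pytest.raises(ValueError):
            exact_lrt_pvalue(make_table([[1, 0], [0, 1]]), hwe)

    def test_streaming_matches_materialized(self, ind22):
        null = build_null_distribution(ind22, n=6)
        pv = null.pvalues_all()
        for idx in [0, 7, 20, null.n_tables - 1]:
            obs = make_table(null.counts[idx])
            assert exact_lrt_pvalue(obs, ind22).p == pytest.approx(
                pv[idx], rel=1e-12
            )


class TestOracleEquivalence:
    """Streaming implementation vs exact-rational brute force."""

    @pytest.mark.parametrize("m1", range(1, 7))
    @pytest.mark.parametrize("m2", range(1, 7))
    def test_homogeneity_all_margins_up_to_6(self, hom22, m1, m2):
        space = list(oracles.tables_fixed_margins((m1, m2), 2))
        expected = oracles.exact_pvalues(
            space, oracles.lam_homogeneity, oracles.h_homogeneity
        )
        null = build_null_distribution(hom22, margins=(m1, m2))
        got = null.pvalues_all()
        for tab, e, g in zip(space, expected, got):
            assert abs(g - float(e)) < 1e-10, (m1, m2, tab)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_independence_totals_up_to_6(self, ind22, n):
        space = list(oracles.tables_fixed_total(n, 2, 2))
        expected = oracles.exact_pvalues(
            space, oracles.lam_independence, oracles.h_independence
        )
        got = build_null_distribution(ind22, n=n).pvalues_all()
        assert np.max(np.abs(got - np.array([float(e) for e in expected]))) < 1e-10

    @pytest.mark.parametrize("n", range(1, 13))
    def test_hwe_totals_up_to_12(self, hwe, n):
        space = list(oracles.genotypes(n))
        expected = oracles.exact_pvalues(space, oracles.lam_hwe, oracles.h_hwe)
        got = build_null_distribution(hwe, n=n).pvalues_all()
        assert np.max(np.abs(got - np.array([float(e) for e in expected]))) < 1e-10


class TestDiscretePvalueProperties:
    @pytest.mark.parametrize(
        "builder",
        [
            lambda: build_null_distribution(
                HypothesisSpec.homogeneity(2, 2), margins=(5, 5)
            ),
            lambda: build_null_distribution(
                HypothesisSpec.homogeneity(2, 2), margins=(10, 10)
            ),
            lambda: build_null_distribution(HypothesisSpec.hwe(), n=10),
        ],
    )
    def test_validity_under_the_null(self, builder):
        # Pr(p <= alpha | H) <= alpha for a valid discrete p-value
        null = builder()
        p = null.pvalues_all()
        probs = null.probabilities
        for alpha in (0.01, 0.05, 0.1):
            assert probs[p <= alpha].sum() <= alpha + 1e-12

    def test_monotone_in_lambda(self, hwe):
        null = build_null_distribution(hwe, n=9)
        p = null.pvalues_all()
        order = np.argsort(null.log_lambda)
        assert np.all(np.diff(p[order]) >= -1e-12)
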