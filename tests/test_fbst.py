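import math

import numpy as np
import pytest
from scipy.stats import dirichlet

from tablesig.classical import asymptotic_lrt_pvalue
from tablesig.exact_lrt import build_null_distribution
from tablesig.fbst import (
    asymptotic_evalue,
    evalue_mc,
    log_posterior_density,
    sup_log_posterior_under_H,
)
from tablesig.lrt_stat import LambdaValue, lambda_homogeneity
from tablesig.tables import GenotypeCounts, HypothesisSpec, make_table

# e-value of the (1,0) table at margins (1,1): the tangent set
# {4 u (1-v) >= 1} of the Beta(2,1) x Beta(1,2) posterior has mass
# 15/16 - ln(4)/8, so Ev = 1/16 + ln(4)/8.
MICRO_EVALUE = 1 / 16 + math.log(4) / 8


class TestPosteriorDensity:
    def test_micro_2x2(self, hom22):
        t = make_table([[1, 0], [0, 1]])
        # Beta(2,1) x Beta(1,2) densities: 2u * 2(1-v) = 1 at (1/2, 1/2)
        lp = log_posterior_density([[0.5, 0.5], [0.5, 0.5]], t, hom22)
        assert lp == pytest.approx(0.0, abs=1e-12)

    def test_no_data_posterior_is_uniform(self, hwe):
        g = GenotypeCounts(0, 0, 0)
        for theta in ([0.2, 0.3, 0.5], [0.9, 0.05, 0.05]):
            # Dirichlet(1,1,1) density is constant 2 on the simplex
            assert log_posterior_density(theta, g, hwe) == pytest.approx(
                math.log(2.0), abs=1e-12
            )

    def test_matches_scipy_dirichlet_hwe(self, hwe):
        g = GenotypeCounts(1, 2, 1)
        theta = [0.25, 0.5, 0.25]
        ref = dirichlet.logpdf(theta, [2, 3, 2])
        assert log_posterior_density(theta, g, hwe) == pytest.approx(ref, rel=1e-12)

    def test_outside_simplex_rejected(self, hwe):
        with pytest.raises(ValueError):
            log_posterior_density([0.5, 0.6, -0.1], GenotypeCounts(1, 1, 1), hwe)


class TestSupUnderH:
    def test_micro_2x2(self, hom22):
        t = make_table([[1, 0], [0, 1]])
        assert sup_log_posterior_under_H(t, hom22) == pytest.approx(0.0, abs=1e-12)

    def test_hwe_closed_form(self, hwe):
        got = sup_log_posterior_under_H(GenotypeCounts(1, 2, 1), hwe)
        assert math.exp(got) == pytest.approx(5.625, rel=1e-12)

    def test_equals_dense_parametrization_of_null(self, hom22, hwe):
        # brute-force the one-dimensional null manifolds
        t = make_table([[3, 2], [1, 4]])
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        dens = [
            log_posterior_density([[u, 1 - u], [u, 1 - u]], t, hom22) for u in grid
        ]
        assert sup_log_posterior_under_H(t, hom22) == pytest.approx(
            max(dens), abs=1e-6
        )
        g = GenotypeCounts(3, 4, 3)
        dens = [
            log_posterior_density(
                [u**2, 2 * u * (1 - u), (1 - u) ** 2], g, hwe
            )
            for u in grid
        ]
        assert sup_log_posterior_under_H(g, hwe) == pytest.approx(max(dens), abs=1e-6)

    def test_never_exceeds_global_posterior_maximum(self, hom22):
        # the unrestricted posterior mode is the product of Beta modes
        from scipy.special import xlogy

        null = build_null_distribution(hom22, margins=(6, 6))
        for counts in null.counts:
            t = make_table(counts)
            x = t.counts.astype(float)
            rm = x.sum(axis=1, keepdims=True)
            const = sum(
                math.lgamma(int(r) + 2) - sum(math.lgamma(v + 1) for v in row)
                for r, row in zip(rm[:, 0], x)
            )
            global_max = const + float(xlogy(x, x / rm).sum())
            assert sup_log_posterior_under_H(t, hom22) <= global_max + 1e-10

    def test_sup_equals_global_max_when_mode_in_null(self, hom22):
        # balanced rows put the posterior mode on the diagonal
        t = make_table([[3, 3], [3, 3]])
        got = sup_log_posterior_under_H(t, hom22)
        mode = log_posterior_density([[0.5, 0.5], [0.5, 0.5]], t, hom22)
        assert got == pytest.approx(mode, abs=1e-12)


class TestEvalueMc:
    def test_reproducible_with_seed(self, hom22):
        t = make_table([[4, 2], [1, 5]])
        a = evalue_mc(t, hom22, k=20_000, seed=7)
        b = evalue_mc(t, hom22, k=20_000, seed=7)
        assert a.evalue == b.evalue
        assert a.mc_standard_error <= 0.5 / math.sqrt(20_000)

    def test_micro_example_analytic_value(self, hom22):
        t = make_table([[1, 0], [0, 1]])
        res = evalue_mc(t, hom22, k=400_000, seed=11)
        assert abs(res.evalue - MICRO_EVALUE) <= 3 * res.mc_standard_error

    def test_concentrates_across_seeds(self, hom22):
        t = make_table([[1, 0], [0, 1]])
        vals = [evalue_mc(t, hom22, k=100_000, seed=s).evalue for s in range(5)]
        se = math.sqrt(MICRO_EVALUE * (1 - MICRO_EVALUE) / 100_000)
        assert all(abs(v - MICRO_EVALUE) <= 4 * se for v in vals)

    def test_balanced_table_evalue_near_one(self, hom22):
        res = evalue_mc(make_table([[5, 5], [5, 5]]), hom22, k=50_000, seed=3)
        assert res.evalue > 0.999

    def test_k_one_is_indicator(self, hwe):
        res = evalue_mc(GenotypeCounts(2, 5, 3), HypothesisSpec.hwe(), k=1, seed=0)
        assert res.evalue in (0.0, 1.0)

    def test_invalid_k(self, hwe):
        with pytest.raises(ValueError):
            evalue_mc(GenotypeCounts(1, 1, 1), hwe, k=0, seed=0)


class TestAsymptoticEvalue:
    def test_lambda_one(self, hom22):
        assert asymptotic_evalue(LambdaValue(0.0), hom22) == 1.0

    def test_chi2_2_tail_closed_form(self, hom22):
        # chi-square_2 survival at -2 ln(1/4) is exactly 1/4
        got = asymptotic_evalue(LambdaValue(math.log(0.25)), hom22)
        assert got == pytest.approx(0.25, rel=1e-12)

    def test_dominates_asymptotic_pvalue(self, hom22):
        # dim Theta > dim Theta - dim Theta_H: heavier reference tail
        null = build_null_distribution(hom22, margins=(10, 10))
        for ll in null.log_lambda:
            lam = LambdaValue(min(ll, 0.0))
            assert asymptotic_evalue(lam, hom22) >= asymptotic_lrt_pvalue(
                lam, hom22
            ) - 1e-14
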