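"""Asymptotic LRT, Pearson chi-square, and Fisher's exact test.

The asymptotic LRT p-value refers −2 ln λ to a chi-square distribution
with dim Θ − dim Θ_H degrees of freedom.  The Pearson statistic uses
plug-in expected counts (product of margins over the total for the
table hypotheses; Hardy-Weinberg proportions at the allele-frequency
MLE for genotype data) with the same degrees of freedom and no
continuity correction.  Fisher's test conditions a 2×2 table on both
margins and sums hypergeometric point probabilities no larger than the
observed one (the two-sided minimum-likelihood rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .lrt_stat import LambdaValue
from .tables import ContingencyTable, GenotypeCounts, HypothesisSpec

__all__ = [
    "ClassicalPvalues",
    "asymptotic_lrt_pvalue",
    "pearson_chisq_pvalue",
    "fisher_exact_2x2",
    "chisq_stat_many",
    "fisher_pvalues_2x2_many",
]

#: Relative slack for the "probability no larger than observed" comparison
#: in Fisher's rule; point probabilities tied by symmetry must count as ties.
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class ClassicalPvalues:
    p_lrt_asymptotic: float
    p_chisq: float
    chisq_stat: float
    p_fisher: float | None = None


def asymptotic_lrt_pvalue(lam: LambdaValue, hypothesis: HypothesisSpec) -> float:
    """Upper chi-square tail of −2 ln λ at df = dim Θ − dim Θ_H."""
    return float(chi2.sf(lam.neg2_log_lambda, hypothesis.df_freq))


def chisq_stat_many(
    counts: np.ndarray, hypothesis: HypothesisSpec
) -> np.ndarray:
    """Pearson X² for a stack of tables ``(N, ℓ, c)`` or genotypes ``(N, 3)``.

    Cells with zero expected count have zero observed count in these
    designs and contribute nothing.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if hypothesis.kind == "hwe":
        n = counts.sum(axis=1)
        theta = (2.0 * counts[:, 0] + counts[:, 1]) / (2.0 * n)
        expected = n[:, None] * np.stack(
            [theta**2, 2.0 * theta * (1.0 - theta), (1.0 - theta) ** 2], axis=1
        )
    else:
        n = counts.sum(axis=(1, 2))
        rm = counts.sum(axis=2)
        cm = counts.sum(axis=1)
        expected = rm[:, :, None] * cm[:, None, :] / n[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    if np.any((expected == 0) & (counts > 0)):
        raise ValueError("observed count in a cell with zero expected count")
    axes = tuple(range(1, counts.ndim))
    return terms.sum(axis=axes)


def pearson_chisq_pvalue(
    observed: ContingencyTable | GenotypeCounts, hypothesis: HypothesisSpec
) -> tuple[float, float]:
    """Pearson X² statistic and its asymptotic p-value.

    Returns ``(statistic, p)`` with p the chi-square upper tail at
    df = dim Θ − dim Θ_H.
    """
    if hypothesis.kind == "hwe":
        if not isinstance(observed, GenotypeCounts):
            raise ValueError("hwe requires GenotypeCounts")
        if observed.n == 0:
            raise ValueError("chi-square undefined for n = 0")
        stack = np.asarray([observed.as_tuple()])
    else:
        if not isinstance(observed, ContingencyTable):
            raise ValueError(f"{hypothesis.kind} requires a ContingencyTable")
        if observed.total == 0:
            raise ValueError("chi-square undefined for an empty table")
        stack = observed.counts[None]
    stat = float(chisq_stat_many(stack, hypothesis)[0])
    return stat, float(chi2.sf(stat, hypothesis.df_freq))


def _hypergeom_logpmf_slice(n1: int, n2: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Log point probabilities of x11 over its admissible range, conditioning
    a 2×2 table on row margins (n1, n2) and first-column total k."""
    lo = max(0, k - n2)
    hi = min(n1, k)
    x = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(n1 + 1)
        - gammaln(x + 1)
        - gammaln(n1 - x + 1)
        + gammaln(n2 + 1)
        - gammaln(k - x + 1)
        - gammaln(n2 - k + x + 1)
        - (gammaln(n1 + n2 + 1) - gammaln(k + 1) - gammaln(n1 + n2 - k + 1))
    )
    return x, logpmf


def fisher_exact_2x2(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2×2 table.

    Conditional on both margins, sums the probabilities of every table
    whose hypergeometric point probability is at most the observed one
    (up to a relative tolerance for symmetric ties).
    """
    if table.shape != (2, 2):
        raise ValueError("Fisher's exact test is implemented for 2x2 tables only")
    if table.total == 0:
        raise ValueError("Fisher's exact test undefined for an empty table")
    n1, n2 = (int(v) for v in table.row_margins)
    k = int(table.col_margins[0])
    x, logpmf = _hypergeom_logpmf_slice(n1, n2, k)
    pmf = np.exp(logpmf)
    obs = pmf[x == int(table.counts[0, 0])][0]
    p = float(pmf[pmf <= obs * (1.0 + FISHER_REL_TOL)].sum())
    return min(p, 1.0)


def fisher_pvalues_2x2_many(counts: np.ndarray) -> np.ndarray:
    """Fisher two-sided p-values for a ``(N, 2, 2)`` stack of tables."""
    counts = np.asarray(counts, dtype=np.int64)
    out = np.empty(counts.shape[0])
    for i, c in enumerate(counts):
        out[i] = fisher_exact_2x2(ContingencyTable(c))
    return out
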