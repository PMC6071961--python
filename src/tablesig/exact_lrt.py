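"""Exact LRT p-values from an integrated-likelihood null distribution.

The nuisance parameter of each null (the shared column-probability
vector under homogeneity, the margin probabilities under independence,
the allele frequency under Hardy-Weinberg) is eliminated by integrating
the null likelihood against the uniform measure on its simplex.  The
resulting weight h(x) is a genuine probability for the observed table
once normalized over the full enumerated sample space, and the exact
p-value is the h-probability of the region R = {λ ≤ λ_obs}.

Closed forms of h (all evaluated through log-gamma, since the factorial
ratios overflow doubles long before the enumerations become infeasible):

homogeneity   h = ∏_i n_i·! ∏_j n_·j! / [∏_ij x_ij! (n_·· + c − 1)!]
independence  h = n_··! ∏_i n_i·! ∏_j n_·j! /
                  [∏_ij x_ij! (n_·· + ℓ − 1)! (n_·· + c − 1)!]
HWE           h = n! 2^{x2} (2x1+x2)! (2x3+x2)! / [x1! x2! x3! (2n+1)!]

Because only the normalized probabilities enter the p-value, rescaling
h by any positive constant changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .lrt_stat import (
    LambdaValue,
    lambda_hwe,
    lambda_homogeneity,
    lambda_independence,
    log_lambda_homogeneity_many,
    log_lambda_hwe_many,
    log_lambda_independence_many,
)
from .tables import ContingencyTable, GenotypeCounts, HypothesisSpec

__all__ = [
    "LOG_TIE_TOL",
    "NullDistribution",
    "ExactPvalue",
    "log_h_weight",
    "log_h_homogeneity_many",
    "log_h_independence_many",
    "log_h_hwe_many",
    "log_h_independence_published_total",
    "build_null_distribution",
    "exact_lrt_pvalue",
    "iter_space_chunks",
]

#: Absolute tolerance on the log-λ scale for the weak inequality defining
#: the rejection region.  Symmetric tables produce exactly tied λ whose
#: floating-point images can differ in the last few ulps; 1e-9 is far above
#: that rounding and far below any genuine λ gap at enumerable sizes.
LOG_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# h-weights


def log_h_homogeneity_many(counts: np.ndarray) -> np.ndarray:
    """log h for a ``(N, ℓ, c)`` stack under homogeneity (fixed row margins)."""
    counts = np.asarray(counts, dtype=np.float64)
    rm = counts.sum(axis=2)
    cm = counts.sum(axis=1)
    n = counts.sum(axis=(1, 2))
    c = counts.shape[2]
    return (
        gammaln(rm + 1).sum(axis=1)
        + gammaln(cm + 1).sum(axis=1)
        - gammaln(counts + 1).sum(axis=(1, 2))
        - gammaln(n + c)
    )


def log_h_independence_many(counts: np.ndarray) -> np.ndarray:
    """log h for a ``(N, ℓ, c)`` stack under independence (fixed total)."""
    counts = np.asarray(counts, dtype=np.float64)
    rm = counts.sum(axis=2)
    cm = counts.sum(axis=1)
    n = counts.sum(axis=(1, 2))
    l, c = counts.shape[1], counts.shape[2]
    return (
        gammaln(n + 1)
        + gammaln(rm + 1).sum(axis=1)
        + gammaln(cm + 1).sum(axis=1)
        - gammaln(counts + 1).sum(axis=(1, 2))
        - gammaln(n + l)
        - gammaln(n + c)
    )


def log_h_hwe_many(x: np.ndarray) -> np.ndarray:
    """log h for a ``(N, 3)`` stack of genotype triples."""
    x = np.asarray(x, dtype=np.float64)
    n = x.sum(axis=1)
    a = 2.0 * x[:, 0] + x[:, 1]
    b = 2.0 * x[:, 2] + x[:, 1]
    return (
        gammaln(n + 1)
        + x[:, 1] * np.log(2.0)
        + gammaln(a + 1)
        + gammaln(b + 1)
        - gammaln(x + 1).sum(axis=1)
        - gammaln(2.0 * n + 2)
    )


def log_h_independence_published_total(counts: np.ndarray) -> np.ndarray:
    """log of (n+ℓ)!(n+c)! / (n! ∏ x_ij!) for a ``(N, ℓ, c)`` stack.

    An alternative closed-form independence weight whose total over the
    ten 2×2 tables with n = 2 is 2304; it is the form behind that widely
    quoted normalization total.  It differs from the integrated
    likelihood by the per-table margin factorials, so it does not define
    the same null distribution; this package's p-values always use the
    integral (:func:`log_h_independence_many`).  Kept for cross-checking
    normalization totals only.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=(1, 2))
    l, c = counts.shape[1], counts.shape[2]
    return (
        gammaln(n + l + 1)
        + gammaln(n + c + 1)
        - gammaln(n + 1)
        - gammaln(counts + 1).sum(axis=(1, 2))
    )


def log_h_weight(
    observed: ContingencyTable | GenotypeCounts, hypothesis: HypothesisSpec
) -> float:
    """log of the integrated-likelihood weight h(observed) under ``hypothesis``."""
    if hypothesis.kind == "hwe":
        if not isinstance(observed, GenotypeCounts):
            raise ValueError("hwe hypothesis requires GenotypeCounts")
        return float(log_h_hwe_many(np.asarray([observed.as_tuple()]))[0])
    if not isinstance(observed, ContingencyTable):
        raise ValueError(f"{hypothesis.kind} hypothesis requires a ContingencyTable")
    if hypothesis.shape != observed.shape:
        raise ValueError(
            f"table shape {observed.shape} does not match hypothesis {hypothesis.shape}"
        )
    if hypothesis.kind == "homogeneity":
        return float(log_h_homogeneity_many(observed.counts[None])[0])
    return float(log_h_independence_many(observed.counts[None])[0])


# ---------------------------------------------------------------------------
# sample-space iteration in vectorized chunks


def _comp_array(total: int, parts: int) -> np.ndarray:
    """All weak compositions of ``total`` into ``parts``, lex order, as rows."""
    if parts == 1:
        return np.array([[total]], dtype=np.int64)
    blocks = []
    for first in range(total + 1):
        rest = _comp_array(total - first, parts - 1)
        head = np.full((rest.shape[0], 1), first, dtype=np.int64)
        blocks.append(np.hstack([head, rest]))
    return np.vstack(blocks)


def _iter_comp_chunks(total: int, parts: int) -> Iterator[np.ndarray]:
    """Weak compositions of ``total`` into ``parts`` in lex order, yielded as
    arrays; the last two coordinates of each prefix are expanded vectorized."""
    if parts <= 2:
        yield _comp_array(total, parts)
        return
    from .tables import _compositions

    for comp in _compositions(total, parts - 1):
        prefix, r = comp[:-1], comp[-1]
        t = np.arange(r + 1, dtype=np.int64)
        block = np.empty((r + 1, parts), dtype=np.int64)
        block[:, : parts - 2] = prefix
        block[:, parts - 2] = t
        block[:, parts - 1] = r - t
        yield block


def iter_space_chunks(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
) -> Iterator[np.ndarray]:
    """Yield the sample space of ``hypothesis`` as stacked count arrays.

    Chunks of shape ``(M, ℓ, c)`` (tables) or ``(M, 3)`` (genotypes), in
    global lexicographic order of the flattened count vector, without
    ever materializing the whole space.
    """
    if hypothesis.kind == "homogeneity":
        if margins is None:
            raise ValueError("homogeneity space requires row margins")
        l, c = hypothesis.shape  # type: ignore[misc]
        if len(margins) != l:
            raise ValueError("number of margins must match the hypothesis shape")
        row_comps = [_comp_array(int(m), c) for m in margins]
        last = row_comps[-1]  # (K, c) vectorized innermost block
        if l == 2:
            for row0 in row_comps[0]:
                chunk = np.empty((last.shape[0], 2, c), dtype=np.int64)
                chunk[:, 0, :] = row0
                chunk[:, 1, :] = last
                yield chunk
            return

        def rec(i: int, rows: list[np.ndarray]) -> Iterator[np.ndarray]:
            if i == l - 1:
                chunk = np.empty((last.shape[0], l, c), dtype=np.int64)
                for k, r in enumerate(rows):
                    chunk[:, k, :] = r
                chunk[:, l - 1, :] = last
                yield chunk
                return
            for r in row_comps[i]:
                rows.append(r)
                yield from rec(i + 1, rows)
                rows.pop()

        yield from rec(0, [])
    elif hypothesis.kind == "independence":
        if n is None:
            raise ValueError("independence space requires a grand total")
        l, c = hypothesis.shape  # type: ignore[misc]
        for block in _iter_comp_chunks(int(n), l * c):
            yield block.reshape(-1, l, c)
    else:
        if n is None:
            raise ValueError("hwe space requires a sample size")
        yield _comp_array(int(n), 3)


def _log_lambda_many(hypothesis: HypothesisSpec, stack: np.ndarray) -> np.ndarray:
    if hypothesis.kind == "homogeneity":
        return log_lambda_homogeneity_many(stack)
    if hypothesis.kind == "independence":
        return log_lambda_independence_many(stack)
    return log_lambda_hwe_many(stack)[0]


def _log_h_many(hypothesis: HypothesisSpec, stack: np.ndarray) -> np.ndarray:
    if hypothesis.kind == "homogeneity":
        return log_h_homogeneity_many(stack)
    if hypothesis.kind == "independence":
        return log_h_independence_many(stack)
    return log_h_hwe_many(stack)


# ---------------------------------------------------------------------------
# null distribution and p-value


@dataclass(frozen=True)
class NullDistribution:
    """The enumerated sample space with normalized h-probabilities.

    ``counts`` stacks the space in enumeration order: ``(N, ℓ, c)`` for
    table hypotheses, ``(N, 3)`` for Hardy-Weinberg.  ``log_prob`` is
    ``log_h − log_h_total`` elementwise and exponentiates to a proper
    probability vector.
    """

    hypothesis: HypothesisSpec
    counts: np.ndarray
    log_h: np.ndarray
    log_h_total: float
    log_lambda: np.ndarray

    @property
    def log_prob(self) -> np.ndarray:
        return self.log_h - self.log_h_total

    @property
    def probabilities(self) -> np.ndarray:
        return np.exp(self.log_prob)

    @property
    def n_tables(self) -> int:
        return self.counts.shape[0]

    def h_total(self) -> float:
        """Σ h over the space (the normalization constant, linear scale)."""
        return float(np.exp(self.log_h_total))

    def pvalues_all(self) -> np.ndarray:
        """Exact p-value of every table in the space, in enumeration order.

        Sort once, then for each table sum the probability of all tables
        with log λ ≤ its own + the tie tolerance.
        """
        order = np.argsort(self.log_lambda, kind="stable")
        ll_sorted = self.log_lambda[order]
        csum = np.cumsum(np.exp(self.log_prob[order]))
        hi = np.searchsorted(ll_sorted, self.log_lambda + LOG_TIE_TOL, side="right")
        p = csum[hi - 1]  # hi >= 1 always: each table is in its own region
        return np.minimum(p, 1.0)

    def index_of(self, observed: ContingencyTable | GenotypeCounts) -> int:
        if isinstance(observed, GenotypeCounts):
            key = np.asarray(observed.as_tuple(), dtype=np.int64)
            flat = self.counts
        else:
            key = observed.counts.ravel()
            flat = self.counts.reshape(self.counts.shape[0], -1)
        hit = np.nonzero((flat == key).all(axis=1))[0]
        if hit.size == 0:
            raise ValueError("observed table is not in this sample space")
        return int(hit[0])


@dataclass(frozen=True)
class ExactPvalue:
    """Exact LRT p-value: h-probability of {λ ≤ λ_obs}."""

    p: float
    lambda_obs: LambdaValue
    n_tables_in_region: int
    n_tables: int


def build_null_distribution(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
    max_tables: int = 20_000_000,
) -> NullDistribution:
    """Materialize the null distribution over the full sample space."""
    from .tables import count_sample_space

    n_space = count_sample_space(hypothesis, margins=margins, n=n)
    if n_space > max_tables:
        raise ValueError(
            f"sample space holds {n_space} tables, above max_tables={max_tables}"
        )
    chunks = list(iter_space_chunks(hypothesis, margins=margins, n=n))
    counts = np.concatenate(chunks, axis=0)
    log_h = _log_h_many(hypothesis, counts)
    log_lambda = _log_lambda_many(hypothesis, counts)
    return NullDistribution(
        hypothesis=hypothesis,
        counts=counts,
        log_h=log_h,
        log_h_total=float(logsumexp(log_h)),
        log_lambda=log_lambda,
    )


class _StreamingLSE:
    """Online log-sum-exp accumulator."""

    def __init__(self) -> None:
        self._max = -np.inf
        self._sum = 0.0

    def add(self, values: np.ndarray) -> None:
        if values.size == 0:
            return
        m = float(values.max())
        if m > self._max:
            if np.isfinite(self._max):
                self._sum *= np.exp(self._max - m)
            self._max = m
        self._sum += float(np.exp(values - self._max).sum())

    @property
    def value(self) -> float:
        if not np.isfinite(self._max):
            return -np.inf
        return self._max + np.log(self._sum)


def exact_lrt_pvalue(
    observed: ContingencyTable | GenotypeCounts,
    hypothesis: HypothesisSpec,
) -> ExactPvalue:
    """Exact LRT p-value of ``observed`` under ``hypothesis``.

    The sample space is inferred from the observed data itself (its row
    margins, grand total, or genotype total) and is streamed in constant
    memory, so the p-value of a single table is available even for
    spaces in the tens of millions.
    """
    if hypothesis.kind == "homogeneity":
        if not isinstance(observed, ContingencyTable):
            raise ValueError("homogeneity requires a ContingencyTable")
        lam = lambda_homogeneity(observed)
        space = dict(margins=observed.row_margins.tolist())
    elif hypothesis.kind == "independence":
        if not isinstance(observed, ContingencyTable):
            raise ValueError("independence requires a ContingencyTable")
        lam = lambda_independence(observed)
        space = dict(n=observed.total)
    else:
        if not isinstance(observed, GenotypeCounts):
            raise ValueError("hwe requires GenotypeCounts")
        lam, _ = lambda_hwe(observed)
        space = dict(n=observed.n)
    if isinstance(observed, ContingencyTable) and hypothesis.shape != observed.shape:
        raise ValueError(
            f"table shape {observed.shape} does not match hypothesis {hypothesis.shape}"
        )

    cutoff = lam.log_lambda + LOG_TIE_TOL
    total = _StreamingLSE()
    region = _StreamingLSE()
    n_region = 0
    n_total = 0
    for stack in iter_space_chunks(hypothesis, **space):
        lh = _log_h_many(hypothesis, stack)
        ll = _log_lambda_many(hypothesis, stack)
        total.add(lh)
        mask = ll <= cutoff
        region.add(lh[mask])
        n_region += int(mask.sum())
        n_total += stack.shape[0]
    p = float(np.exp(region.value - total.value))
    return ExactPvalue(
        p=min(p, 1.0),
        lambda_obs=lam,
        n_tables_in_region=n_region,
        n_tables=n_total,
    )
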