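"""Barnard's unconditional exact test.

The nuisance parameter is eliminated by maximization: with the critical
region R = {λ ≤ λ_obs} fixed, the p-value is the supremum over θ of the
null probability of R.  Supported designs are the 2×2 homogeneity test
(two independent binomials sharing θ under the null) and Hardy-Weinberg
equilibrium (trinomial with cell probabilities (θ², 2θ(1−θ), (1−θ)²)).

Pr(R | θ) is a polynomial in θ.  It is evaluated on a uniform 1001-point
grid of [0, 1] (endpoints by the 0⁰ = 1 limit) and the maximum refined
by golden-section search in the bracketing interval, which is exact
enough for a smooth low-degree polynomial and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp, xlogy

from .exact_lrt import LOG_TIE_TOL, iter_space_chunks, _log_lambda_many
from .lrt_stat import lambda_homogeneity, lambda_hwe
from .tables import ContingencyTable, GenotypeCounts, HypothesisSpec

__all__ = [
    "BarnardResult",
    "barnard_pvalue",
    "region_log_poly",
    "maximize_region_poly",
]

_GRID_POINTS = 1001
_REFINE_TOL = 1e-10


@dataclass(frozen=True)
class BarnardResult:
    """sup_θ Pr(R | θ), the maximizing θ, and the size of R."""

    p: float
    theta_at_max: float
    region_size: int


def region_log_poly(
    observed: ContingencyTable | GenotypeCounts, hypothesis: HypothesisSpec
) -> tuple[np.ndarray, int, int]:
    """Log-coefficients of Pr(R | θ) = Σ_s exp(la_s) θ^s (1−θ)^{T−s}.

    Returns ``(la, T, region_size)`` where ``la[s]`` is the log of the
    summed combinatorial coefficients of the region's tables with s
    pooled successes (2×2 homogeneity: s = x11 + x21, T = n1 + n2;
    HWE: s = 2x1 + x2 copies of the A allele, T = 2n).
    """
    if hypothesis.kind == "homogeneity":
        if not isinstance(observed, ContingencyTable) or observed.shape != (2, 2):
            raise ValueError(
                "Barnard's test supports homogeneity for 2x2 tables only"
            )
        lam = lambda_homogeneity(observed)
        space = dict(margins=observed.row_margins.tolist())
        n1, n2 = (int(v) for v in observed.row_margins)
        T = n1 + n2
    elif hypothesis.kind == "hwe":
        if not isinstance(observed, GenotypeCounts):
            raise ValueError("hwe requires GenotypeCounts")
        lam, _ = lambda_hwe(observed)
        space = dict(n=observed.n)
        T = 2 * observed.n
    else:
        raise ValueError(
            "Barnard's test is not defined here for the independence hypothesis"
        )

    cutoff = lam.log_lambda + LOG_TIE_TOL
    la = np.full(T + 1, -np.inf)
    region_size = 0
    for stack in iter_space_chunks(hypothesis, **space):
        ll = _log_lambda_many(hypothesis, stack)
        mask = ll <= cutoff
        if not np.any(mask):
            continue
        sel = stack[mask].astype(np.float64)
        region_size += sel.shape[0]
        if hypothesis.kind == "homogeneity":
            i, j = sel[:, 0, 0], sel[:, 1, 0]
            logcoef = (
                gammaln(n1 + 1) - gammaln(i + 1) - gammaln(n1 - i + 1)
                + gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1)
            )
            s = (i + j).astype(np.int64)
        else:
            n = sel.sum(axis=1)
            logcoef = (
                gammaln(n + 1)
                - gammaln(sel + 1).sum(axis=1)
                + sel[:, 1] * np.log(2.0)
            )
            s = (2 * sel[:, 0] + sel[:, 1]).astype(np.int64)
        for deg in np.unique(s):
            vals = logcoef[s == deg]
            la[deg] = logsumexp(np.append(vals, la[deg]))
    return la, T, region_size


def _profile(la: np.ndarray, T: int, theta: np.ndarray) -> np.ndarray:
    """Pr(R | θ) for an array of θ values (0⁰ = 1 at the endpoints)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=np.float64))
    s = np.arange(T + 1, dtype=np.float64)
    finite = np.isfinite(la)
    terms = (
        la[finite][None, :]
        + xlogy(s[finite][None, :], theta[:, None])
        + xlogy(T - s[finite][None, :], 1.0 - theta[:, None])
    )
    # xlogy(0, 0) = 0 handles both endpoints; only impossible terms hit -inf
    return np.exp(terms).sum(axis=1)


def maximize_region_poly(la: np.ndarray, T: int) -> tuple[float, float]:
    """Maximize Σ_s exp(la_s) θ^s (1−θ)^{T−s} over θ ∈ [0, 1].

    Deterministic: a 1001-point uniform grid locates the bracketing
    interval, then golden-section search refines to 1e-10 in θ.
    Returns ``(max_value, argmax_theta)``.
    """
    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    vals = _profile(la, T, grid)
    k = int(np.argmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, _GRID_POINTS - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _profile(la, T, np.array([c]))[0]
    fd = _profile(la, T, np.array([d]))[0]
    while b - a > _REFINE_TOL:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _profile(la, T, np.array([c]))[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _profile(la, T, np.array([d]))[0]
    candidates = np.array([a, (a + b) / 2.0, b, grid[k]])
    cand_vals = _profile(la, T, candidates)
    best = int(np.argmax(cand_vals))
    return float(cand_vals[best]), float(candidates[best])


def barnard_pvalue(
    observed: ContingencyTable | GenotypeCounts, hypothesis: HypothesisSpec
) -> BarnardResult:
    """Barnard's unconditional exact p-value of ``observed``."""
    la, T, region_size = region_log_poly(observed, hypothesis)
    pmax, theta = maximize_region_poly(la, T)
    return BarnardResult(
        p=min(pmax, 1.0),
        theta_at_max=theta,
        region_size=region_size,
    )
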