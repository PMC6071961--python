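"""Likelihood-ratio λ statistics, evaluated in natural-log space.

λ is the supremum of the likelihood over the null set divided by its
supremum over the whole parameter space, so 0 < λ ≤ 1 and −2 ln λ is the
Wilks statistic.  All evaluation uses terms of the form x·ln(x/m) with
the 0·ln 0 = 0 convention (``scipy.special.xlogy``), which is both the
continuous limit of the likelihood at empty cells and immune to
under/overflow at the sample sizes the exact indices can enumerate.

Downstream code always compares ``log_lambda`` values, never the
exponentiated λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .tables import ContingencyTable, GenotypeCounts

__all__ = [
    "LambdaValue",
    "lambda_homogeneity",
    "lambda_independence",
    "lambda_hwe",
    "log_lambda_homogeneity_many",
    "log_lambda_independence_many",
    "log_lambda_hwe_many",
]


@dataclass(frozen=True)
class LambdaValue:
    """ln λ of a likelihood-ratio statistic; λ ∈ (0, 1]."""

    log_lambda: float

    def __post_init__(self) -> None:
        if self.log_lambda > 0.0 or not np.isfinite(self.log_lambda):
            raise ValueError(f"log lambda must be finite and <= 0, got {self.log_lambda}")

    @property
    def lam(self) -> float:
        return float(np.exp(self.log_lambda))

    @property
    def neg2_log_lambda(self) -> float:
        return -2.0 * self.log_lambda


def log_lambda_homogeneity_many(counts: np.ndarray) -> np.ndarray:
    """ln λ of the homogeneity LRT for a stack of tables.

    Parameters
    ----------
    counts : numpy.ndarray
        ``(N, ℓ, c)`` stack of tables sharing the fixed-row-margin design
        (margins may differ; each table uses its own).

    Under homogeneity the null MLE of the shared column-probability
    vector is n_·j/n_·· and the unrestricted row-wise MLE is x_ij/n_i·:
    ln λ = Σ_j n_·j ln(n_·j/n_··) − Σ_ij x_ij ln(x_ij/n_i·).
    """
    counts = np.asarray(counts, dtype=np.float64)
    rm = counts.sum(axis=2, keepdims=True)
    if np.any(rm == 0):
        raise ValueError("homogeneity lambda undefined for a zero row margin")
    cm = counts.sum(axis=1)
    n = counts.sum(axis=(1, 2))
    num = xlogy(cm, cm / n[:, None]).sum(axis=1)
    den = xlogy(counts, counts / rm).sum(axis=(1, 2))
    return np.minimum(num - den, 0.0)


def log_lambda_independence_many(counts: np.ndarray) -> np.ndarray:
    """ln λ of the independence LRT for a ``(N, ℓ, c)`` stack.

    ln λ = Σ_i n_i· ln(n_i·/n) + Σ_j n_·j ln(n_·j/n) − Σ_ij x_ij ln(x_ij/n).
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum(axis=(1, 2))
    if np.any(n == 0):
        raise ValueError("independence lambda undefined for an empty table")
    rm = counts.sum(axis=2)
    cm = counts.sum(axis=1)
    num = xlogy(rm, rm / n[:, None]).sum(axis=1) + xlogy(cm, cm / n[:, None]).sum(axis=1)
    den = xlogy(counts, counts / n[:, None, None]).sum(axis=(1, 2))
    return np.minimum(num - den, 0.0)


def log_lambda_hwe_many(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ln λ and the allele-frequency MLE θ̂ for a ``(N, 3)`` stack.

    θ̂ = (2x1 + x2)/(2n) and
    ln λ = x2 ln 2 + (2x1+x2) ln θ̂ + (2x3+x2) ln(1−θ̂) − Σ_i x_i ln(x_i/n),
    with boundary samples (θ̂ ∈ {0, 1}, monomorphic) handled by the
    0·ln 0 convention: they give λ = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.sum(axis=1)
    if np.any(n == 0):
        raise ValueError("hwe lambda undefined for n = 0")
    a = 2.0 * x[:, 0] + x[:, 1]  # copies of the A allele
    b = 2.0 * x[:, 2] + x[:, 1]
    theta = a / (2.0 * n)
    num = x[:, 1] * np.log(2.0) + xlogy(a, theta) + xlogy(b, 1.0 - theta)
    den = xlogy(x, x / n[:, None]).sum(axis=1)
    return np.minimum(num - den, 0.0), theta


def lambda_homogeneity(table: ContingencyTable) -> LambdaValue:
    """Homogeneity LRT λ for one table (fixed positive row margins)."""
    return LambdaValue(float(log_lambda_homogeneity_many(table.counts[None])[0]))


def lambda_independence(table: ContingencyTable) -> LambdaValue:
    """Independence LRT λ for one table (positive grand total)."""
    return LambdaValue(float(log_lambda_independence_many(table.counts[None])[0]))


def lambda_hwe(g: GenotypeCounts) -> tuple[LambdaValue, float]:
    """Hardy-Weinberg LRT λ and the null MLE θ̂ = (2x1+x2)/(2n)."""
    ll, theta = log_lambda_hwe_many(np.asarray([g.as_tuple()]))
    return LambdaValue(float(ll[0])), float(theta[0])
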