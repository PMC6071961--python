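"""Contingency-table types and exhaustive sample-space enumeration.

The exact indices in this package are computed by summing over *every*
table compatible with the sampling design: fixed row margins
(homogeneity, independent multinomial rows), fixed grand total
(independence, one multinomial over all cells), or a fixed number of
genotyped individuals (Hardy-Weinberg).  This module provides the
validated table containers, the enumerations, and their closed-form
counts (products of stars-and-bars binomial coefficients).

Enumeration order is lexicographic in the flattened count vector.  The
order is a package convention — every p-value computed here is a sum
over an order-independent region — but fixing it makes streams
deterministic and lets golden fixtures be compared byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ContingencyTable",
    "GenotypeCounts",
    "HypothesisSpec",
    "make_table",
    "enumerate_fixed_row_margins",
    "enumerate_fixed_total",
    "enumerate_genotype",
    "count_fixed_row_margins",
    "count_fixed_total",
    "count_genotype",
    "count_sample_space",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An ℓ×c table of nonnegative integer counts with derived margins.

    Attributes
    ----------
    counts : numpy.ndarray
        Read-only ``(ℓ, c)`` integer array of cell counts ``x_ij``.
    row_margins : numpy.ndarray
        Row sums ``n_i·``.
    col_margins : numpy.ndarray
        Column sums ``n_·j``.
    total : int
        Grand total ``n_··``.
    """

    counts: np.ndarray
    row_margins: np.ndarray = field(init=False)
    col_margins: np.ndarray = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError(f"counts must be a 2-D matrix, got ndim={c.ndim}")
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError(f"table must be at least 2x2, got shape {c.shape}")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                bad = np.argwhere(np.mod(c, 1) != 0)[0]
                raise ValueError(
                    f"non-integer count at row {bad[0] + 1}, column {bad[1] + 1}"
                )
            c = c.astype(np.int64)
        else:
            c = c.astype(np.int64)
        if np.any(c < 0):
            bad = np.argwhere(c < 0)[0]
            raise ValueError(
                f"negative count at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        rm = c.sum(axis=1)
        cm = c.sum(axis=0)
        rm.setflags(write=False)
        cm.setflags(write=False)
        object.__setattr__(self, "row_margins", rm)
        object.__setattr__(self, "col_margins", cm)
        object.__setattr__(self, "total", int(c.sum()))

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape  # type: ignore[return-value]

    @property
    def is_degenerate(self) -> bool:
        """True when some row margin (hence possibly the total) is zero."""
        return bool(np.any(self.row_margins == 0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return self.shape == other.shape and bool(
            np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.counts.tobytes()))

    def __repr__(self) -> str:
        return f"ContingencyTable({self.counts.tolist()})"


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype tallies (AA, Aa, aa) from ``n`` diploid individuals."""

    x1: int
    x2: int
    x3: int

    def __post_init__(self) -> None:
        for name in ("x1", "x2", "x3"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.x1 + self.x2 + self.x3

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.x1, self.x2, self.x3)


_KINDS = ("homogeneity", "independence", "hwe")


@dataclass(frozen=True)
class HypothesisSpec:
    """Which null is tested, plus its two degree-of-freedom counts.

    ``df_freq`` is ``dim Θ − dim Θ_H``, the Wilks degrees of freedom of
    −2 ln λ; ``df_bayes`` is ``dim Θ``, the degrees of freedom of the
    asymptotic e-value reference distribution.  The Bayesian count is
    always the larger, which is why e-values dominate the matching
    asymptotic p-values.
    """

    kind: str
    shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "hwe":
            if self.shape is not None:
                raise ValueError("hwe hypothesis takes no table shape")
        else:
            if self.shape is None:
                raise ValueError(f"{self.kind} hypothesis requires a table shape")
            l, c = self.shape
            if l < 2 or c < 2:
                raise ValueError(f"shape must be at least 2x2, got {self.shape}")
            object.__setattr__(self, "shape", (int(l), int(c)))

    @classmethod
    def homogeneity(cls, n_rows: int, n_cols: int) -> "HypothesisSpec":
        return cls("homogeneity", (n_rows, n_cols))

    @classmethod
    def independence(cls, n_rows: int, n_cols: int) -> "HypothesisSpec":
        return cls("independence", (n_rows, n_cols))

    @classmethod
    def hwe(cls) -> "HypothesisSpec":
        return cls("hwe")

    @property
    def df_freq(self) -> int:
        if self.kind == "hwe":
            return 1
        l, c = self.shape  # type: ignore[misc]
        return (l - 1) * (c - 1)

    @property
    def df_bayes(self) -> int:
        if self.kind == "hwe":
            return 2
        l, c = self.shape  # type: ignore[misc]
        if self.kind == "homogeneity":
            return l * (c - 1)
        return l * c - 1


def make_table(counts) -> ContingencyTable:
    """Validate a matrix of counts and return an immutable table."""
    return ContingencyTable(np.asarray(counts))


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    # weak compositions of `total` into `parts` nonnegative parts,
    # lexicographically ascending
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def enumerate_fixed_row_margins(
    margins: Sequence[int], n_cols: int
) -> Iterator[ContingencyTable]:
    """Stream every table with the given row sums, ``n_cols`` columns.

    Tables appear in lexicographic order of the flattened count vector;
    the stream holds one table at a time.
    """
    margins = [int(m) for m in margins]
    if len(margins) < 2 or n_cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if any(m < 0 for m in margins):
        raise ValueError("row margins must be nonnegative")

    def rec(i: int, rows: list[tuple[int, ...]]) -> Iterator[ContingencyTable]:
        if i == len(margins):
            yield ContingencyTable(np.array(rows, dtype=np.int64))
            return
        for comp in _compositions(margins[i], n_cols):
            rows.append(comp)
            yield from rec(i + 1, rows)
            rows.pop()

    yield from rec(0, [])


def enumerate_fixed_total(
    n: int, n_rows: int, n_cols: int
) -> Iterator[ContingencyTable]:
    """Stream every ``n_rows × n_cols`` table with grand total ``n``."""
    if n < 0:
        raise ValueError("total must be nonnegative")
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    for flat in _compositions(int(n), n_rows * n_cols):
        yield ContingencyTable(
            np.asarray(flat, dtype=np.int64).reshape(n_rows, n_cols)
        )


def enumerate_genotype(n: int) -> Iterator[GenotypeCounts]:
    """Stream every genotype triple (x1, x2, x3) summing to ``n``."""
    if n < 0:
        raise ValueError("total must be nonnegative")
    for x1, x2, x3 in _compositions(int(n), 3):
        yield GenotypeCounts(x1, x2, x3)


def count_fixed_row_margins(margins: Sequence[int], n_cols: int) -> int:
    return int(np.prod([comb(int(m) + n_cols - 1, n_cols - 1) for m in margins]))


def count_fixed_total(n: int, n_rows: int, n_cols: int) -> int:
    k = n_rows * n_cols
    return comb(int(n) + k - 1, k - 1)


def count_genotype(n: int) -> int:
    return comb(int(n) + 2, 2)


def count_sample_space(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
) -> int:
    """Closed-form size of the sample space of ``hypothesis``.

    Homogeneity needs ``margins``; independence and HWE need ``n``.
    """
    if hypothesis.kind == "homogeneity":
        if margins is None:
            raise ValueError("homogeneity count requires row margins")
        return count_fixed_row_margins(margins, hypothesis.shape[1])  # type: ignore[index]
    if hypothesis.kind == "independence":
        if n is None:
            raise ValueError("independence count requires a grand total")
        l, c = hypothesis.shape  # type: ignore[misc]
        return count_fixed_total(n, l, c)
    if n is None:
        raise ValueError("hwe count requires a sample size")
    return count_genotype(n)


def enumerate_sample_space(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
):
    """Dispatch to the enumeration matching ``hypothesis``."""
    if hypothesis.kind == "homogeneity":
        if margins is None:
            raise ValueError("homogeneity enumeration requires row margins")
        return enumerate_fixed_row_margins(margins, hypothesis.shape[1])  # type: ignore[index]
    if hypothesis.kind == "independence":
        if n is None:
            raise ValueError("independence enumeration requires a grand total")
        l, c = hypothesis.shape  # type: ignore[misc]
        return enumerate_fixed_total(n, l, c)
    if n is None:
        raise ValueError("hwe enumeration requires a sample size")
    return enumerate_genotype(n)
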