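"""Independent brute-force oracles, kept deliberately naive.

Everything here works over fully materialized micro sample spaces with
exact rational arithmetic (``fractions.Fraction``): λ statistics are
rational numbers, h-weights are ratios of factorials, and regions are
resolved by exact comparison — so ties are exact and p-values come out
as exact rationals.  None of this code shares a line with the
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb, factorial


def compositions(total: int, parts: int):
    """Weak compositions, lexicographic, as tuples."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first, *rest)


def tables_fixed_margins(margins, c):
    per_row = [list(compositions(m, c)) for m in margins]
    for rows in product(*per_row):
        yield tuple(rows)


def tables_fixed_total(n, l, c):
    for flat in compositions(n, l * c):
        yield tuple(tuple(flat[i * c : (i + 1) * c]) for i in range(l))


def genotypes(n):
    yield from compositions(n, 3)


def _pow(base: Fraction, exp: int) -> Fraction:
    # 0^0 = 1 convention
    if exp == 0:
        return Fraction(1)
    return base**exp


def lam_homogeneity(tab) -> Fraction:
    rm = [sum(r) for r in tab]
    n = sum(rm)
    cm = [sum(r[j] for r in tab) for j in range(len(tab[0]))]
    num = Fraction(1)
    for m in cm:
        num *= _pow(Fraction(m, n), m)
    den = Fraction(1)
    for i, row in enumerate(tab):
        for x in row:
            den *= _pow(Fraction(x, rm[i]), x)
    return num / den


def lam_independence(tab) -> Fraction:
    n = sum(sum(r) for r in tab)
    rm = [sum(r) for r in tab]
    cm = [sum(r[j] for r in tab) for j in range(len(tab[0]))]
    num = Fraction(1)
    for m in rm + cm:
        num *= _pow(Fraction(m, n), m)
    den = Fraction(1)
    for row in tab:
        for x in row:
            den *= _pow(Fraction(x, n), x)
    return num / den


def lam_hwe(g) -> Fraction:
    x1, x2, x3 = g
    n = x1 + x2 + x3
    a, b = 2 * x1 + x2, 2 * x3 + x2
    theta = Fraction(a, 2 * n)
    num = Fraction(2) ** x2 * _pow(theta, a) * _pow(1 - theta, b)
    den = Fraction(1)
    for x in g:
        den *= _pow(Fraction(x, n), x)
    return num / den


def h_homogeneity(tab) -> Fraction:
    rm = [sum(r) for r in tab]
    n = sum(rm)
    c = len(tab[0])
    cm = [sum(r[j] for r in tab) for j in range(c)]
    num = 1
    for m in rm + cm:
        num *= factorial(m)
    den = factorial(n + c - 1)
    for row in tab:
        for x in row:
            den *= factorial(x)
    return Fraction(num, den)


def h_independence(tab) -> Fraction:
    n = sum(sum(r) for r in tab)
    l, c = len(tab), len(tab[0])
    rm = [sum(r) for r in tab]
    cm = [sum(r[j] for r in tab) for j in range(c)]
    num = factorial(n)
    for m in rm + cm:
        num *= factorial(m)
    den = factorial(n + l - 1) * factorial(n + c - 1)
    for row in tab:
        for x in row:
            den *= factorial(x)
    return Fraction(num, den)


def h_hwe(g) -> Fraction:
    x1, x2, x3 = g
    n = x1 + x2 + x3
    num = factorial(n) * 2**x2 * factorial(2 * x1 + x2) * factorial(2 * x3 + x2)
    den = factorial(x1) * factorial(x2) * factorial(x3) * factorial(2 * n + 1)
    return Fraction(num, den)


def exact_pvalues(space, lam_fn, h_fn) -> list[Fraction]:
    """Exact LRT p-value of every element of ``space``, as exact rationals."""
    space = list(space)
    lams = [lam_fn(t) for t in space]
    hs = [h_fn(t) for t in space]
    total = sum(hs)
    out = []
    for lo in lams:
        out.append(sum(h for lam, h in zip(lams, hs) if lam <= lo) / total)
    return out


def fisher_p_2x2(tab) -> Fraction:
    """Two-sided minimum-likelihood Fisher p-value by direct enumeration."""
    (a, b), (c, d) = tab
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    denom = comb(n, k)
    probs = {}
    for x in range(max(0, k - n2), min(n1, k) + 1):
        probs[x] = Fraction(comb(n1, x) * comb(n2, k - x), denom)
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs)
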