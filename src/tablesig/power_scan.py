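"""All-tables index scans and power surfaces.

A *scan* evaluates every requested significance index for every table
of an enumerated sample space — no simulation, the exact finite-sample
behavior of each index over its whole domain.  A *power surface*
evaluates, on a grid of parameter values, the probability that an index
falls at or below the significance level: by Monte Carlo table
sampling (the procedure the indices are usually compared with) or
exactly, summing sampling probabilities over the pre-computed rejection
set.  Because the sample space is fixed, each index is computed once
per table and reused across all grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy
from scipy.stats import chi2

from .barnard import maximize_region_poly
from .classical import chisq_stat_many, fisher_pvalues_2x2_many
from .exact_lrt import LOG_TIE_TOL, NullDistribution, build_null_distribution
from .fbst import evalue_mc
from .tables import ContingencyTable, GenotypeCounts, HypothesisSpec

__all__ = [
    "SCENARIOS",
    "PowerSurface",
    "FREQUENTIST_INDICES",
    "default_indices",
    "index_values_for_space",
    "scan_all_tables",
    "interior_grid",
    "power_surface_mc",
    "power_surface_exact",
]

#: The ten scan scenarios: (hypothesis, sizes keyword arguments).
SCENARIOS: dict[int, tuple[HypothesisSpec, dict]] = {
    1: (HypothesisSpec.homogeneity(2, 2), {"margins": (30, 30)}),
    2: (HypothesisSpec.homogeneity(2, 2), {"margins": (100, 100)}),
    3: (HypothesisSpec.homogeneity(2, 3), {"margins": (30, 30)}),
    4: (HypothesisSpec.homogeneity(3, 3), {"margins": (15, 15, 15)}),
    5: (HypothesisSpec.independence(2, 2), {"n": 30}),
    6: (HypothesisSpec.independence(2, 3), {"n": 30}),
    7: (HypothesisSpec.independence(3, 3), {"n": 15}),
    8: (HypothesisSpec.independence(3, 3), {"n": 25}),
    9: (HypothesisSpec.hwe(), {"n": 30}),
    10: (HypothesisSpec.hwe(), {"n": 100}),
}

FREQUENTIST_INDICES = ("exact_lrt", "asymptotic_lrt", "chisq", "fisher", "barnard")
_ALL_INDICES = FREQUENTIST_INDICES + ("evalue_mc", "asymptotic_evalue")


def _fisher_supported(hypothesis: HypothesisSpec) -> bool:
    return hypothesis.kind == "homogeneity" and hypothesis.shape == (2, 2)


def _barnard_supported(hypothesis: HypothesisSpec) -> bool:
    return _fisher_supported(hypothesis) or hypothesis.kind == "hwe"


def default_indices(
    hypothesis: HypothesisSpec, with_evalue_mc: bool = False
) -> tuple[str, ...]:
    """Every index defined for ``hypothesis`` (MC e-value on request)."""
    names = ["exact_lrt", "asymptotic_lrt", "chisq"]
    if _fisher_supported(hypothesis):
        names.append("fisher")
    if _barnard_supported(hypothesis):
        names.append("barnard")
    if with_evalue_mc:
        names.append("evalue_mc")
    names.append("asymptotic_evalue")
    return tuple(names)


def _validate_indices(hypothesis: HypothesisSpec, indices: Sequence[str]) -> None:
    for name in indices:
        if name not in _ALL_INDICES:
            raise ValueError(f"unknown index {name!r}; choose from {_ALL_INDICES}")
    if "fisher" in indices and not _fisher_supported(hypothesis):
        raise ValueError(
            "Fisher's exact test is only defined for 2x2 homogeneity tables"
        )
    if "barnard" in indices and not _barnard_supported(hypothesis):
        raise ValueError(
            "Barnard's test is only defined for 2x2 homogeneity tables and HWE"
        )


def _barnard_values(null: NullDistribution) -> np.ndarray:
    """Barnard p-value of every table, sharing one enumeration of the space."""
    hyp = null.hypothesis
    if hyp.kind == "homogeneity":
        counts = null.counts.astype(np.float64)
        n1 = int(counts[0].sum(axis=1)[0])
        n2 = int(counts[0].sum(axis=1)[1])
        i, j = counts[:, 0, 0], counts[:, 1, 0]
        logcoef = (
            gammaln(n1 + 1) - gammaln(i + 1) - gammaln(n1 - i + 1)
            + gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1)
        )
        s = (i + j).astype(np.int64)
        T = n1 + n2
    else:
        x = null.counts.astype(np.float64)
        n = int(x[0].sum())
        logcoef = (
            gammaln(n + 1) - gammaln(x + 1).sum(axis=1) + x[:, 1] * np.log(2.0)
        )
        s = (2 * x[:, 0] + x[:, 1]).astype(np.int64)
        T = 2 * n
    out = np.empty(null.n_tables)
    for t in range(null.n_tables):
        mask = null.log_lambda <= null.log_lambda[t] + LOG_TIE_TOL
        la = np.full(T + 1, -np.inf)
        for deg in np.unique(s[mask]):
            la[deg] = logsumexp(logcoef[mask][s[mask] == deg])
        out[t] = min(maximize_region_poly(la, T)[0], 1.0)
    return out


def index_values_for_space(
    null: NullDistribution,
    indices: Sequence[str],
    k: int = 100_000,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Each requested index evaluated at every table of ``null``'s space.

    Arrays are aligned with the enumeration order of ``null.counts``.
    ``k`` and ``seed`` only matter when ``"evalue_mc"`` is requested;
    per-table substreams are spawned from the master seed.
    """
    hyp = null.hypothesis
    _validate_indices(hyp, indices)
    out: dict[str, np.ndarray] = {}
    neg2 = -2.0 * null.log_lambda
    for name in indices:
        if name == "exact_lrt":
            out[name] = null.pvalues_all()
        elif name == "asymptotic_lrt":
            out[name] = chi2.sf(neg2, hyp.df_freq)
        elif name == "asymptotic_evalue":
            out[name] = chi2.sf(neg2, hyp.df_bayes)
        elif name == "chisq":
            out[name] = chi2.sf(chisq_stat_many(null.counts, hyp), hyp.df_freq)
        elif name == "fisher":
            out[name] = fisher_pvalues_2x2_many(null.counts)
        elif name == "barnard":
            out[name] = _barnard_values(null)
        else:  # evalue_mc
            streams = np.random.SeedSequence(seed).spawn(null.n_tables)
            vals = np.empty(null.n_tables)
            for t in range(null.n_tables):
                if hyp.kind == "hwe":
                    obs = GenotypeCounts(*null.counts[t].tolist())
                else:
                    obs = ContingencyTable(null.counts[t])
                vals[t] = evalue_mc(
                    obs, hyp, k=k, rng=np.random.default_rng(streams[t])
                ).evalue
            out[name] = vals
    return out


def scan_all_tables(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
    indices: Sequence[str] | None = None,
    k: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Evaluate indices for every table of a sample space.

    Returns one row per table in enumeration order: ``table_id``, the
    flattened cell counts, ``log_lambda``, and one column per index.
    Only the MC e-value consumes randomness, so the output is
    deterministic given ``seed``.
    """
    if indices is None:
        indices = default_indices(hypothesis)
    null = build_null_distribution(hypothesis, margins=margins, n=n)
    values = index_values_for_space(null, indices, k=k, seed=seed)
    flat = null.counts.reshape(null.n_tables, -1)
    if hypothesis.kind == "hwe":
        cell_names = ["x1", "x2", "x3"]
    else:
        l, c = hypothesis.shape  # type: ignore[misc]
        cell_names = [f"x{i + 1}{j + 1}" for i in range(l) for j in range(c)]
    data = {"table_id": np.arange(null.n_tables)}
    data.update({name: flat[:, idx] for idx, name in enumerate(cell_names)})
    data["log_lambda"] = null.log_lambda
    data.update(values)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# power surfaces


@dataclass(frozen=True)
class PowerSurface:
    """Per-index rejection probability over a parameter grid.

    ``data`` has one row per grid point: ``theta1``, ``theta2`` and one
    power column per index.  ``reps`` is None for the enumeration-exact
    surface.
    """

    hypothesis: HypothesisSpec
    sizes: dict
    alpha: float
    grid: np.ndarray
    data: pd.DataFrame
    reps: int | None = None
    seed: int | None = None
    indices: tuple[str, ...] = field(default=())

    def to_long(self) -> pd.DataFrame:
        """(theta1, theta2, index, power) long form, for CSV output."""
        return self.data.melt(
            id_vars=["theta1", "theta2"], var_name="index", value_name="power"
        )


def interior_grid(resolution: int) -> np.ndarray:
    """``resolution`` equally spaced interior points of (0, 1).

    Midpoint placement (2k+1)/(2·resolution + 2) keeps every binomial
    and trinomial sampling model non-degenerate.
    """
    k = np.arange(resolution)
    return (2.0 * k + 1.0) / (2.0 * resolution + 2.0)


def _power_setup(
    hypothesis: HypothesisSpec,
    margins: Sequence[int] | None,
    n: int | None,
    indices: Sequence[str] | None,
    alpha: float,
    grid,
):
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    if hypothesis.kind == "homogeneity":
        if hypothesis.shape != (2, 2):
            raise ValueError("power surfaces support 2x2 homogeneity only")
        if margins is None or len(margins) != 2:
            raise ValueError("2x2 homogeneity power requires two row margins")
        sizes = {"margins": tuple(int(m) for m in margins)}
    elif hypothesis.kind == "hwe":
        if n is None:
            raise ValueError("hwe power requires a sample size n")
        sizes = {"n": int(n)}
    else:
        raise ValueError("power surfaces are not defined for independence here")
    if indices is None:
        indices = tuple(
            name for name in default_indices(hypothesis) if name in FREQUENTIST_INDICES
        )
    for name in indices:
        if name not in FREQUENTIST_INDICES:
            raise ValueError(
                f"power is defined for frequentist p-value indices only, got {name!r}"
            )
    _validate_indices(hypothesis, indices)
    axis = interior_grid(grid) if isinstance(grid, int) else np.asarray(grid, float)
    null = build_null_distribution(hypothesis, **sizes)
    pvals = index_values_for_space(null, indices)
    reject = {name: pvals[name] <= alpha for name in indices}
    return sizes, tuple(indices), axis, null, reject


def _hwe_flat_index(n: int) -> np.ndarray:
    """Lookup L[x1, x2] -> position of (x1, x2, n-x1-x2) in lex order."""
    L = np.full((n + 1, n + 1), -1, dtype=np.int64)
    pos = 0
    for x1 in range(n + 1):
        for x2 in range(n - x1 + 1):
            L[x1, x2] = pos
            pos += 1
    return L


def power_surface_mc(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
    grid: int | Sequence[float] = 100,
    reps: int = 1000,
    alpha: float = 0.05,
    indices: Sequence[str] | None = None,
    seed: int | None = None,
) -> PowerSurface:
    """Monte-Carlo power surface: rejection proportion among ``reps``
    sampled tables at each grid point.

    Each grid point draws from its own substream spawned from the master
    seed, so the surface is reproducible in any evaluation order.
    """
    if reps < 1:
        raise ValueError(f"reps must be positive, got {reps}")
    sizes, indices, axis, null, reject = _power_setup(
        hypothesis, margins, n, indices, alpha, grid
    )
    if hypothesis.kind == "homogeneity":
        n1, n2 = sizes["margins"]
        rej_mat = {nm: reject[nm].reshape(n1 + 1, n2 + 1) for nm in indices}
        points = [(t1, t2) for t1 in axis for t2 in axis]
    else:
        L = _hwe_flat_index(sizes["n"])
        points = [(t1, t2) for t1 in axis for t2 in axis if t1 + t2 < 1.0]
    streams = np.random.SeedSequence(seed).spawn(len(points))
    rows = []
    for idx, (t1, t2) in enumerate(points):
        rng = np.random.default_rng(streams[idx])
        row = {"theta1": t1, "theta2": t2}
        if hypothesis.kind == "homogeneity":
            i = rng.binomial(n1, t1, size=reps)
            j = rng.binomial(n2, t2, size=reps)
            for nm in indices:
                row[nm] = float(rej_mat[nm][i, j].mean())
        else:
            draws = rng.multinomial(sizes["n"], (t1, t2, 1.0 - t1 - t2), size=reps)
            flat = L[draws[:, 0], draws[:, 1]]
            for nm in indices:
                row[nm] = float(reject[nm][flat].mean())
        rows.append(row)
    return PowerSurface(
        hypothesis=hypothesis,
        sizes=sizes,
        alpha=alpha,
        grid=axis,
        data=pd.DataFrame(rows),
        reps=reps,
        seed=seed,
        indices=indices,
    )


def power_surface_exact(
    hypothesis: HypothesisSpec,
    *,
    margins: Sequence[int] | None = None,
    n: int | None = None,
    grid: int | Sequence[float] = 100,
    alpha: float = 0.05,
    indices: Sequence[str] | None = None,
) -> PowerSurface:
    """Enumeration-exact power: Σ over rejected tables of their sampling
    probability at each grid parameter.  No randomness."""
    sizes, indices, axis, null, reject = _power_setup(
        hypothesis, margins, n, indices, alpha, grid
    )
    rows = []
    if hypothesis.kind == "homogeneity":
        n1, n2 = sizes["margins"]
        i = np.arange(n1 + 1)
        j = np.arange(n2 + 1)
        lb1 = gammaln(n1 + 1) - gammaln(i + 1) - gammaln(n1 - i + 1)
        lb2 = gammaln(n2 + 1) - gammaln(j + 1) - gammaln(n2 - j + 1)
        rej_mat = {nm: reject[nm].reshape(n1 + 1, n2 + 1) for nm in indices}
        for t1 in axis:
            b1 = np.exp(lb1 + xlogy(i, t1) + xlogy(n1 - i, 1.0 - t1))
            for t2 in axis:
                b2 = np.exp(lb2 + xlogy(j, t2) + xlogy(n2 - j, 1.0 - t2))
                row = {"theta1": t1, "theta2": t2}
                for nm in indices:
                    row[nm] = float(b1 @ rej_mat[nm] @ b2)
                rows.append(row)
    else:
        x = null.counts.astype(np.float64)
        lcoef = gammaln(x.sum(axis=1)[0] + 1) - gammaln(x + 1).sum(axis=1)
        for t1 in axis:
            for t2 in axis:
                if t1 + t2 >= 1.0:
                    continue
                logp = (
                    lcoef
                    + xlogy(x[:, 0], t1)
                    + xlogy(x[:, 1], t2)
                    + xlogy(x[:, 2], 1.0 - t1 - t2)
                )
                pmf = np.exp(logp)
                row = {"theta1": t1, "theta2": t2}
                for nm in indices:
                    row[nm] = float(pmf[reject[nm]].sum())
                rows.append(row)
    return PowerSurface(
        hypothesis=hypothesis,
        sizes=sizes,
        alpha=alpha,
        grid=axis,
        data=pd.DataFrame(rows),
        reps=None,
        seed=None,
        indices=indices,
    )
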