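# Methods

## Models and hypotheses

Three sampling designs are supported, each with a finite sample space
given its design constants:

- **Homogeneity** (ℓ×c, fixed row margins n₁·, …, n_ℓ·): independent
  rows X_i ~ Multinomial(n_i·, θ_i1, …, θ_ic); H states that all rows
  share one column-probability vector. The sample space is the product
  of the per-row composition sets, ∏_i C(n_i·+c−1, c−1) tables.
- **Independence** (ℓ×c, fixed grand total n): one
  Multinomial(n, θ₁₁, …, θ_ℓc) over all cells; H states
  θ_ij = θ_i·θ_·j. Sample space: C(n+ℓc−1, ℓc−1) tables.
- **Hardy-Weinberg equilibrium** (genotype counts (x₁, x₂, x₃) of
  AA/Aa/aa, fixed n): Trinomial(n, θ₁, θ₂, θ₃); H restricts
  (θ₁, θ₂, θ₃) = (θ², 2θ(1−θ), (1−θ)²) for an allele frequency θ.
  Sample space: C(n+2, 2) outcomes.

Degrees of freedom: the frequentist reference χ² uses
dim Θ − dim Θ_H — (ℓ−1)(c−1) for both table hypotheses, 1 for HWE; the
Bayesian (FBST) reference uses dim Θ — ℓ(c−1) for homogeneity, ℓc−1
for independence, 2 for HWE.

## The exact LRT p-value

The null likelihood depends on a nuisance parameter (the shared column
probabilities; the margin probabilities; the allele frequency). It is
eliminated by integration against the uniform (flat Dirichlet) measure
on its domain, giving a weight h(x) per table with closed forms:

- homogeneity: h = ∏_i n_i·! ∏_j n_·j! / [∏ x_ij! (n+c−1)!]
- independence: h = n! ∏_i n_i·! ∏_j n_·j! / [∏ x_ij! (n+ℓ−1)!(n+c−1)!]
- HWE: h = n! 2^{x₂} (2x₁+x₂)! (2x₃+x₂)! / [x₁!x₂!x₃! (2n+1)!]

Normalizing h over the enumerated space yields Pr(x | H); the p-value
is the probability of the region R = {λ ≤ λ_obs}. Any positive
rescaling of h cancels in the normalization, so p-values are invariant
to the overall constant; for 2×2 homogeneity Σh = 1 exactly, for ℓ×c
independence Σh = 1/[(ℓ−1)!(c−1)!].

A second closed form for the independence weight,
(n+ℓ)!(n+c)!/(n! ∏ x_ij!), is provided separately
(`log_h_independence_published_total`). It reproduces the widely
quoted total 2304 over the ten 2×2 tables with n = 2, but it drops the
margin factorials and therefore defines a *different* distribution
over tables; this package's independence p-values always use the
integrated likelihood above, which is the construction the index is
defined by. The variant exists only so the published normalization
total can be cross-checked.

## Numerical choices

- All λ and h evaluation is in natural-log space: λ through terms
  x·ln(x/m) with the 0·ln 0 = 0 convention (`scipy.special.xlogy`),
  h through log-gamma. Factorial ratios like (n+c−1)! overflow doubles
  near n ≈ 170, well inside the sizes the enumerations support; the
  log forms do not.
- Region membership uses the weak inequality
  ln λ ≤ ln λ_obs + 1e−9. Symmetric tables are exact ties
  mathematically but can differ by ulps in floating point; 1e−9 is
  orders of magnitude above that noise and below any genuine λ gap on
  enumerable spaces. The tests confirm agreement to 1e−10 with an
  exact-rational oracle that resolves ties with `fractions.Fraction`.
- Enumeration order is lexicographic in the flattened count vector —
  p-values are order-independent, but a fixed order makes streams and
  golden fixtures reproducible byte for byte.
- Single-table exact p-values stream the space in vectorized chunks
  with an online log-sum-exp accumulator (constant memory per chunk);
  whole-space scans materialize per-table arrays and obtain all
  p-values at once by sorting λ and accumulating probability mass.
- Degenerate inputs: the all-zero table enumerates fine but λ is a
  domain error under homogeneity when a row margin is 0 (the design
  fixes positive sample sizes) and under independence/HWE when n = 0.
  Pearson cells with zero expected count have zero observed count in
  these designs and contribute nothing.

## Barnard's test

The critical region R is the same λ-region as the exact p-value.
Pr(R | θ) is a polynomial in θ: Σ_s a_s θ^s (1−θ)^{T−s} with s the
pooled success count (2×2) or allele count (HWE) and coefficients
accumulated in log space. The maximum over [0, 1] is located on a
uniform 1001-point grid (endpoints by the 0⁰ = 1 limit) and refined by
golden-section search to 1e−10 in θ — deterministic, and verified in
tests against a 10⁶-point dense grid to 1e−8. Barnard's test is
computed only where its product-binomial/trinomial null is defined
here: 2×2 homogeneity and HWE.

## Fisher's test

Conditional on both margins of a 2×2 table, the point probabilities
are hypergeometric; the two-sided p-value sums all point probabilities
at most the observed one (minimum-likelihood rule, the convention of
standard statistical software), with relative tolerance 1e−7 so that
symmetric ties count as ties. No mid-p variant, no continuity
correction anywhere in the package.

## FBST e-value

With flat Dirichlet priors the posterior is Dirichlet(x+1) (row-wise
under homogeneity). The supremum of the posterior density over the
null set has closed forms (the restricted profile is maximized at the
pooled column frequencies, the empirical margins, or the allele-
frequency MLE respectively), evaluated in log space and checked
against dense parametrizations of the null manifold. The e-value is
estimated by k posterior draws (default k = 10⁵; Gamma-normalized
Dirichlet sampling from a seeded generator): the fraction of draws
whose log density reaches the null supremum, within a 1e−12 log-scale
slack so rounding cannot flip an exact tie, estimates the tangent-set
mass. The binomial standard error √(f(1−f)/k) is attached. No
decision rule is attached to the e-value, and priors are not
configurable: the flat prior is the point of the comparison.

## Scans and power surfaces

Scans evaluate every requested index for every table of a scenario's
space; ten presets cover 2×2/2×3/3×3 homogeneity and independence at
totals 15–100 per row or table and HWE at n = 30 and 100. Since each
index depends only on the table, scans cache one value per table; the
MC e-value is the only consumer of randomness (per-table substreams
spawned from a master seed).

Power surfaces use the grid θ ∈ {1/202, 3/202, …} (interior midpoints;
100 points per axis by default) so no binomial is degenerate, with the
simplex-interior analogue for HWE. Rejection is index ≤ α with
α = 0.05 by default; ties at exactly α are included deliberately and
documented. The Monte-Carlo surface draws `reps` tables per grid point
(default 1000) from per-point substreams; the exact surface instead
sums each rejected table's sampling probability — a deterministic
reference the MC surface is tested against. Per-table p-values are
computed once and reused across all grid points, so a 100×100×1000
power study costs one scan plus table lookups.

## What the tests do and do not show

The test suite verifies exact agreement (to 1e−10) with rational-
arithmetic brute force on complete micro spaces (2×2 homogeneity
margins up to (6,6), independence totals up to 6 in 2×2 and 2×3, HWE
up to n = 12), closed-form micro examples for every index, the
discrete-p-value validity bound Pr(p ≤ α | H) ≤ α, null calibration of
the asymptotic LRT at margins (100,100) and HWE n = 100, the power
ordering (asymptotic LRT ≥ exact LRT ≥ chi-square ≥ Fisher, Barnard ≥
Fisher in grid mean at margins (10,10), computed on a 20×20 grid with
500 Monte-Carlo replicates checked against the exact surface), and
Spearman rank agreement > 0.99 between exact and asymptotic indices on
the margins-(30,30) scan. The simulated tables come from the exact
product-binomial/trinomial models — they probe the indices'
finite-sample behavior under the stated designs, not robustness to
misspecified sampling (dependent subjects, structured zeros), which no
test here addresses. Monte-Carlo comparisons are made at 3 binomial
standard errors per point; across the ~2000 point-index pairs of the
power check the count of 3σ exceedances is itself bounded at its 3σ
level, since a handful of exceedances is what correct sampling
produces.

## Known limitations

- Exhaustive enumeration only: no sampling approximation of the exact
  p-value, so independence spaces much beyond 3×3 with n ≈ 25
  (≈1.4×10⁷ tables) become impractical.
- Fisher is 2×2-homogeneity only; Barnard is 2×2-homogeneity and HWE
  only; power surfaces cover the two designs whose power is
  representable on a planar grid (2×2 homogeneity, HWE).
- The MC e-value inherits O(k^{−1/2}) error; k = 10⁶ gives ~5×10⁻⁴.
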