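# Methods

## Estimator

For paired vectors x, y of length n, every unordered pair of
observations is concordant ((x_i−x_j)(y_i−y_j) > 0), discordant (< 0),
tied in x only, tied in y only, or tied in both. With m = n(n−1)/2,
the tie-corrected Kendall coefficient is

    τ_b = (c − d) / √((m − T_x)(m − T_y)),

T_x and T_y counting pairs tied in x resp. y, joint ties included in
both. With no ties this reduces to (c − d)/m = 4c/(n(n−1)) − 1.

Knight's algorithm computes this in O(n log n):

1. sort observations by x, breaking x-ties by y, carrying y along;
2. count tie pairs in x (T_x), jointly in (x, y) (T_xy), and — after the
   merge sort has produced sorted y — in y (T_y), each as Σ L(L−1)/2
   over runs of equal values;
3. count inversions of the rearranged y with a merge sort. The (x, then
   y) sort order is essential: x-tied blocks are already ascending in
   y, so no x-tied pair can register as an inversion, and equal-y
   comparisons never count. The swap count therefore equals d exactly;
4. assemble the numerator S = m − T_x − T_y + T_xy − 2·swaps. The first
   four terms equal c + d (pairs tied in neither variable), so
   S = c − d;
5. τ_b = S / √((m − T_x)(m − T_y)).

The merge sort delegates to an insertion sort below length 10
(configurable constant; sub-threshold sorting strategy does not affect
any count, only constant factors). Ties are exact floating-point
equality — rank semantics, no epsilon; callers wanting tolerant ties
must pre-round. Infinities are valid ordered values; NaN is the missing
marker and is removed upstream. All pair counters are Python integers,
so counts up to m never overflow. The square root is taken of the exact
integer product (m−T_x)(m−T_y), which keeps τ = ±1 exact for perfectly
(anti)monotone data; the result is clamped to [−1, 1] against ulp-level
spill.

The definitional O(n²) scan (`oracle_counts`/`oracle_tau`) is kept as a
first-class function. It is the correctness anchor: the suite checks
knight_tau ≡ oracle_tau to 1e−12 over hundreds of randomized instances
(n ∈ [2, 200]) including tie-heavy and constant-run-heavy draws, plus
the partition invariant c + d + e + f + joint = m.

## Exact null distribution

Under independence with no ties, the concordant-pair statistic T has
the same null distribution as the inversion count of a uniform random
permutation, with counts

    w(n, k) = Σ_{i=0}^{n−1} w(n−1, k−i),  w(1, 0) = 1,  k ∈ [0, u],

u = n(n−1)/2. `ckendall` evaluates this recursion with a memoization
table (`NullTable`); out-of-range k returns 0. `pkendall(q, n)` returns
P(T ≤ ⌊q⌋) by summing counts and normalizing by Γ(n+1) = n!; q < 0
maps to 0 and q ≥ u to 1.

Counts are stored as doubles. Individual counts lose integer exactness
once they exceed 2^53 (first relevant around n ≈ 19–20), but CDF
ratios stay accurate to ~1e−15; n! overflows doubles near n = 171, and
the inference layer caps the exact path at n < 50, far below that. The
table is allocated per call by default; callers running many exact
tests at one n (e.g. null simulations) may pass a shared table — the
values are identical either way, the memo only avoids recomputation.

`gammafn` delegates to the platform double-precision gamma
(`math.gamma`), which satisfies the integer factorial identity exactly
within double range and implements reflection for negative non-integer
arguments. Poles at nonpositive integers raise `ValueError`.

## Hypothesis tests

Exact path (tie-free data, n < 50 under `exact_mode="auto"`; the cutoff
mirrors the convention of R's `cor.test`): statistic T = number of
concordant pairs,

    p_greater = 1 − pkendall(T−1, n),  p_less = pkendall(T, n),
    p_two = min(2·min(p_greater, p_less), 1).

Both tails include the observed point, so p_greater + p_less ≥ 1
always. Forcing the exact path on tied data is an error — the
permutation null assumes distinct ranks.

Approximate path: S = c − d is asymptotically normal with null variance

    v = (v0 − vt − vu)/18 + v1 + v2,

with v0 = n(n−1)(2n+5), vt = Σ t(t−1)(2t+5) over x tie-group sizes,
vu the same over y, v1 = [Σ t(t−1)][Σ u(u−1)]/(2n(n−1)), and
v2 = [Σ t(t−1)(t−2)][Σ u(u−1)(u−2)]/(9n(n−1)(n−2)); with no ties this
is n(n−1)(2n+5)/18. The statistic is z = (S − shift)/√v with
shift = sign(S) when the continuity correction is on (default off; the
correction accounts for the discreteness of S, and is what makes the
normal p comparable to the exact p, whose tails include the observed
point). The suite cross-checks this path against an independent
asymptotic tau-b test implementation on tied data.

## Confidence intervals

The interval uses the normal approximation with the null standard
error se = √(2(2n+5)/(9n(n−1))) and the z_{1−α/2} quantile for every
alternative: two-sided τ ± z·se; one-sided intervals pin the other
bound at ±1. Bounds are clamped to [−1, 1], and n ≥ 3 is required.
This reconstruction reproduces the worked example's printed 80%
one-sided lower bound 0.5038182 to all printed decimals. A caveat worth
stating: se is the standard error under τ = 0, so coverage away from
the null is approximate; on bivariate-normal data with ρ = 0.5 at
n = 200 the suite verifies ≥ 90% empirical coverage for the 95%
interval over 1,000 replicates.

## Validation semantics

`check_data` enforces: equal dimensions; pairwise-complete deletion
(a row is dropped if either value is NaN); at least two complete
observations; at least two distinct values per variable (zero variance
is an error since τ is undefined); numeric input. It is idempotent.
`tau_matrix` extends this per column pair with pairwise-complete rows
— the matrix semantics are a package design choice; pairs failing
validation give NaN entries with a warning rather than failing the
whole matrix. The CSV/TSV reader treats empty fields and the literal
`NA` as missing and infers the delimiter from the file extension.

## Synthetic data generator

`generate_sample` draws (x, y) from a standard bivariate normal with
latent correlation ρ, for which the population Kendall correlation is
exactly τ = (2/π)·arcsin ρ (Greiner's relation) — giving a known truth
for recovery and coverage tests. Setting `tie_granularity` rounds both
coordinates to a fixed grid, inducing the tied, discrete-valued data
the tie corrections exist for; discretization perturbs the effective
population τ, so exact-recovery assertions use the continuous form.
What the generator does not emulate: heavy tails, outliers,
monotone-but-nonlinear marginals (τ is invariant to those anyway),
serial dependence, or structured missingness. Passing tests on this
generator demonstrate algorithmic correctness and calibration under
clean exchangeable sampling, not robustness to real-data pathologies
beyond what rank invariance already provides.

## Problem sizes used in the test suite

Randomized-equivalence checks run 500 instances at n ∈ [2, 200]
(oracle-bounded); type-I-error calibration uses n = 20 with 2,000
replicates against the exact null; CI coverage uses n = 200 with 1,000
replicates; parameter recovery uses n = 20,000 (tolerance ±0.02 on τ,
consistent with the Monte-Carlo standard error at that size); the
subquadratic-scaling smoke check compares n = 40,000 vs 80,000 with a
generous factor and asserts no absolute times.

## Known limitations

- The exact null is unavailable for tied data (standard limitation);
  tied samples always use the normal approximation.
- The CI is a null-variance normal approximation; no bootstrap or
  variance-stabilized interval is provided.
- Weighted τ, τ-c, partial τ, and Pearson/Spearman coefficients are out
  of scope.
- `ckendall` counts are doubles: beyond n ≈ 19 they are correctly
  rounded but not exact integers; the exact-path cap keeps this
  irrelevant in practice.
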