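# Methods

## Model

One gene, n tissue pairs, expression (e_H, e_D) per pair.  A threshold
couple (k₁ ≤ k₂) maps values to signs in {−1, 0, +1}; values exactly on
a threshold map to 0 (the convention only matters for user-supplied
thresholds — the internal candidate cuts are midpoints between observed
values and never collide with data).  The discordance statistic
H = n_{+,−} + n_{−,+} counts pairs whose members lie on opposite sides
of the no-change band.

### Threshold search

H is piecewise constant in (k₁, k₂), so the exhaustive optimizer scans
the midpoints of consecutive sorted *unique* pooled values plus a
sentinel one unit below the minimum and one above the maximum — at most
2n + 1 candidates, O(m²) pairs evaluated with two boolean matrix
products.  Ties on H are broken by the widest band **in rank space**
(most candidate gaps spanned, then smallest lower index).  Rank-space
width, unlike k₂ − k₁, is preserved by every strictly increasing
transform of the data, which makes (x̂, p) exactly transform-invariant;
for evenly spaced values both rules coincide.  A seeded genetic
algorithm (tournament selection, uniform crossover, random-reset
mutation, elitism) over the same candidate set is provided for very
long profiles; it cannot exceed the exhaustive optimum and matches it
on small inputs in the test suite.  A shared-cut mode maximizes the
summed H over all genes with one threshold couple.

### Null models and the exact p-value

Constrained null: sign multisets K_H, K_D fixed, pairing uniformly
random.  The confusion matrix then has only four free entries (the
marginal system has rank 5); its law is the product of two multivariate
hypergeometric factors — the K_H⁺ healthy "up" tissues draw partners
from the diseased sign pool, the K_H⁻ row draws from the remainder.
The conditional pmf of x is computed by marginalizing the second factor
over n_{−,−} analytically (a univariate hypergeometric marginal),
leaving an O(n³) sum.

Relaxed null (the Hy-test proper): only the pooled counts
(K⁺, K⁻, K⁰) over the 2n tissues are fixed; the n diseased labels and
the pairing are both uniform.  The p-value is the split mixture of
conditional tails with multivariate hypergeometric weights.  The
implementation exploits an exact equivalence: a uniform label subset
followed by a uniform pairing is a uniform *oriented perfect matching*
of the 2n tissues, and x counts matched pairs containing one + and one
− sign, independent of orientation.  Counting matchings by pair-type
composition (t mixed, p "++", q "−−", a "+0", b "−0", c "00" pairs)
gives

    P(x = t) ∝ K⁺! K⁻! K⁰! / (t! 2ᵖ p! 2^q q! a! b! 2ᶜ c!),

normalized by (2n)!/(2ⁿ n!).  The whole pmf costs one O(n³) log-space
sum (log-gamma terms, log-sum-exp accumulation), is stable past
2n = 150, and is memoized on (K⁺, K⁻, K⁰) — the p-value is sufficient
in these counts plus x̂, so repeated sign compositions across genes are
free.  Three independent routes are reconciled in the tests to 1e−10:
this closed-form sum, the explicit split mixture, and brute-force
enumeration of every labelling and pairing (feasible to 2n = 14,
exercised to 12).

Numerical conventions: x̂ = 0 returns exactly 1; tails are clipped to
[0, 1]; empty tails return 0.  Bonferroni correction multiplies by the
number of tests and caps at 1.

## Preprocessing pipeline

Order: collapse duplicate gene rows to their mean → quantile
normalization jointly across all samples → log2(value + offset).  The
offset defaults to 1 for raw intensities; use 0 for already-positive
normalized data.  Quantile normalization maps each column's ranks onto
the vector of row means of the column order statistics; ties receive
the mean of the reference values their rank positions span.  With that
tie rule a second pass is *not* an exact no-op when columns have
different tie patterns (the per-column averaging operators do not
commute); idempotence holds exactly on tie-free data, where the
procedure also agrees with limma::normalizeQuantiles (checked in the
tests).  The Hy-test itself is rank-based past thresholding, so these
choices cannot change its per-gene results; they matter for the
scale-sensitive moderated-t comparator and are implemented for fidelity
to the standard workflow.

## Moderated paired t-test (comparator)

Per-gene paired differences d_g; s²_g shrunk toward a prior: a scaled F
distribution is moment-matched on log variances (digamma/trigamma
matching, Newton inversion of the trigamma function), giving prior df
d₀ and prior variance s₀²; the posterior variance is
(d₀ s₀² + (n−1) s²_g)/(d₀ + n − 1) and the moderated t uses
d₀ + n − 1 degrees of freedom (standard normal in the degenerate
d₀ = ∞ case, where s₀² is the mean sample variance).  Setting the prior
df to 0 recovers the ordinary paired t exactly.  The implementation is
validated against Bioconductor limma's eBayes to machine precision.

## Synthetic data generator

Each Monte Carlo replicate is one gene.  Pairs are coupled by a
Gaussian copula with parameter ρ (the simplest mechanism consistent
with a single correlation parameter; the data it produces have
within-pair Pearson correlation ≈ ρ on the log2 scale).

* Log-normal margins: bivariate normal on the log2 scale, marginal
  variance 0.25 (sd 0.5), mean 0 (healthy) vs mean_shift = 1
  (diseased) under the alternative — a two-fold change equal to two
  marginal standard deviations.
* Power-law margins: Pareto(x_min = 20, α = 3.5) vs
  Pareto(x_min = 40, α = 3.5) through the copula.  These parameters
  imply a log2 mean difference of exactly 1 and a log2 variance of
  1/((α−1) ln 2)² ≈ 0.33; an optional flag rescales the log2 spread to
  0.25 so the two marginal families can be matched on variance.  The
  default honours the Pareto parameters and leaves the variance
  statement to the log-normal case, where it is exactly realizable.
* Null blocks: independent samples, zero shift, same margins.

Study grid: marginals × n ∈ {50, 75} × ρ ∈ {0.1, 0.2, 0.4}, 250
replicates per cell, both tests applied to the log2-scale data, and
p-values Bonferroni-corrected with m = 250 (the only reading under
which a mean corrected rejection rate is well defined for the
shrinkage-based comparator, which needs the replicate ensemble).
Per-scenario seeds are spawned from one base seed and recorded in the
output table.

The fixture generator reuses the log-normal machinery with
gene-specific baselines (log2 mean ~ N(7, 2²)) and plants a fraction of
DE genes (default 10 of 60, alternating ±2 log2 shift = four marginal
SDs, n = 20 pairs, ρ = 0.2); it writes raw-scale intensities so the
full preprocessing path is exercised.

### What the generator does and does not emulate

It reproduces paired log2-scale expression with controllable mean
shifts, within-pair correlation, skewed/heavy-tailed margins and a
planted truth set.  It does **not** emulate gene–gene correlation,
batch effects, count-derived ties and zeros, or mixed effect sizes —
so passing tests show correctness of the inference machinery under the
stated sampling models, not performance on any particular real data
set.

### Known limitations of the study reproduction

Under this generator the published rate table is only partly
reproducible, and the failures are informative:

* With a log2 shift of 2 SDs at n = 50, the moderated t has
  noncentrality ≈ 10 and corrected power ≈ 1.0 in every cell; the
  published sub-unity t rates (0.70–0.96) — in particular a *lower* t
  power at (n = 75, ρ = 0.1) than at (n = 50, ρ = 0.2) — cannot be
  produced by any iid sampling scheme with a common effect size.
* Under a Gaussian copula with fixed margins, positive within-pair
  correlation makes (low, high) pairs *rarer*, so Hy-test power
  **decreases** in ρ (measured: 0.54 → 0.41 across ρ = 0.1 → 0.4,
  log-normal, n = 50); the published Hy trend increases in ρ, which is
  consistent with paired-t behaviour but not with a copula-coupled
  discordance count.  The dependence mechanism behind the published
  table evidently differs from a Gaussian copula; no alternative is
  specified, so the copula — the simplest one-parameter choice — is
  kept and the discrepancy is documented rather than tuned away.
* The power-law cells, where the discretizing test is at its strongest,
  do reproduce within Monte Carlo tolerance, as do the null blocks
  (corrected type-I rates ≤ 0.4% for both tests).

Problem sizes throughout (250 replicates per cell, enumeration oracles
to 2n = 12, fixture of 60 genes × 20 pairs) are the package's chosen
desk-scale defaults; the grid completes in seconds on one CPU thanks to
the memoized O(n³) p-value.

## Association tests

A single log-space upper-tail hypergeometric kernel serves the
literature co-occurrence test (articles with a disease keyword × a term
keyword among N articles) and gene-set over-representation (universe ×
set × query).  Tail terms are accumulated with log-sum-exp, so
associations far below the double-precision floor (~1.1e−16) are
reported exactly on the log10 scale with an underflow flag, instead of
collapsing to 0.  PubMed counts are user-supplied inputs: automated
querying depends on a live external service and would not be
deterministic.  Bonferroni across tested sets, significance at 5%.

## Degenerate inputs and edge conventions

Constant genes: a single unique pooled value yields two sentinel
candidates, h_max = 0, all signs 0, p = 1 — not an error.  Profiles
need n ≥ 2 and finite values.  Splits inconsistent with pooled counts,
out-of-range p-values, non-positive log arguments, duplicated samples
in a design, and queries outside the universe all raise ValueError.
Infeasible confusion configurations have probability 0 rather than
raising.
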