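"""Exact null distributions and p-values for the discordance statistic.

Two nested null models are implemented for the discordance count
x = n_{+,-} + n_{-,+} of a discretized paired profile.

Constrained model (fixed split): the healthy sign multiset K_H and the
diseased sign multiset K_D are both fixed and the pairing between the two
sets of tissues is uniformly random.  The 3x3 confusion matrix then
follows a product of multivariate hypergeometric laws: the K_H+ healthy
"up" tissues draw their partners without replacement from the diseased
sign pool, and the K_H- "down" tissues draw from the remainder.

Relaxed model (the Hy-test): only the pooled sign counts
(K+, K-, K0) over all 2n tissues are fixed; which n tissues carry the
"diseased" label, and the pairing, are both uniformly random.  This is a
mixture of constrained models with multivariate hypergeometric weights
C(K+, K_D+) C(K-, K_D-) C(K0, K_D0) / C(2n, n).

Choosing a uniformly random label subset and then a uniformly random
pairing is equivalent to drawing a uniformly random perfect matching of
the 2n tissues and orienting each matched pair at random; the statistic x
is simply the number of matched pairs containing one + and one - sign,
which does not depend on the orientation.  Counting matchings by their
pair-type composition therefore gives the relaxed null pmf as a single
three-index sum:

    P(x = t) = K+! K-! K0! / M(2n) *
               sum_{p,q} 1 / (t! 2^p p! 2^q q! a! b! 2^c c!)

with a = K+ - t - 2p "+0" pairs, b = K- - t - 2q "-0" pairs,
c = (K0 - a - b)/2 "00" pairs (integer, else the term vanishes) and
M(2n) = (2n)! / (2^n n!) the number of perfect matchings.  The sum is
evaluated in log space, costs O(n^3) for the whole pmf, and is verified
in the test-suite against both the split-mixture route and brute-force
enumeration of every labelling and pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math
from itertools import combinations

import numpy as np
from scipy.special import gammaln, logsumexp

from .discretize import (
    ConfusionMatrix,
    PairedGeneProfile,
    ThresholdPair,
    confusion_matrix,
    discretize,
    disagreement_statistic,
    optimize_thresholds,
)

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class PooledSignCounts:
    """Pooled sign counts (K+, K-, K0) over the 2n tissues of one gene."""

    k_plus: int
    k_minus: int
    k_zero: int
    n: int

    def __post_init__(self) -> None:
        if min(self.k_plus, self.k_minus, self.k_zero) < 0 or self.n < 1:
            raise ValueError("sign counts must be non-negative and n >= 1")
        if self.k_plus + self.k_minus + self.k_zero != 2 * self.n:
            raise ValueError("pooled sign counts must sum to 2n")

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.k_plus, self.k_minus, self.k_zero)


@dataclass(frozen=True)
class SplitCounts:
    """Sign counts per condition: kh = (K_H+, K_H-, K_H0), kd likewise."""

    kd: tuple[int, int, int]
    kh: tuple[int, int, int]

    def __post_init__(self) -> None:
        kd = tuple(int(v) for v in self.kd)
        kh = tuple(int(v) for v in self.kh)
        object.__setattr__(self, "kd", kd)
        object.__setattr__(self, "kh", kh)
        if min(kd) < 0 or min(kh) < 0:
            raise ValueError("sign counts must be non-negative")
        if sum(kd) != sum(kh):
            raise ValueError("both conditions must contain n tissues")

    @property
    def n(self) -> int:
        return sum(self.kd)


@dataclass
class HyTestResult:
    """Per-gene outcome: thresholds, observed discordance and p-values."""

    gene_id: str
    thresholds: ThresholdPair
    x_hat: int
    p_value: float
    pooled: PooledSignCounts
    p_adjusted: float = float("nan")


def _lchoose(n, k):
    """log C(n, k), elementwise; -inf where the coefficient vanishes."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = np.full(np.broadcast(n, k).shape, -np.inf)
    ok = (k >= 0) & (k <= n) & (n >= 0)
    nn = np.where(ok, n, 1.0)
    kk = np.where(ok, k, 0.0)
    vals = gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)
    out[ok] = vals[ok]
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Relaxed null model (the Hy-test proper)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=100_000)
def _null_logpmf(k_plus: int, k_minus: int, k_zero: int) -> np.ndarray:
    """Log pmf of x under the relaxed null, indexed 0..n."""
    total = k_plus + k_minus + k_zero
    n = total // 2
    log_m = gammaln(total + 1) - n * _LN2 - gammaln(n + 1)
    const = (
        gammaln(k_plus + 1)
        + gammaln(k_minus + 1)
        + gammaln(k_zero + 1)
        - log_m
    )
    logpmf = np.full(n + 1, -np.inf)
    for t in range(min(k_plus, k_minus) + 1):
        p = np.arange((k_plus - t) // 2 + 1)
        q = np.arange((k_minus - t) // 2 + 1)
        a = k_plus - t - 2 * p  # "+0" pairs
        b = k_minus - t - 2 * q  # "-0" pairs
        rem = k_zero - a[:, None] - b[None, :]
        ok = (rem >= 0) & (rem % 2 == 0)
        if not ok.any():
            continue
        c = np.where(ok, rem // 2, 0)
        terms = (
            -gammaln(t + 1)
            - (p * _LN2 + gammaln(p + 1) + gammaln(a + 1))[:, None]
            - (q * _LN2 + gammaln(q + 1) + gammaln(b + 1))[None, :]
            - c * _LN2
            - gammaln(c + 1)
        )
        logpmf[t] = const + logsumexp(terms[ok])
    logpmf.setflags(write=False)
    return logpmf


def null_statistic_pmf(pooled: PooledSignCounts) -> np.ndarray:
    """Exact pmf of the discordance statistic x under the relaxed null."""
    return np.exp(_null_logpmf(*pooled.key))


def hytest_pvalue(x_hat: int, pooled: PooledSignCounts) -> float:
    """Exact upper-tail p-value P(x >= x_hat) under the relaxed null.

    Depends on the data only through (K+, K-, K0, n, x_hat); results are
    memoized on the pooled counts so repeated genes with the same sign
    composition are free.
    """
    if x_hat <= 0:
        return 1.0
    if x_hat > pooled.n:
        return 0.0
    logpmf = _null_logpmf(*pooled.key)
    tail = logpmf[x_hat:]
    if np.all(np.isneginf(tail)):
        return 0.0
    return float(np.clip(np.exp(logsumexp(tail)), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Constrained model (fixed split) and the split-mixture route
# ---------------------------------------------------------------------------


def split_probability(split: SplitCounts, pooled: PooledSignCounts) -> float:
    """Probability that a random n-subset of the 2n tissues has sign
    composition ``split.kd`` (multivariate hypergeometric weight)."""
    if tuple(a + b for a, b in zip(split.kd, split.kh)) != pooled.key:
        raise ValueError("split is inconsistent with the pooled sign counts")
    if split.n != pooled.n:
        raise ValueError("split size differs from the number of pairs")
    lp = (
        _lchoose(pooled.k_plus, split.kd[0])
        + _lchoose(pooled.k_minus, split.kd[1])
        + _lchoose(pooled.k_zero, split.kd[2])
        - _lchoose(2 * pooled.n, pooled.n)
    )
    return float(np.exp(lp))


def _dependent_entries(
    n_pp: int, n_pm: int, n_mp: int, n_mm: int, split: SplitCounts
) -> tuple[int, int, int, int, int] | None:
    """Solve the marginal constraint system for the remaining confusion
    entries; None when any entry would be negative (infeasible)."""
    kd_p, kd_m, kd_0 = split.kd
    kh_p, kh_m, kh_0 = split.kh
    n_p0 = kh_p - n_pp - n_pm
    n_m0 = kh_m - n_mp - n_mm
    n_0p = kd_p - n_pp - n_mp
    n_0m = kd_m - n_pm - n_mm
    n_00 = kh_0 - n_0p - n_0m
    entries = (n_p0, n_m0, n_0p, n_0m, n_00)
    if min(entries) < 0:
        return None
    return entries


def confusion_pmf_given_split(
    n_pp: int, n_pm: int, n_mp: int, n_mm: int, split: SplitCounts
) -> float:
    """P(C | K_H, K_D) for the confusion matrix with the four free entries
    (n_{+,+}, n_{+,-}, n_{-,+}, n_{-,-}) under uniformly random pairing.

    Product of two multivariate hypergeometric factors: the healthy "+"
    row drawn from the diseased sign pool, then the healthy "-" row drawn
    from what remains.  Infeasible configurations have probability 0.
    """
    if min(n_pp, n_pm, n_mp, n_mm) < 0:
        return 0.0
    dep = _dependent_entries(n_pp, n_pm, n_mp, n_mm, split)
    if dep is None:
        return 0.0
    n_p0, n_m0, _, _, _ = dep
    kd_p, kd_m, kd_0 = split.kd
    kh_p, kh_m, _ = split.kh
    n = split.n
    lp = (
        _lchoose(kd_p, n_pp)
        + _lchoose(kd_m, n_pm)
        + _lchoose(kd_0, n_p0)
        - _lchoose(n, kh_p)
        + _lchoose(kd_p - n_pp, n_mp)
        + _lchoose(kd_m - n_pm, n_mm)
        + _lchoose(kd_0 - n_p0, n_m0)
        - _lchoose(n - kh_p, kh_m)
    )
    return float(np.exp(lp))


def statistic_distribution_given_split(split: SplitCounts) -> np.ndarray:
    """Exact pmf of x = n_{+,-} + n_{-,+} under the constrained null.

    The second hypergeometric factor is marginalized over n_{-,-}
    analytically: given the healthy "+" row, n_{-,+} follows a univariate
    hypergeometric law, so the pmf is a sum over (n_{+,+}, n_{+,-}) only.
    """
    kd_p, kd_m, kd_0 = split.kd
    kh_p, kh_m, _ = split.kh
    n = split.n
    pmf = np.zeros(n + 1)
    mp = np.arange(kh_m + 1)
    for n_pp in range(min(kh_p, kd_p) + 1):
        # marginal of n_{-,+}: draw kh_m partners from the n - kh_p
        # remaining diseased tissues, kd_p - n_pp of which are "+"
        log_hg = (
            _lchoose(kd_p - n_pp, mp)
            + _lchoose(n - kh_p - (kd_p - n_pp), kh_m - mp)
            - _lchoose(n - kh_p, kh_m)
        )
        for n_pm in range(min(kh_p - n_pp, kd_m) + 1):
            n_p0 = kh_p - n_pp - n_pm
            lp1 = (
                _lchoose(kd_p, n_pp)
                + _lchoose(kd_m, n_pm)
                + _lchoose(kd_0, n_p0)
                - _lchoose(n, kh_p)
            )
            if lp1 == -np.inf:
                continue
            contrib = np.exp(lp1 + log_hg)
            np.add.at(pmf, n_pm + mp, contrib)
    return pmf


def conditional_pvalue(x_hat: int, split: SplitCounts) -> float:
    """P(x >= x_hat | K_H, K_D) under the constrained null."""
    if x_hat <= 0:
        return 1.0
    if x_hat > split.n:
        return 0.0
    pmf = statistic_distribution_given_split(split)
    return float(np.clip(pmf[x_hat:].sum(), 0.0, 1.0))


def enumerate_splits(pooled: PooledSignCounts):
    """All feasible (K_D, K_H) splits of the pooled sign counts."""
    n = pooled.n
    for kd_p in range(min(pooled.k_plus, n) + 1):
        for kd_m in range(min(pooled.k_minus, n - kd_p) + 1):
            kd_0 = n - kd_p - kd_m
            if kd_0 < 0 or kd_0 > pooled.k_zero:
                continue
            kh = (
                pooled.k_plus - kd_p,
                pooled.k_minus - kd_m,
                pooled.k_zero - kd_0,
            )
            if min(kh) < 0 or sum(kh) != n:
                continue
            yield SplitCounts(kd=(kd_p, kd_m, kd_0), kh=kh)


def hytest_pvalue_by_splits(x_hat: int, pooled: PooledSignCounts) -> float:
    """Relaxed-null p-value via the explicit split mixture.

    Sums split_probability x conditional tail over every feasible split.
    Mathematically identical to :func:`hytest_pvalue`; kept as the slower
    reference route and exercised against it in the test-suite.
    """
    if x_hat <= 0:
        return 1.0
    total = 0.0
    for split in enumerate_splits(pooled):
        w = split_probability(split, pooled)
        if w == 0.0:
            continue
        total += w * conditional_pvalue(x_hat, split)
    return float(np.clip(total, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

_ENUMERATION_LIMIT = 14


def _distinct_permutations(items: tuple):
    """Distinct permutations of a multiset (lexicographic, iterative)."""
    seq = sorted(items)
    yield tuple(seq)
    n = len(seq)
    while True:
        i = n - 2
        while i >= 0 and seq[i] >= seq[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while seq[j] <= seq[i]:
            j -= 1
        seq[i], seq[j] = seq[j], seq[i]
        seq[i + 1 :] = reversed(seq[i + 1 :])
        yield tuple(seq)


@lru_cache(maxsize=50_000)
def _pairing_counts(h_signs: tuple, d_signs: tuple) -> tuple:
    """Counts of x over all n! pairings of two fixed sign multisets.

    Enumerates the distinct arrangements of the diseased signs against a
    fixed healthy order; each arrangement stands for prod_i (count of
    sign i in d)! indistinguishable bijections.
    """
    n = len(h_signs)
    weight = 1
    for s in (-1, 0, 1):
        weight *= math.factorial(d_signs.count(s))
    counts = [0] * (n + 1)
    for perm in _distinct_permutations(d_signs):
        x = sum(
            1
            for h, d in zip(h_signs, perm)
            if (h == 1 and d == -1) or (h == -1 and d == 1)
        )
        counts[x] += weight
    return tuple(counts)


def enumerate_null_oracle(pooled: PooledSignCounts) -> np.ndarray:
    """Exact relaxed-null pmf of x by brute-force enumeration.

    Walks every way of choosing which n of the 2n pooled signs are
    labelled diseased and, for each labelling, every pairing against the
    remaining signs, all with uniform probability.  Only intended as an
    independent oracle; refuses profiles with 2n > 14.
    """
    total = 2 * pooled.n
    if total > _ENUMERATION_LIMIT:
        raise ValueError(f"enumeration oracle limited to 2n <= {_ENUMERATION_LIMIT}")
    signs = (1,) * pooled.k_plus + (-1,) * pooled.k_minus + (0,) * pooled.k_zero
    counts = np.zeros(pooled.n + 1, dtype=float)
    for d_idx in combinations(range(total), pooled.n):
        d_set = frozenset(d_idx)
        d_signs = tuple(sorted(signs[i] for i in d_idx))
        h_signs = tuple(sorted(signs[i] for i in range(total) if i not in d_set))
        counts += np.asarray(_pairing_counts(h_signs, d_signs), dtype=float)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Multiple testing and the per-gene pipeline
# ---------------------------------------------------------------------------


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("multiplier m must be at least the number of tests")
    return np.minimum(p * m, 1.0)


def hytest_gene(
    profile: PairedGeneProfile,
    method: str = "exhaustive",
    seed: int | None = None,
    thresholds: ThresholdPair | None = None,
) -> HyTestResult:
    """Run the full Hy-test on one gene.

    Optimizes the discretization thresholds (unless supplied), counts the
    observed discordance x_hat and the pooled signs of the discretized
    profile, and returns the exact relaxed-null p-value.  ``p_adjusted``
    is NaN until a multiple-testing correction is applied by the caller.
    """
    if thresholds is None:
        thresholds, _ = optimize_thresholds(profile, method=method, seed=seed)
    v_h = discretize(profile.expr_h, thresholds)
    v_d = discretize(profile.expr_d, thresholds)
    c = confusion_matrix(v_h, v_d)
    x_hat = disagreement_statistic(c)
    signs = np.concatenate([v_h, v_d])
    pooled = PooledSignCounts(
        k_plus=int(np.count_nonzero(signs == 1)),
        k_minus=int(np.count_nonzero(signs == -1)),
        k_zero=int(np.count_nonzero(signs == 0)),
        n=profile.n_pairs,
    )
    p = hytest_pvalue(x_hat, pooled)
    return HyTestResult(
        gene_id=profile.gene_id,
        thresholds=thresholds,
        x_hat=x_hat,
        p_value=p,
        pooled=pooled,
    )
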