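"""Two-threshold sign discretization of paired expression profiles.

A gene measured in n healthy/diseased tissue pairs is discretized by a
threshold pair (k1, k2), k1 <= k2: values below k1 become -1 (down),
values above k2 become +1 (up), the band [k1, k2] becomes 0 (no change).
The thresholds are chosen, per gene, to maximize the discordance
statistic H = n_{+,-} + n_{-,+}: the number of pairs whose healthy and
diseased members fall on opposite sides of the no-change band.

Because H is piecewise constant in (k1, k2), an exhaustive scan over the
midpoints between consecutive sorted pooled values (plus one sentinel
below the minimum and one above the maximum) finds the global optimum
exactly.  A seeded genetic algorithm is available for very long profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_SIGN_INDEX = {1: 0, -1: 1, 0: 2}  # matrix index order (+, -, 0)


@dataclass(frozen=True)
class ThresholdPair:
    """A discretization cut (k1, k2) with k1 <= k2."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise ValueError("thresholds must be finite")
        if self.k1 > self.k2:
            raise ValueError(f"k1={self.k1} must not exceed k2={self.k2}")


@dataclass(frozen=True)
class PairedGeneProfile:
    """One gene's expression across n healthy/diseased tissue pairs.

    ``expr_h[i]`` and ``expr_d[i]`` come from the same donor.
    """

    gene_id: str
    expr_h: np.ndarray
    expr_d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "expr_h", np.asarray(self.expr_h, dtype=float))
        object.__setattr__(self, "expr_d", np.asarray(self.expr_d, dtype=float))
        if self.expr_h.ndim != 1 or self.expr_d.ndim != 1:
            raise ValueError("expression vectors must be one-dimensional")
        if self.expr_h.shape != self.expr_d.shape:
            raise ValueError("healthy and diseased vectors must have equal length")
        if self.n_pairs < 2:
            raise ValueError("need at least two tissue pairs")
        if not (np.isfinite(self.expr_h).all() and np.isfinite(self.expr_d).all()):
            raise ValueError("expression values must be finite")

    @property
    def n_pairs(self) -> int:
        return self.expr_h.shape[0]

    @property
    def pooled(self) -> np.ndarray:
        """All 2n values, healthy first."""
        return np.concatenate([self.expr_h, self.expr_d])


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 sign co-occurrence counts, rows = healthy sign, cols = diseased.

    Index order is (+, -, 0) on both axes.  Row sums give the healthy
    sign counts K_H, column sums the diseased sign counts K_D.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")
        object.__setattr__(self, "counts", c)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def k_h(self) -> tuple[int, int, int]:
        """(K_H+, K_H-, K_H0): sign counts of the healthy vector."""
        return tuple(int(v) for v in self.counts.sum(axis=1))

    @property
    def k_d(self) -> tuple[int, int, int]:
        """(K_D+, K_D-, K_D0): sign counts of the diseased vector."""
        return tuple(int(v) for v in self.counts.sum(axis=0))


def discretize(values: np.ndarray, thresholds: ThresholdPair) -> np.ndarray:
    """Map expression values to signs in {-1, 0, +1}.

    Values strictly below k1 map to -1, strictly above k2 to +1, and
    everything in the closed band [k1, k2] — including values exactly on
    a threshold — to 0.
    """
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("expression values must be finite")
    signs = np.zeros(v.shape, dtype=np.int8)
    signs[v < thresholds.k1] = -1
    signs[v > thresholds.k2] = 1
    return signs


def confusion_matrix(v_h: np.ndarray, v_d: np.ndarray) -> ConfusionMatrix:
    """Count sign co-occurrences of two paired sign vectors."""
    v_h = np.asarray(v_h)
    v_d = np.asarray(v_d)
    if v_h.shape != v_d.shape:
        raise ValueError("sign vectors must have equal length")
    for v in (v_h, v_d):
        if not np.isin(v, (-1, 0, 1)).all():
            raise ValueError("sign vectors may only contain -1, 0, +1")
    counts = np.zeros((3, 3), dtype=int)
    for h, d in zip(v_h.tolist(), v_d.tolist()):
        counts[_SIGN_INDEX[h], _SIGN_INDEX[d]] += 1
    return ConfusionMatrix(counts)


def disagreement_statistic(c: ConfusionMatrix) -> int:
    """H = n_{+,-} + n_{-,+}: pairs on opposite sides of the band."""
    return int(c.counts[0, 1] + c.counts[1, 0])


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Candidate cut points for a pooled value vector.

    Midpoints between consecutive sorted unique values, plus a sentinel
    one unit below the minimum and one above the maximum.  H is piecewise
    constant between observed values, so these candidates attain every
    achievable discretization.
    """
    u = np.unique(np.asarray(values, dtype=float))
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _h_matrix(expr_h: np.ndarray, expr_d: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """H for every candidate pair: entry (i, j) is H at k1=cand[i], k2=cand[j].

    n_{-,+}(k1, k2) counts pairs with h < k1 and d > k2, and symmetrically
    for n_{+,-}; both are inner products of boolean indicator matrices.
    """
    below_h = (expr_h[:, None] < cand[None, :]).astype(np.float64)
    below_d = (expr_d[:, None] < cand[None, :]).astype(np.float64)
    above_h = (expr_h[:, None] > cand[None, :]).astype(np.float64)
    above_d = (expr_d[:, None] > cand[None, :]).astype(np.float64)
    h = below_h.T @ above_d + below_d.T @ above_h
    return np.rint(h).astype(int)


def _best_cell(h: np.ndarray) -> tuple[int, int, int]:
    """Argmax over the upper triangle with deterministic tie-breaking.

    Ties on H are broken by the widest band in rank space (largest j - i,
    i.e. most candidate gaps inside the no-change band), then smallest i.
    Rank-space width, unlike k2 - k1, is preserved by any strictly
    increasing transform of the data, which keeps the whole test
    transform-invariant.
    """
    m = h.shape[0]
    ii, jj = np.triu_indices(m)
    vals = h[ii, jj]
    h_max = int(vals.max())
    at_max = vals == h_max
    width = (jj - ii)[at_max]
    cand_i = ii[at_max]
    cand_j = jj[at_max]
    best = np.lexsort((cand_i, -width))[0]
    return int(cand_i[best]), int(cand_j[best]), h_max


def optimize_thresholds(
    profile: PairedGeneProfile,
    method: str = "exhaustive",
    seed: int | None = None,
    generations: int = 200,
    population: int = 40,
) -> tuple[ThresholdPair, int]:
    """Find a threshold pair maximizing the discordance statistic H.

    method="exhaustive" scans every candidate pair and is exact and
    deterministic.  method="genetic" runs a seeded genetic algorithm over
    the same candidate set; it reaches the exhaustive optimum on small
    inputs given enough generations but does not guarantee it in general.
    """
    cand = candidate_thresholds(profile.pooled)
    if method == "exhaustive":
        h = _h_matrix(profile.expr_h, profile.expr_d, cand)
        i, j, h_max = _best_cell(h)
        return ThresholdPair(float(cand[i]), float(cand[j])), h_max
    if method == "genetic":
        i, j, h_max = _genetic_search(
            profile.expr_h, profile.expr_d, cand, seed, generations, population
        )
        return ThresholdPair(float(cand[i]), float(cand[j])), h_max
    raise ValueError(f"unknown method {method!r}")


def _genetic_search(
    expr_h: np.ndarray,
    expr_d: np.ndarray,
    cand: np.ndarray,
    seed: int | None,
    generations: int,
    population: int,
) -> tuple[int, int, int]:
    """Genetic algorithm over candidate index pairs (i <= j).

    Tournament selection, uniform crossover, random-reset mutation and
    elitism; fitness is (H, band width in rank space, -i) lexicographically
    so the reported optimum uses the same tie-break as the exhaustive scan.
    """
    rng = np.random.default_rng(seed)
    m = len(cand)

    def h_value(i: int, j: int) -> int:
        k1, k2 = cand[i], cand[j]
        return int(
            np.count_nonzero((expr_h < k1) & (expr_d > k2))
            + np.count_nonzero((expr_d < k1) & (expr_h > k2))
        )

    def fitness(ind: tuple[int, int]) -> tuple[int, int, int]:
        i, j = ind
        return (h_value(i, j), j - i, -i)

    def repair(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    pop = [repair(*sorted(rng.integers(0, m, size=2))) for _ in range(population)]
    scored = sorted(((fitness(p), p) for p in pop), reverse=True)
    best_fit, best = scored[0]
    for _ in range(generations):
        new_pop = [best, scored[1][1] if len(scored) > 1 else best]  # elitism
        while len(new_pop) < population:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, population, size=3)
                parents.append(max((scored[k][0], scored[k][1]) for k in idx)[1])
            child = tuple(parents[rng.integers(0, 2)][g] for g in range(2))
            if rng.random() < 0.3:
                child = (int(rng.integers(0, m)), child[1])
            if rng.random() < 0.3:
                child = (child[0], int(rng.integers(0, m)))
            new_pop.append(repair(*child))
        pop = new_pop
        scored = sorted(((fitness(p), p) for p in pop), reverse=True)
        if scored[0][0] > best_fit:
            best_fit, best = scored[0]
    return best[0], best[1], best_fit[0]


def optimize_shared_thresholds(
    profiles: list[PairedGeneProfile],
    max_candidates: int | None = None,
    seed: int | None = None,
) -> tuple[ThresholdPair, int]:
    """One cut-off couple shared by all genes, maximizing the summed H.

    Candidates are the midpoints over the pooled values of every gene;
    ``max_candidates`` optionally thins them to an evenly spaced subset
    for very large collections.  Returns the shared pair and the attained
    sum of per-gene discordance statistics.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    pooled = np.concatenate([p.pooled for p in profiles])
    cand = candidate_thresholds(pooled)
    if max_candidates is not None and len(cand) > max_candidates:
        keep = np.unique(np.linspace(0, len(cand) - 1, max_candidates).round().astype(int))
        cand = cand[keep]
    total = np.zeros((len(cand), len(cand)), dtype=int)
    for p in profiles:
        total += _h_matrix(p.expr_h, p.expr_d, cand)
    i, j, h_sum = _best_cell(total)
    return ThresholdPair(float(cand[i]), float(cand[j])), h_sum
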