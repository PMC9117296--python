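"""Hypergeometric association and over-representation tests.

One upper-tail hypergeometric kernel serves two purposes: quantifying
the literature co-occurrence of a disease keyword and a term keyword
across PubMed article counts, and testing a significant-gene list for
over-representation in named gene sets (GMT collections) against a gene
universe.  Tail probabilities are accumulated in log space, so
associations far below the double-precision floor (~1.1e-16) are still
reported exactly on the log scale and flagged as underflowing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exact import _lchoose, bonferroni_adjust

__all__ = [
    "LiteratureCounts",
    "hypergeom_tail",
    "literature_association_pvalue",
    "read_gmt",
    "gene_set_enrichment",
]

#: double-precision floor below which upper-tail p-values are flagged
UNDERFLOW_FLOOR = 1.11e-16


@dataclass(frozen=True)
class LiteratureCounts:
    """PubMed co-occurrence counts for one (disease, term) keyword pair.

    n_total articles overall, n_c with the disease keyword, n_t with the
    term keyword, n_ct with both.
    """

    n_total: int
    n_c: int
    n_t: int
    n_ct: int

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_c, self.n_t, self.n_ct) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_c > self.n_total or self.n_t > self.n_total:
            raise ValueError("keyword counts cannot exceed the article total")
        if self.n_ct > min(self.n_c, self.n_t):
            raise ValueError("joint count cannot exceed either margin")
        if self.n_ct < self.n_c + self.n_t - self.n_total:
            raise ValueError("joint count below the feasible minimum")


def hypergeom_log_tail(k: int, population: int, successes: int, draws: int) -> float:
    """log P(X >= k) for X hypergeometric(population, successes, draws)."""
    if k <= max(0, draws + successes - population):
        return 0.0
    upper = min(successes, draws)
    if k > upper:
        return -np.inf
    x = np.arange(k, upper + 1)
    log_terms = (
        _lchoose(successes, x)
        + _lchoose(population - successes, draws - x)
        - _lchoose(population, draws)
    )
    return float(logsumexp(log_terms))


def hypergeom_tail(k: int, population: int, successes: int, draws: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), in [0, 1]."""
    return float(np.clip(np.exp(hypergeom_log_tail(k, population, successes, draws)), 0.0, 1.0))


def literature_association_pvalue(
    counts: LiteratureCounts, log: bool = False
) -> float:
    """P(N_CT >= n_ct) under random allocation of term articles.

    The n_t term articles are modelled as a uniform draw from the
    n_total articles, n_c of which carry the disease keyword.  With
    ``log`` the natural-log tail is returned (exact even when the
    probability underflows a double).
    """
    lp = hypergeom_log_tail(counts.n_ct, counts.n_total, counts.n_c, counts.n_t)
    if log:
        return lp
    return float(np.clip(np.exp(lp), 0.0, 1.0))


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        sets[name] = {g for g in genes if g}
    return sets


def gene_set_enrichment(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    Gene sets are intersected with the universe; the query must be a
    subset of the universe.  Shares its kernel with the literature
    association test (population = universe, successes = set, draws =
    query, observed = overlap).  Bonferroni correction across sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & universe
        overlap = len(members & query)
        log_p = hypergeom_log_tail(overlap, len(universe), len(members), len(query))
        p = float(np.clip(np.exp(log_p), 0.0, 1.0))
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "overlap": overlap,
                "p_value": p,
                "log10_p": log_p / np.log(10.0),
                "underflow": p < UNDERFLOW_FLOOR,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bonferroni_adjust(table["p_value"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    return table
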