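"""Matrix-level differential expression analysis.

Preprocessing follows the usual microarray workflow: duplicated gene
rows are collapsed to their mean expression, columns are quantile
normalized to a shared reference distribution (the vector of row means
of the column order statistics), and values are log2-transformed with a
configurable offset.  The Hy-test itself is invariant to any strictly
increasing transform of a gene's pooled values, so normalization mainly
matters for the scale-sensitive moderated-t comparator; it is applied
for fidelity to the standard workflow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .discretize import PairedGeneProfile
from .exact import bonferroni_adjust, hytest_gene

__all__ = [
    "read_expression",
    "read_pairs",
    "collapse_duplicates",
    "quantile_normalize",
    "log2_transform",
    "preprocess",
    "run_dea",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Expects a tab- or comma-separated text file whose first column holds
    gene identifiers and whose header row holds sample identifiers.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample identifiers in header")
    return df.astype(float)


def read_pairs(path) -> list[tuple[str, str]]:
    """Read a two-column pairing table (healthy_id, diseased_id) with header."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("pairing table must have exactly two columns")
    return [tuple(row) for row in df.itertuples(index=False)]


def collapse_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace duplicated gene rows by their element-wise mean expression.

    Row order follows the first occurrence of each gene identifier.
    """
    if not matrix.index.duplicated().any():
        return matrix
    order = matrix.index.drop_duplicates()
    out = matrix.groupby(level=0, sort=False).mean()
    return out.loc[order]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the same empirical distribution.

    The reference distribution is the mean of the column order
    statistics.  Ties within a column all receive the mean of the
    reference values their rank positions span, so the procedure is
    well-defined and idempotent on tied data.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete data")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        normalized = reference.copy()
        # average the reference over runs of tied values
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    normalized[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = normalized
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Element-wise log2(value + offset)."""
    values = matrix.to_numpy(dtype=float) + offset
    if (values <= 0).any():
        raise ValueError("log2 transform requires value + offset > 0")
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def preprocess(
    matrix: pd.DataFrame,
    offset: float = 1.0,
    quantile: bool = True,
    log2: bool = True,
) -> pd.DataFrame:
    """Collapse duplicates, quantile-normalize (jointly across all
    samples), then log2-transform."""
    out = collapse_duplicates(matrix)
    if quantile:
        out = quantile_normalize(out)
    if log2:
        out = log2_transform(out, offset=offset)
    return out


def run_dea(
    matrix: pd.DataFrame,
    design: list[tuple[str, str]],
    alpha: float = 0.05,
    correction: str = "bonferroni",
    mode: str = "per-gene",
    method: str = "exhaustive",
    seed: int | None = None,
) -> pd.DataFrame:
    """Hy-test every gene of a preprocessed matrix over a paired design.

    ``design`` lists (healthy_sample_id, diseased_sample_id) couples; no
    sample may appear twice.  mode="per-gene" optimizes one threshold
    pair per gene; mode="global" shares a single cut-off couple across
    all genes.  Returns one row per gene with the thresholds, observed
    discordance, pooled sign counts, exact and Bonferroni-adjusted
    p-values, and the significance flag at level ``alpha``.
    """
    if correction != "bonferroni":
        raise ValueError("only the Bonferroni correction is supported")
    if not design:
        raise ValueError("empty paired design")
    h_ids = [h for h, _ in design]
    d_ids = [d for _, d in design]
    used = h_ids + d_ids
    if len(set(used)) != len(used):
        raise ValueError("a sample appears more than once in the design")
    missing = [s for s in used if s not in matrix.columns]
    if missing:
        raise ValueError(f"sample ids not in the matrix: {missing}")

    expr_h = matrix[h_ids].to_numpy(dtype=float)
    expr_d = matrix[d_ids].to_numpy(dtype=float)

    profiles = [
        PairedGeneProfile(gene_id=str(g), expr_h=expr_h[i], expr_d=expr_d[i])
        for i, g in enumerate(matrix.index)
    ]
    shared = None
    if mode == "global":
        from .discretize import optimize_shared_thresholds

        shared, _ = optimize_shared_thresholds(profiles)
    elif mode != "per-gene":
        raise ValueError(f"unknown mode {mode!r}")

    results = [
        hytest_gene(p, method=method, seed=seed, thresholds=shared)
        for p in profiles
    ]
    p_values = np.array([r.p_value for r in results])
    p_adj = bonferroni_adjust(p_values)
    table = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "k1": [r.thresholds.k1 for r in results],
            "k2": [r.thresholds.k2 for r in results],
            "x_hat": [r.x_hat for r in results],
            "K_plus": [r.pooled.k_plus for r in results],
            "K_minus": [r.pooled.k_minus for r in results],
            "K_zero": [r.pooled.k_zero for r in results],
            "p_value": p_values,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return table
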