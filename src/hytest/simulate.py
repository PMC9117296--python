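"""Monte Carlo robustness study and synthetic-data generator.

Paired synthetic expression profiles (Y1, Y2) are generated with either
log-normal or power-law (Pareto) marginals, coupled by a Gaussian copula
with parameter rho.  Each Monte Carlo replicate is treated as one gene:
a study scenario produces a genes x pairs matrix per condition, both
tests are applied gene-wise, p-values are Bonferroni-corrected across
the replicate ensemble, and the mean rejection rate is recorded.

Study conditions follow the published simulation design: n in {50, 75}
tissue pairs, rho in {0.1, 0.2, 0.4}, 250 replicates, a log2-scale mean
shift E[Y2] - E[Y1] = 1 with marginal log2 variance 0.25 under the
alternative, Pareto marginals PL(x_min = 20 resp. 40, alpha = 3.5), and
independent equal-mean samples under the null.  The module doubles as
the fixture generator for pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .discretize import PairedGeneProfile
from .ebayes import moderated_t_paired
from .exact import hytest_gene

__all__ = [
    "SimulationScenario",
    "simulate_paired_matrix",
    "rejection_rate",
    "run_power_study",
    "table_scenarios",
    "make_fixture",
    "write_fixture",
]

#: log2-scale standard deviation of log2(Pareto(x_min, alpha)); the log2
#: values are x_min-shifted exponentials with rate (alpha - 1) * ln 2.
def _pareto_log2_sd(alpha: float) -> float:
    return 1.0 / ((alpha - 1.0) * np.log(2.0))


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the Monte Carlo study.

    ``marginal`` selects log-normal or power-law (Pareto) expression;
    ``n`` is the number of tissue pairs per gene; ``rho`` the Gaussian
    copula parameter coupling the members of a pair; ``mean_shift`` and
    ``variance`` are the log2-scale mean difference and marginal
    variance (the variance applies to the log-normal case; the Pareto
    case inherits its spread from pl_alpha unless
    ``rescale_pl_variance`` is set); ``n_genes`` replicates are treated
    as genes of one matrix.
    """

    marginal: str
    n: int
    rho: float
    mean_shift: float = 1.0
    variance: float = 0.25
    pl_xmin1: float = 20.0
    pl_xmin2: float = 40.0
    pl_alpha: float = 3.5
    n_genes: int = 250
    seed: int = 0
    hypothesis: str = "alternative"
    rescale_pl_variance: bool = False

    def __post_init__(self) -> None:
        if self.marginal not in ("lognormal", "powerlaw"):
            raise ValueError("marginal must be 'lognormal' or 'powerlaw'")
        if self.hypothesis not in ("null", "alternative"):
            raise ValueError("hypothesis must be 'null' or 'alternative'")
        if self.n < 2:
            raise ValueError("need at least two pairs")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.variance <= 0:
            raise ValueError("variance must be positive")
        if self.pl_alpha <= 2:
            raise ValueError("pl_alpha must exceed 2 for a finite variance")
        if self.n_genes < 1:
            raise ValueError("need at least one replicate gene")


def _correlated_normals(
    rng: np.random.Generator, shape: tuple[int, int], rho: float
) -> tuple[np.ndarray, np.ndarray]:
    z1 = rng.standard_normal(shape)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(shape)
    return z1, z2


def _pareto_quantile(u: np.ndarray, xmin: float, alpha: float) -> np.ndarray:
    """Inverse CDF of the Pareto law with density ~ y^-alpha, y >= xmin."""
    return xmin * (1.0 - u) ** (-1.0 / (alpha - 1.0))


def simulate_paired_matrix(
    scenario: SimulationScenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (y1, y2): genes x pairs matrices of raw-scale expression.

    Under the alternative the pair members are coupled by a Gaussian
    copula with parameter rho and the stated log2-scale mean shift is
    applied; under the null the two samples are independent with equal
    means.  Log-normal margins are simulated directly as bivariate
    normal on the log2 scale; Pareto margins are obtained by pushing the
    copula margins through the Pareto quantile function.  Output is
    bit-reproducible from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    shape = (scenario.n_genes, scenario.n)
    null = scenario.hypothesis == "null"
    rho = 0.0 if null else scenario.rho
    z1, z2 = _correlated_normals(rng, shape, rho)

    if scenario.marginal == "lognormal":
        sd = np.sqrt(scenario.variance)
        x1 = sd * z1
        x2 = sd * z2 + (0.0 if null else scenario.mean_shift)
        return 2.0**x1, 2.0**x2

    xmin2 = scenario.pl_xmin1 if null else scenario.pl_xmin2
    y1 = _pareto_quantile(ndtr(z1), scenario.pl_xmin1, scenario.pl_alpha)
    y2 = _pareto_quantile(ndtr(z2), xmin2, scenario.pl_alpha)
    if scenario.rescale_pl_variance:
        # affine shrink of the log2 values about their mean so the log2
        # marginal variance matches scenario.variance
        scale = np.sqrt(scenario.variance) / _pareto_log2_sd(scenario.pl_alpha)
        for arr, xmin in ((y1, scenario.pl_xmin1), (y2, xmin2)):
            log2v = np.log2(arr)
            mean = np.log2(xmin) + _pareto_log2_sd(scenario.pl_alpha)
            arr[:] = 2.0 ** (mean + (log2v - mean) * scale)
    return y1, y2


def rejection_rate(p_values, alpha: float = 0.05, m: int | None = None) -> float:
    """Fraction of genes significant after Bonferroni correction."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("multiplier m must be at least the number of tests")
    return float(np.mean(np.minimum(p * m, 1.0) < alpha))


def _hytest_pvalues(log2_y1: np.ndarray, log2_y2: np.ndarray) -> np.ndarray:
    out = np.empty(log2_y1.shape[0])
    for g in range(log2_y1.shape[0]):
        profile = PairedGeneProfile(f"g{g}", log2_y1[g], log2_y2[g])
        out[g] = hytest_gene(profile).p_value
    return out


def run_power_study(
    scenarios: list[SimulationScenario],
    alpha: float = 0.05,
    tests: tuple[str, ...] = ("hytest", "moderated_t"),
) -> pd.DataFrame:
    """Simulate every scenario and record mean Bonferroni rejection rates.

    Both tests run on the log2-scale data (the Hy-test is invariant to
    the transform; the moderated t is not).  Returns a tidy frame with
    one row per (scenario, test).
    """
    rows = []
    for sc in scenarios:
        y1, y2 = simulate_paired_matrix(sc)
        x1, x2 = np.log2(y1), np.log2(y2)
        for test in tests:
            if test == "hytest":
                p = _hytest_pvalues(x1, x2)
            elif test == "moderated_t":
                p = moderated_t_paired(x1, x2)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(
                {
                    "method": test,
                    "marginal": sc.marginal,
                    "n": sc.n,
                    "rho": sc.rho,
                    "hypothesis": sc.hypothesis,
                    "n_genes": sc.n_genes,
                    "seed": sc.seed,
                    "rejection_rate": rejection_rate(p, alpha=alpha, m=sc.n_genes),
                }
            )
    return pd.DataFrame(rows)


def table_scenarios(
    seed: int = 0,
    n_genes: int = 250,
    include_null: bool = False,
) -> list[SimulationScenario]:
    """The published study grid: marginals x n in {50, 75} x rho in
    {0.1, 0.2, 0.4} under the alternative, plus optional null blocks."""
    seeds = np.random.SeedSequence(seed).generate_state(64) % (2**31)
    scenarios = []
    k = 0
    for marginal in ("lognormal", "powerlaw"):
        for n in (50, 75):
            for rho in (0.1, 0.2, 0.4):
                scenarios.append(
                    SimulationScenario(
                        marginal=marginal,
                        n=n,
                        rho=rho,
                        n_genes=n_genes,
                        seed=int(seeds[k]),
                        hypothesis="alternative",
                    )
                )
                k += 1
            if include_null:
                scenarios.append(
                    SimulationScenario(
                        marginal=marginal,
                        n=n,
                        rho=0.0,
                        n_genes=n_genes,
                        seed=int(seeds[k]),
                        hypothesis="null",
                    )
                )
                k += 1
    return scenarios


# ---------------------------------------------------------------------------
# Fixture generation for pipeline tests
# ---------------------------------------------------------------------------


def make_fixture(
    n_genes: int = 60,
    n_pairs: int = 20,
    frac_de: float = 1.0 / 6.0,
    effect: float = 2.0,
    variance: float = 0.25,
    rho: float = 0.2,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.DataFrame]:
    """Synthetic paired expression data with planted DE genes.

    Returns (expression matrix on the raw intensity scale, pairing list,
    truth table).  Genes are log-normal with gene-specific baseline
    means; a fraction ``frac_de`` receives a log2-scale shift of
    ``effect`` in the diseased tissues, alternating in sign.  Defaults
    plant 10 strongly shifted genes (a two-unit shift on log2, i.e. a
    four-fold change, four marginal standard deviations) among 50 nulls.
    """
    rng = np.random.default_rng(seed)
    n_de = int(round(n_genes * frac_de))
    sd = np.sqrt(variance)
    base = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    shifts = np.zeros(n_genes)
    shifts[:n_de] = effect * np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    order = rng.permutation(n_genes)
    base, shifts = base[order], shifts[order]

    z1, z2 = _correlated_normals(rng, (n_genes, n_pairs), rho)
    log2_h = base[:, None] + sd * z1
    log2_d = base[:, None] + shifts[:, None] + sd * z2

    h_ids = [f"N{i:02d}" for i in range(n_pairs)]
    d_ids = [f"T{i:02d}" for i in range(n_pairs)]
    gene_ids = [f"gene{i:03d}" for i in range(n_genes)]
    expr = pd.DataFrame(
        np.hstack([2.0**log2_h, 2.0**log2_d]),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=h_ids + d_ids,
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": shifts != 0.0, "log2_shift": shifts}
    )
    return expr, list(zip(h_ids, d_ids)), truth


def write_fixture(out_dir, **kwargs) -> dict[str, Path]:
    """Write a fixture data set (expression, pairs, truth) as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, pairs, truth = make_fixture(**kwargs)
    paths = {
        "expression": out / "expression.tsv",
        "pairs": out / "pairs.tsv",
        "truth": out / "truth.tsv",
    }
    expr.to_csv(paths["expression"], sep="\t")
    pd.DataFrame(pairs, columns=["healthy_id", "diseased_id"]).to_csv(
        paths["pairs"], sep="\t", index=False
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
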