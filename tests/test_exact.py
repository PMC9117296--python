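"""Exact null models: split weights, conditional laws, relaxed p-values."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hytest import (
    PairedGeneProfile,
    PooledSignCounts,
    SplitCounts,
    bonferroni_adjust,
    conditional_pvalue,
    confusion_pmf_given_split,
    enumerate_null_oracle,
    hytest_gene,
    hytest_pvalue,
    hytest_pvalue_by_splits,
    null_statistic_pmf,
    split_probability,
    statistic_distribution_given_split,
)
from hytest.exact import enumerate_splits


def pooled_configs(total):
    """All pooled sign configurations (K+, K-, K0) with K+ + K- + K0 = total."""
    for kp in range(total + 1):
        for km in range(total - kp + 1):
            yield PooledSignCounts(kp, km, total - kp - km, total // 2)


class TestSplitProbability:
    def test_all_zero_signs_single_split(self):
        pooled = PooledSignCounts(0, 0, 6, 3)
        split = SplitCounts(kd=(0, 0, 3), kh=(0, 0, 3))
        assert split_probability(split, pooled) == pytest.approx(1.0)

    def test_balanced_example(self):
        pooled = PooledSignCounts(2, 2, 0, 2)
        split = SplitCounts(kd=(1, 1, 0), kh=(1, 1, 0))
        assert split_probability(split, pooled) == pytest.approx(4 / 6, abs=1e-12)

    @pytest.mark.parametrize("kp,km,k0", [(3, 2, 3), (0, 4, 4), (5, 5, 0), (2, 2, 8)])
    def test_split_weights_normalize(self, kp, km, k0):
        pooled = PooledSignCounts(kp, km, k0, (kp + km + k0) // 2)
        total = sum(split_probability(s, pooled) for s in enumerate_splits(pooled))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_split_rejected(self):
        pooled = PooledSignCounts(2, 2, 0, 2)
        with pytest.raises(ValueError):
            split_probability(SplitCounts(kd=(2, 0, 0), kh=(1, 1, 0)), pooled)


class TestConditionalModel:
    def test_forced_configuration(self):
        split = SplitCounts(kd=(3, 0, 0), kh=(3, 0, 0))
        assert confusion_pmf_given_split(3, 0, 0, 0, split) == pytest.approx(1.0)

    def test_two_pairings_example(self):
        split = SplitCounts(kd=(1, 1, 0), kh=(1, 1, 0))
        assert confusion_pmf_given_split(0, 1, 1, 0, split) == pytest.approx(0.5)
        pmf = statistic_distribution_given_split(split)
        assert pmf == pytest.approx([0.5, 0.0, 0.5], abs=1e-12)
        assert conditional_pvalue(2, split) == pytest.approx(0.5)

    def test_all_zero_healthy_row_point_mass(self):
        split = SplitCounts(kd=(2, 1, 1), kh=(0, 0, 4))
        pmf = statistic_distribution_given_split(split)
        assert pmf[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_confusion_pmf_normalizes_over_free_entries(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            kd = rng.multinomial(n, [1 / 3] * 3)
            kh = rng.multinomial(n, [1 / 3] * 3)
            split = SplitCounts(kd=tuple(kd), kh=tuple(kh))
            total = sum(
                confusion_pmf_given_split(a, b, c, d, split)
                for a in range(n + 1)
                for b in range(n + 1)
                for c in range(n + 1)
                for d in range(n + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-10)
            pmf = statistic_distribution_given_split(split)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            assert (pmf >= -1e-15).all()

    def test_tail_boundaries(self):
        split = SplitCounts(kd=(1, 1, 0), kh=(1, 1, 0))
        assert conditional_pvalue(0, split) == 1.0
        assert conditional_pvalue(split.n + 1, split) == 0.0


class TestRelaxedNull:
    def test_worked_example_two_thirds(self):
        pooled = PooledSignCounts(2, 2, 0, 2)
        assert hytest_pvalue(2, pooled) == pytest.approx(2 / 3, abs=1e-12)

    def test_trivial_tails(self):
        pooled = PooledSignCounts(3, 2, 3, 4)
        assert hytest_pvalue(0, pooled) == 1.0
        assert hytest_pvalue(pooled.n + 1, pooled) == 0.0
        all_zero = PooledSignCounts(0, 0, 8, 4)
        assert hytest_pvalue(1, all_zero) == 0.0

    @pytest.mark.parametrize("total", [2, 4, 6, 8])
    def test_matches_enumeration_oracle(self, total):
        for pooled in pooled_configs(total):
            pmf = null_statistic_pmf(pooled)
            oracle = enumerate_null_oracle(pooled)
            assert np.max(np.abs(pmf - oracle)) < 1e-10

    @pytest.mark.parametrize("total", [4, 6, 8, 10])
    def test_split_mixture_route_agrees(self, total):
        """Closed-form matching route == explicit split-mixture route."""
        for pooled in pooled_configs(total):
            for x_hat in range(pooled.n + 1):
                a = hytest_pvalue(x_hat, pooled)
                b = hytest_pvalue_by_splits(x_hat, pooled)
                assert a == pytest.approx(b, abs=1e-10)

    @given(
        kp=st.integers(0, 20),
        km=st.integers(0, 20),
        kz=st.integers(0, 12),
    )
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_structure_properties(self, kp, km, kz):
        if (kp + km + kz) % 2:
            kz += 1
        if kp + km + kz == 0:
            kz = 2
        total = kp + km + kz
        pooled = PooledSignCounts(kp, km, kz, total // 2)
        pmf = null_statistic_pmf(pooled)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        # monotone non-increasing tail in x_hat
        tails = [hytest_pvalue(x, pooled) for x in range(pooled.n + 2)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))
        # +/- sign symmetry
        swapped = PooledSignCounts(km, kp, total - kp - km, total // 2)
        assert np.allclose(pmf, null_statistic_pmf(swapped), atol=1e-12)


class TestHytestGene:
    def test_perfectly_separated_small(self):
        p = PairedGeneProfile("g", [0.0, 0.1], [5.0, 5.1])
        res = hytest_gene(p)
        assert res.x_hat == 2
        assert res.pooled.key == (2, 2, 0)
        assert res.p_value == pytest.approx(2 / 3, abs=1e-12)

    def test_constant_gene(self):
        p = PairedGeneProfile("g", [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        res = hytest_gene(p)
        assert res.x_hat == 0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_composition_contract_and_sufficiency(self, seed):
        rng = np.random.default_rng(seed)
        p = PairedGeneProfile("g", rng.normal(0, 1, 7), rng.normal(1, 1, 7))
        res = hytest_gene(p)
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value == hytest_pvalue(res.x_hat, res.pooled)

    @pytest.mark.parametrize("seed", range(5))
    def test_label_symmetry(self, seed):
        rng = np.random.default_rng(seed + 50)
        h, d = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
        r1 = hytest_gene(PairedGeneProfile("g", h, d))
        r2 = hytest_gene(PairedGeneProfile("g", d, h))
        assert r1.x_hat == r2.x_hat
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed + 99)
        h, d = rng.normal(0, 1, 9), rng.normal(0.6, 1, 9)
        r1 = hytest_gene(PairedGeneProfile("g", h, d))
        r2 = hytest_gene(
            PairedGeneProfile("g", np.tanh(h) + 3 * h**3 + h, np.tanh(d) + 3 * d**3 + d)
        )
        assert (r1.x_hat, r1.p_value) == (r2.x_hat, pytest.approx(r2.p_value, abs=1e-14))


class TestBonferroni:
    def test_multiply_and_cap(self):
        assert bonferroni_adjust([0.01, 0.5]) == pytest.approx([0.02, 1.0])
        assert bonferroni_adjust([0.3]) == pytest.approx([0.3])
        assert bonferroni_adjust([0.001], m=1000) == pytest.approx([1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)
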