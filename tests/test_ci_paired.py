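import math

import numpy as np
import pytest

from mccstats import (
    PairedCounts,
    fisher_ci,
    marginalize,
    mt_ci,
    mt_transform,
    paired_estimate,
    simple_diff_ci,
    zou_ci,
)
from mccstats.ci_paired import _zou_bounds
from mccstats.ci_single import z_quantile

from conftest import interior_points


def paired_from_labels(actual, pred1, pred2) -> PairedCounts:
    cells = np.zeros((2, 2, 2), dtype=int)
    for a, p1, p2 in zip(actual, pred1, pred2):
        cells[p1, p2, a] += 1
    return PairedCounts.from_array(cells)


def random_paired_counts(rng, n=500) -> PairedCounts:
    p = interior_points(rng, 8, 1)[0]
    return PairedCounts.from_array(rng.multinomial(n, p).reshape(2, 2, 2))


def swap_classifiers(pc: PairedCounts) -> PairedCounts:
    return PairedCounts.from_array(np.asarray(pc.cells).transpose(1, 0, 2))


class TestPairedEstimate:
    def test_identical_classifiers(self, rng):
        a = rng.integers(0, 2, size=60)
        p1 = np.where(rng.random(60) < 0.8, a, 1 - a)
        pe = paired_estimate(paired_from_labels(a, p1, p1))
        assert pe.r1 == pytest.approx(pe.r2, abs=1e-12)
        assert pe.diff == pytest.approx(0.0, abs=1e-12)
        assert pe.corr == pytest.approx(1.0, abs=1e-9)

    def test_complementary_classifiers(self, rng):
        a = rng.integers(0, 2, size=60)
        p1 = np.where(rng.random(60) < 0.8, a, 1 - a)
        pe = paired_estimate(paired_from_labels(a, p1, 1 - p1))
        assert pe.r2 == pytest.approx(-pe.r1, abs=1e-12)
        assert pe.corr == pytest.approx(-1.0, abs=1e-9)

    def test_marginal_variance_consistency(self, rng):
        """var1 from the 8-dim delta matrix equals the single-table delta
        variance of the marginalized 2x2 table."""
        from mccstats.ci_single import _phi_and_var

        for _ in range(5):
            pc = random_paired_counts(rng)
            pe = paired_estimate(pc)
            m1 = marginalize(pc, 1)
            _, var_unit, _ = _phi_and_var(m1.as_array() / m1.n)
            assert pe.var1 == pytest.approx(float(var_unit) / pc.n, abs=1e-12)

    def test_na_on_zero_margin(self):
        cells = np.zeros((2, 2, 2), dtype=int)
        cells[1, 1, 1] = 10  # no actual negatives anywhere
        cells[0, 0, 1] = 5
        pe = paired_estimate(PairedCounts.from_array(cells))
        assert pe.na and "zero margin" in pe.na_reason


class TestSimpleDiffCi:
    def test_na_for_identical_classifiers(self, rng):
        a = rng.integers(0, 2, size=60)
        p1 = np.where(rng.random(60) < 0.8, a, 1 - a)
        ci = simple_diff_ci(paired_from_labels(a, p1, p1))
        assert ci.na and "variance" in ci.na_reason

    def test_variance_identity(self, rng):
        """Var(diff) = var1 + var2 - 2 corr sqrt(var1 var2)."""
        for _ in range(5):
            pc = random_paired_counts(rng)
            ci = simple_diff_ci(pc)
            pe = paired_estimate(pc)
            half = (ci.upper - ci.lower) / 2.0
            var = pe.var1 + pe.var2 - 2.0 * pe.corr * math.sqrt(pe.var1 * pe.var2)
            assert half == pytest.approx(z_quantile(0.95) * math.sqrt(var), abs=1e-12)

    def test_swap_negates_endpoints(self, rng):
        pc = random_paired_counts(rng)
        ci = simple_diff_ci(pc)
        sw = simple_diff_ci(swap_classifiers(pc))
        assert sw.lower == pytest.approx(-ci.upper, abs=1e-12)
        assert sw.upper == pytest.approx(-ci.lower, abs=1e-12)

    def test_symmetric(self, rng):
        pc = random_paired_counts(rng)
        ci = simple_diff_ci(pc)
        assert ci.upper - ci.estimate == pytest.approx(ci.estimate - ci.lower, abs=1e-12)


class TestZouCi:
    def test_pythagorean_reduction_at_zero_corr(self):
        w1, w2 = 0.11, 0.07
        lo, hi = _zou_bounds(0.5, 0.3, 0.5 - w1, 0.5 + w1, 0.3 - w2, 0.3 + w2, 0.0)
        half = math.sqrt(w1**2 + w2**2)
        assert hi - (0.5 - 0.3) == pytest.approx(half, abs=1e-14)
        assert (0.5 - 0.3) - lo == pytest.approx(half, abs=1e-14)

    def test_direct_substitution(self, rng):
        for _ in range(10):
            r1, r2 = rng.uniform(-0.8, 0.8, size=2)
            w = rng.uniform(0.01, 0.3, size=4)
            l1, u1, l2, u2 = r1 - w[0], r1 + w[1], r2 - w[2], r2 + w[3]
            c = rng.uniform(-1, 1)
            lo, hi = _zou_bounds(r1, r2, l1, u1, l2, u2, c)
            d = r1 - r2
            exp_lo = d - math.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2))
            exp_hi = d + math.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2))
            assert lo == pytest.approx(exp_lo, abs=1e-14)
            assert hi == pytest.approx(exp_hi, abs=1e-14)

    def test_equal_marginals_half_width(self):
        # r1 = r2 with equal symmetric marginals of half-width w and
        # correlation c: interval symmetric about 0, half-width sqrt(2(1-c)) w
        r, w = 0.4, 0.09
        for c in (-0.5, 0.0, 0.6, 0.95):
            lo, hi = _zou_bounds(r, r, r - w, r + w, r - w, r + w, c)
            expect = math.sqrt(2.0 * (1.0 - c)) * w
            assert hi == pytest.approx(expect, abs=1e-14)
            assert lo == pytest.approx(-expect, abs=1e-14)

    def test_marginals_use_fisher_intervals(self, rng):
        """Zou's limits rebuild from the two marginal Fisher intervals."""
        pc = random_paired_counts(rng)
        pe = paired_estimate(pc)
        f1 = fisher_ci(marginalize(pc, 1))
        f2 = fisher_ci(marginalize(pc, 2))
        lo, hi = _zou_bounds(pe.r1, pe.r2, f1.lower, f1.upper, f2.lower, f2.upper, pe.corr)
        ci = zou_ci(pc)
        assert ci.lower == pytest.approx(float(lo), abs=1e-12)
        assert ci.upper == pytest.approx(float(hi), abs=1e-12)

    def test_na_at_unit_marginal_mcc(self):
        cells = np.zeros((2, 2, 2), dtype=int)
        cells[1, 1, 1] = 10
        cells[0, 0, 0] = 10
        cells[0, 1, 1] = 3  # classifier 1 stays perfect; classifier 2 not
        ci = zou_ci(PairedCounts.from_array(cells))
        assert ci.na and "equals 1" in ci.na_reason


class TestMtCi:
    def test_symmetric_at_zero_diff(self):
        # a table symmetric in the two prediction indices has identical
        # marginals, hence diff = 0 exactly, and g odd makes the MT
        # interval symmetric about 0
        cells = np.array([[[30, 5], [10, 8]], [[10, 8], [4, 25]]])
        pc = PairedCounts.from_array(cells)
        pe = paired_estimate(pc)
        assert pe.diff == 0.0
        ci = mt_ci(pc)
        assert ci.upper == pytest.approx(-ci.lower, abs=1e-12)

    def test_chain_rule_half_width(self, rng):
        """On the g scale the MT half-width equals the Simple half-width
        times g'(diff) = 2/(4 - diff^2)."""
        for _ in range(5):
            pc = random_paired_counts(rng)
            simple = simple_diff_ci(pc)
            mt = mt_ci(pc)
            d = simple.estimate
            half_g = mt_transform(mt.upper) - mt_transform(d)
            expect = (simple.upper - d) * 2.0 / (4.0 - d * d)
            assert half_g == pytest.approx(expect, rel=1e-10)

    def test_limits_inside_open_range(self, rng):
        pc = random_paired_counts(rng)
        ci = mt_ci(pc)
        assert -2 < ci.lower < ci.upper < 2

    def test_swap_negates_and_swaps_limits(self, rng):
        pc = random_paired_counts(rng)
        ci = mt_ci(pc)
        sw = mt_ci(swap_classifiers(pc))
        assert sw.lower == pytest.approx(-ci.upper, abs=1e-12)
        assert sw.upper == pytest.approx(-ci.lower, abs=1e-12)


class TestLargeSampleAgreement:
    def test_methods_converge_as_counts_scale(self, rng):
        pc = random_paired_counts(rng, n=200)
        base = np.asarray(pc.cells)
        gaps = []
        for k in (1, 10, 100, 1000):
            scaled = PairedCounts.from_array(base * k)
            cis = [simple_diff_ci(scaled), zou_ci(scaled), mt_ci(scaled)]
            gap = max(
                max(abs(a.lower - b.lower), abs(a.upper - b.upper))
                for i, a in enumerate(cis)
                for b in cis[i + 1 :]
            )
            gaps.append(gap)
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))

    def test_na_sets(self):
        """Simple and MT share the zero-margin NA rule; Zou additionally
        fails at unit marginal MCC."""
        cells = np.zeros((2, 2, 2), dtype=int)
        cells[1, 1, 1] = 10
        cells[0, 0, 0] = 10
        cells[0, 1, 1] = 3
        pc = PairedCounts.from_array(cells)
        assert not simple_diff_ci(pc).na
        assert not mt_ci(pc).na
        assert zou_ci(pc).na
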