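import math

import numpy as np
import pytest

from foundercnv.formats import GeneInterval
from foundercnv.stats import (
    Table2x2,
    adjust_p,
    associate,
    burden_metrics,
    burden_test,
    chi_square_p,
    odds_ratio_ci,
    power_by_simulation,
    solve_noncarrier_rate,
    two_by_two,
)
from tests.conftest import make_call

# the reconstructed carrier-by-AUD table for the chr22 VCF-region duplication:
# 27 carriers of whom 22 cases, 360 non-carriers of whom 209 cases (N=387)
VCF_DUP_TABLE = Table2x2(22, 5, 209, 151)


class TestTwoByTwo:
    def test_cross_tabulation(self):
        carriers = {f"S{i}": int(i < 27) for i in range(387)}
        cases = {f"S{i}": int(i < 22 or 27 <= i < 236) for i in range(387)}
        t = two_by_two(carriers, cases)
        assert (t.a, t.b, t.c, t.d) == (22, 5, 209, 151)

    def test_no_carriers(self):
        t = two_by_two({"A": 0, "B": 0}, {"A": 1, "B": 0})
        assert (t.a, t.b, t.c, t.d) == (0, 0, 1, 1)

    def test_all_cases_empty_noncase_column(self):
        t = two_by_two({"A": 1, "B": 0}, {"A": 1, "B": 1})
        assert t.b == 0 and t.d == 0

    def test_partial_overlap_dropped_disjoint_error(self):
        t = two_by_two({"A": 1, "B": 0, "X": 1}, {"A": 1, "B": 0, "Y": 1})
        assert t.n == 2
        with pytest.raises(ValueError):
            two_by_two({"A": 1}, {"B": 1})


class TestOddsRatio:
    def test_reconstructed_association_table(self):
        """OR 3.18 with Woolf CI [1.18, 8.59] on the reconstructed table."""
        res = odds_ratio_ci(VCF_DUP_TABLE)
        assert round(res.odds_ratio, 2) == 3.18
        assert round(res.ci_low, 2) == 1.18
        assert round(res.ci_high, 2) == 8.58  # 8.5839; printed 8.59 rounds the CI up
        assert res.ci_high == pytest.approx(8.59, abs=0.01)

    def test_balanced_table(self):
        res = odds_ratio_ci(Table2x2(10, 10, 10, 10))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_haldane_correction(self):
        res = odds_ratio_ci(Table2x2(5, 0, 10, 10))
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx(11.0)

    def test_double_zero_undefined(self):
        res = odds_ratio_ci(Table2x2(0, 0, 10, 10))
        assert res.undefined and math.isnan(res.odds_ratio)

    def test_transpose_inverts(self):
        t = VCF_DUP_TABLE
        res = odds_ratio_ci(t)
        swapped = odds_ratio_ci(Table2x2(t.c, t.d, t.a, t.b))
        assert swapped.odds_ratio == pytest.approx(1 / res.odds_ratio)
        assert swapped.ci_low == pytest.approx(1 / res.ci_high)
        assert swapped.ci_high == pytest.approx(1 / res.ci_low)

    def test_exact_method_available(self):
        res = odds_ratio_ci(VCF_DUP_TABLE, method="exact")
        assert res.ci_low < res.odds_ratio < res.ci_high


class TestChiSquare:
    def test_equal_proportions_zero(self):
        chi2, p = chi_square_p(Table2x2(10, 10, 20, 20))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_reconstructed_table_statistic(self):
        """N(ad-bc)^2 / (r1 r2 c1 c2) = 5.73 on the reconstructed table;
        the one-sided p matches the printed 0.01 at its precision."""
        chi2, p_two = chi_square_p(VCF_DUP_TABLE)
        t = VCF_DUP_TABLE
        by_hand = (
            t.n * (t.a * t.d - t.b * t.c) ** 2
            / ((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d))
        )
        assert chi2 == pytest.approx(by_hand)
        assert round(chi2, 2) == 5.73
        _, p_one = chi_square_p(VCF_DUP_TABLE, sided="one")
        assert p_one == pytest.approx(p_two / 2)
        assert round(p_one, 2) == 0.01

    def test_equals_squared_two_proportion_z(self):
        from scipy import stats as sps

        t = Table2x2(12, 30, 9, 50)
        chi2, _ = chi_square_p(t)
        p1, p2 = t.a / (t.a + t.b), t.c / (t.c + t.d)
        pooled = (t.a + t.c) / t.n
        z = (p1 - p2) / math.sqrt(pooled * (1 - pooled) * (1 / (t.a + t.b) + 1 / (t.c + t.d)))
        assert chi2 == pytest.approx(z**2)

    def test_permutation_invariance(self):
        t = Table2x2(7, 13, 29, 3)
        base = chi_square_p(t)[0]
        assert chi_square_p(Table2x2(13, 7, 3, 29))[0] == pytest.approx(base)
        assert chi_square_p(Table2x2(29, 3, 7, 13))[0] == pytest.approx(base)

    def test_zero_margin_undefined(self):
        chi2, p = chi_square_p(Table2x2(0, 0, 5, 5))
        assert math.isnan(chi2) and math.isnan(p)


class TestAdjustP:
    def test_bh_top_rank_thirteen_tests(self):
        """The smallest of 13 p-values, 0.006, has BH q = 0.006*13 = 0.078."""
        ps = [0.45, 0.96, 0.84, 0.91, 0.38, 0.71, 0.91, 0.13, 0.006, 0.28,
              0.74, 0.21, 0.70]
        q = adjust_p(ps, "bh")
        assert min(q) == pytest.approx(0.078)

    def test_p_one_stays_one(self):
        assert adjust_p([1.0], "bonferroni")[0] == 1.0
        assert adjust_p([1.0], "bh")[0] == 1.0

    def test_monotone_and_ordering(self):
        rng = np.random.default_rng(8)
        ps = rng.random(20)
        for method in ("bonferroni", "bh"):
            adj = adjust_p(ps, method)
            assert np.all(adj >= ps)
            order = np.argsort(ps)
            assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adjust_p(ps, "bonferroni")[np.argmin(ps)] >= adjust_p(ps, "bh")[np.argmin(ps)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p([0.5, 1.2], "bh")


class TestBurden:
    GENES = [
        GeneInterval("chr6", 31_360_000, 31_380_000, "MICA"),
        GeneInterval("chr6", 31_400_000, 31_410_000, "HCG26"),
        GeneInterval("chr7", 111_000_000, 111_200_000, "IMMP2L"),
    ]

    def test_multi_gene_overlap(self):
        call = make_call(sample="S1", chrom="chr6", start=31_355_318, end=31_451_476)
        b = burden_metrics([call], self.GENES)["S1"]
        assert b.n_cnvs == 1 and b.gene_load == 2

    def test_non_genic_region(self):
        call = make_call(sample="S1", chrom="chr13", start=84_102_440, end=84_157_927)
        assert burden_metrics([call], self.GENES)["S1"].gene_load == 0

    def test_partial_overlap_counts_once(self):
        # partly deletes IMMP2L, via two overlapping calls: one gene
        calls = [
            make_call(sample="S1", chrom="chr7", start=111_085_618, end=111_242_161),
            make_call(sample="S1", chrom="chr7", start=111_150_000, end=111_250_000),
        ]
        b = burden_metrics(calls, self.GENES)["S1"]
        assert b.n_cnvs == 2 and b.gene_load == 1

    def test_zero_call_samples_included(self):
        b = burden_metrics([], self.GENES, samples=["S9"])
        assert b["S9"].n_cnvs == 0 and b["S9"].gene_load == 0

    def test_burden_test_separation_and_rank_invariance(self):
        burdens = {f"C{i}": 10 + i for i in range(4)} | {f"K{i}": i for i in range(4)}
        phen = {f"C{i}": 1 for i in range(4)} | {f"K{i}": 0 for i in range(4)}
        _, p = burden_test(burdens, phen)
        assert p == pytest.approx(2 / 70)
        logged = {k: math.log1p(v) for k, v in burdens.items()}
        _, p2 = burden_test(logged, phen)
        assert p2 == pytest.approx(p)

    def test_empty_class_error(self):
        with pytest.raises(ValueError):
            burden_test({"A": 1.0}, {"A": 1})


class TestPower:
    def test_null_power_near_alpha(self):
        est = power_by_simulation(387, 0.60, 0.07, odds_ratio=1.0,
                                  alpha=0.05, reps=10_000, seed=11)
        assert abs(est.power - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / 10_000)

    def test_rare_carriers_low_power(self):
        est = power_by_simulation(387, 0.60, 0.001, odds_ratio=10,
                                  alpha=0.05, reps=2_000, seed=12)
        assert est.power < 0.2

    def test_power_monotone_in_effect_and_frequency(self):
        """Around the >2.2% carrier-frequency design point (OR 10, n=387),
        power grows with both the odds ratio and the carrier frequency and
        is far above the null rate."""
        kw = dict(n=387, prevalence=0.60, alpha=0.05, reps=4_000, seed=13)
        at_design = power_by_simulation(carrier_freq=0.022, odds_ratio=10, **kw)
        weaker = power_by_simulation(carrier_freq=0.022, odds_ratio=3, **kw)
        rarer = power_by_simulation(carrier_freq=0.01, odds_ratio=10, **kw)
        assert at_design.power > weaker.power + 3 * at_design.se
        assert at_design.power > rarer.power + 3 * at_design.se
        assert at_design.power > 0.3

    def test_reproducible_by_seed(self):
        a = power_by_simulation(100, 0.5, 0.1, 2.0, reps=500, seed=3)
        b = power_by_simulation(100, 0.5, 0.1, 2.0, reps=500, seed=3)
        assert a.power == b.power

    def test_solver_matches_constraints(self):
        p0, p1 = solve_noncarrier_rate(0.6, 0.07, 3.18)
        assert 0.07 * p1 + 0.93 * p0 == pytest.approx(0.6, abs=1e-9)
        odds = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds == pytest.approx(3.18, abs=1e-6)
        # OR=1 collapses both classes to the prevalence
        p0, p1 = solve_noncarrier_rate(0.6, 0.07, 1.0)
        assert p0 == pytest.approx(0.6) and p1 == pytest.approx(0.6)

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            solve_noncarrier_rate(1.5, 0.1, 2.0)
        with pytest.raises(ValueError):
            power_by_simulation(100, 0.0, 0.1, 2.0, reps=10, seed=1)


class TestAssociate:
    def test_full_result(self):
        carriers = {f"S{i}": int(i < 27) for i in range(387)}
        cases = {f"S{i}": int(i < 22 or 27 <= i < 236) for i in range(387)}
        r = associate("chr22_dup:AUD", carriers, cases)
        assert round(r.odds_ratio, 2) == 3.18
        assert r.p_one_sided < r.p_two_sided < 0.05
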