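"""2x2 association statistics against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fibrosnp as fs
from fibrosnp.cohort import AlleleTable

from oracles import (
    chi2_statistic_expected_loop,
    fisher_two_sided_enumeration,
    hwe_exact_enumeration,
)

positive_cell = st.integers(1, 200)


class TestOddsRatioWoolf:
    @pytest.mark.parametrize(
        "cells,or2,lo2,hi2",
        [
            # frozen from the published cohort rows that reproduce exactly
            ((71, 25, 125, 89), 0.49, 0.29, 0.84),
            ((95, 1, 198, 16), 0.13, 0.02, 1.00),
        ],
    )
    def test_reference_rows_2dp(self, cells, or2, lo2, hi2):
        from fibrosnp._util import round_half_away

        or_, lo, hi = fs.odds_ratio_woolf(AlleleTable(*cells))
        assert round_half_away(or_, 2) == or2
        assert round_half_away(lo, 2) == lo2
        assert round_half_away(hi, 2) == hi2

    def test_identity_table(self):
        or_, lo, hi = fs.odds_ratio_woolf(AlleleTable(10, 10, 10, 10))
        assert or_ == 1.0
        assert lo < 1.0 < hi

    @given(a=positive_cell, b=positive_cell, c=positive_cell, d=positive_cell)
    @settings(max_examples=200, deadline=None)
    def test_group_swap_reciprocity(self, a, b, c, d):
        """Swapping case and control rows inverts the OR and its CI."""
        or1, lo1, hi1 = fs.odds_ratio_woolf(AlleleTable(a, b, c, d))
        or2, lo2, hi2 = fs.odds_ratio_woolf(AlleleTable(c, d, a, b))
        assert or2 == pytest.approx(1 / or1)
        assert lo2 == pytest.approx(1 / hi1)
        assert hi2 == pytest.approx(1 / lo1)

    @given(a=positive_cell, b=positive_cell, c=positive_cell, d=positive_cell)
    @settings(max_examples=200, deadline=None)
    def test_allele_relabel_reciprocity(self, a, b, c, d):
        """Relabeling allele1 <-> allele2 inverts the OR, swaps CI bounds."""
        or1, lo1, hi1 = fs.odds_ratio_woolf(AlleleTable(a, b, c, d))
        or2, lo2, hi2 = fs.odds_ratio_woolf(AlleleTable(b, a, d, c))
        assert or2 == pytest.approx(1 / or1)
        assert (lo2, hi2) == (pytest.approx(1 / hi1), pytest.approx(1 / lo1))

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError):
            fs.odds_ratio_woolf(AlleleTable(10, 0, 10, 10))

    @given(a=positive_cell, b=positive_cell, c=positive_cell, d=positive_cell)
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, a, b, c, d):
        """Independent cross-check against statsmodels' 2x2 machinery."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t2 = sm.Table2x2([[b, a], [d, c]], shift_zeros=False)
        or_, lo, hi = fs.odds_ratio_woolf(AlleleTable(a, b, c, d))
        assert or_ == pytest.approx(t2.oddsratio)
        sm_lo, sm_hi = t2.oddsratio_confint(0.05)
        assert (lo, hi) == (pytest.approx(sm_lo), pytest.approx(sm_hi))


class TestRiskRatioKatz:
    def test_reference_fallback_row(self):
        """Variant in cases only: RR 3.28 (2.77-3.88) for (94,2,214,0)."""
        from fibrosnp._util import round_half_away

        rr, lo, hi = fs.risk_ratio_katz(AlleleTable(94, 2, 214, 0))
        assert rr == pytest.approx(308 / 94)  # hand arithmetic of the formula
        assert round_half_away(rr, 2) == 3.28
        assert (round_half_away(lo, 2), round_half_away(hi, 2)) == (2.77, 3.88)

    def test_closed_form(self):
        rr, _, _ = fs.risk_ratio_katz(AlleleTable(10, 10, 10, 0))
        assert rr == pytest.approx((10 / 10) / (10 / 20)) == 2.0

    def test_requires_case_variant(self):
        with pytest.raises(ValueError):
            fs.risk_ratio_katz(AlleleTable(10, 0, 10, 5))

    @given(a=positive_cell, b=positive_cell, c=positive_cell,
           d=st.integers(0, 200))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels(self, a, b, c, d):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t2 = sm.Table2x2([[b, d], [a, c]], shift_zeros=False)
        rr, lo, hi = fs.risk_ratio_katz(AlleleTable(a, b, c, d))
        assert rr == pytest.approx(t2.riskratio)
        sm_lo, sm_hi = t2.riskratio_confint(0.05)
        assert (lo, hi) == (pytest.approx(sm_lo), pytest.approx(sm_hi))


class TestPearsonChi2:
    def test_reference_row(self):
        stat, p = fs.pearson_chi2(AlleleTable(71, 25, 125, 89))
        assert stat == pytest.approx(6.889, abs=0.001)
        assert p == pytest.approx(0.00867, abs=1e-4)
        assert p < 0.01

    def test_independence(self):
        stat, p = fs.pearson_chi2(AlleleTable(10, 10, 10, 10))
        assert stat == 0.0
        assert p == 1.0

    @given(a=positive_cell, b=positive_cell, c=positive_cell, d=positive_cell)
    @settings(max_examples=200, deadline=None)
    def test_matches_expected_count_loop_oracle(self, a, b, c, d):
        stat, _ = fs.pearson_chi2(AlleleTable(a, b, c, d))
        assert stat == pytest.approx(chi2_statistic_expected_loop(a, b, c, d))

    def test_zero_margin_not_applicable(self):
        with pytest.raises(ValueError, match="zero margin"):
            fs.pearson_chi2(AlleleTable(10, 0, 10, 0))

    def test_yates_flag_lowers_statistic(self):
        plain, _ = fs.pearson_chi2(AlleleTable(20, 5, 15, 10))
        yates, _ = fs.pearson_chi2(AlleleTable(20, 5, 15, 10), correction=True)
        assert yates < plain


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((3, 0, 0, 3), 0.10),  # two extreme tables of probability 0.05
            ((5, 5, 5, 5), 1.0),
            ((96, 0, 213, 1), 1.0),  # variant only in controls
        ],
    )
    def test_known_values(self, cells, expected):
        assert fs.fisher_exact_two_sided(AlleleTable(*cells)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_degenerate_margin(self):
        assert fs.fisher_exact_two_sided(AlleleTable(5, 0, 7, 0)) == 1.0

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        p = fs.fisher_exact_two_sided(AlleleTable(a, b, c, d))
        assert p == pytest.approx(fisher_two_sided_enumeration(a, b, c, d), abs=1e-9)

    def test_doubling_convention(self):
        """Legacy doubling convention: caps at 1 for near-null sparse tables."""
        t = AlleleTable(95, 1, 213, 1)
        assert fs.fisher_exact_two_sided(t) == pytest.approx(0.524, abs=0.001)
        assert fs.fisher_exact_two_sided(t, convention="doubling") == 1.0


class TestChooseTest:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((71, 25, 125, 89), "chi_square"),  # min expected ~9.4
            # min expected cell = 96*17/310 = 5.27 >= 5 -> Cochran admits chi2
            ((95, 1, 198, 16), "chi_square"),
            ((92, 4, 207, 7), "fisher_exact"),  # expected case-variant 3.4
            ((96, 0, 214, 0), "fisher_exact"),  # zero margin
        ],
    )
    def test_cochran_rule(self, cells, expected):
        assert fs.choose_test(AlleleTable(*cells)) == expected

    def test_reproduces_reference_test_assignment(self, npc_results):
        """Cochran's rule reproduces the published chi-square/Fisher split."""
        fisher_rows = {
            "rs1800371", "rs9282871", "rs1800471", "rs11466314", "rs8179182",
            "rs11466334", "rs3213369", "rs3212112", "rs3734091", "rs41296835",
            "rs4987182", "rs1805389",
        }
        for r in npc_results:
            if r.test_used == "none":
                continue
            expected = "fisher_exact" if r.rs_id in fisher_rows else "chi_square"
            assert r.test_used == expected, r.rs_id

    def test_chi2_fisher_tail_agreement(self):
        """Asymptotic and exact p agree closely in the rejection tail.

        For tables with every cell >= 30 and exact p <= 0.1 the two
        tests differ by < 0.03 (away from the tail the two-sided
        conventions legitimately diverge).
        """
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 150:
            a, b, c, d = rng.integers(30, 120, 4)
            p_f = fs.fisher_exact_two_sided(AlleleTable(a, b, c, d))
            if p_f > 0.1:
                continue
            checked += 1
            _, p_c = fs.pearson_chi2(AlleleTable(a, b, c, d))
            assert abs(p_c - p_f) < 0.03


class TestEstimateEffect:
    def test_or_row(self):
        est = fs.estimate_effect(AlleleTable(83, 13, 155, 59))
        assert est.effect_type == "OR"
        assert est.effect == pytest.approx(0.4115, abs=1e-4)

    def test_zero_row(self):
        est = fs.estimate_effect(AlleleTable(96, 0, 213, 1))
        assert est.effect_type == "zero"
        assert est.effect == 0.0
        assert est.ci_low is None and est.ci_high is None

    def test_monomorphic_undefined(self):
        est = fs.estimate_effect(AlleleTable(96, 0, 214, 0))
        assert est.effect_type == "undefined"
        assert est.effect is None

    def test_rr_dispatch(self):
        est = fs.estimate_effect(AlleleTable(94, 2, 214, 0))
        assert est.effect_type == "RR"
        assert est.effect == pytest.approx(308 / 94)

    def test_haldane_flag(self):
        est = fs.estimate_effect(AlleleTable(96, 0, 213, 1), haldane=True)
        assert est.effect_type == "OR"
        assert 0 < est.effect < 1


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 45, 0.05 / 45), (0.05, 1, 0.05)]
    )
    def test_threshold(self, alpha, m, expected):
        assert fs.bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ValueError):
            fs.bonferroni_threshold(0.05, 0)

    def test_small_p_survives(self):
        assert 0.0005 < fs.bonferroni_threshold(0.05, 20)


class TestHweExact:
    def test_perfect_hwe_proportions(self):
        assert fs.hwe_exact_test((25, 50, 25)) >= 0.5

    def test_extreme_het_deficit(self):
        assert fs.hwe_exact_test((50, 0, 50)) < 1e-6

    def test_monomorphic(self):
        assert fs.hwe_exact_test((100, 0, 0)) == 1.0

    @given(
        naa=st.integers(0, 25), nab=st.integers(0, 25), nbb=st.integers(0, 25)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_rational_enumeration(self, naa, nab, nbb):
        p = fs.hwe_exact_test((naa, nab, nbb))
        assert p == pytest.approx(hwe_exact_enumeration(naa, nab, nbb), abs=1e-9)

    def test_simulated_hwe_genotypes_rarely_rejected(self):
        from fibrosnp.simulate import sample_genotypes_hwe

        rng = np.random.default_rng(1)
        rejections = 0
        for _ in range(100):
            dos = sample_genotypes_hwe(0.3, 150, rng)
            counts = ((dos == 0).sum(), (dos == 1).sum(), (dos == 2).sum())
            rejections += fs.hwe_exact_test(counts) <= 0.05
        assert rejections <= 12  # exact test is conservative at alpha=0.05


class TestAssociateAll:
    def test_reference_significant_set(self, npc_results):
        """Six SNPs nominally significant, matching the reported set."""
        sig = {r.rs_id for r in npc_results if r.significant_nominal}
        assert sig == {
            "rs1801516", "rs2279744", "rs1196333",
            "rs1800469", "rs25487", "rs1051677",
        }

    def test_direction_of_significant_effects(self, npc_results):
        """ATM variant deleterious, the other five variants protective."""
        for r in npc_results:
            if not r.significant_nominal:
                continue
            if r.rs_id == "rs1801516":
                assert math.log(r.effect) > 0
            else:
                assert math.log(r.effect) < 0

    def test_monomorphic_panel_all_undefined(self, toy_panel):
        tables = [AlleleTable(20, 0, 30, 0), AlleleTable(10, 0, 12, 0)]
        results = fs.associate_tables(toy_panel, tables)
        assert all(r.effect_type == "undefined" for r in results)
        assert all(r.test_used == "none" and r.p_value is None for r in results)
        assert not any(r.significant_nominal for r in results)

    def test_bonferroni_default_divisor_counts_informative_snps(
        self, npc_panel, npc_tables
    ):
        """Default m = SNPs with any variant allele observed (29 of 45)."""
        informative = sum(1 for t in npc_tables if t.b + t.d > 0)
        assert informative == 29
        default = fs.associate_tables(npc_panel, npc_tables)
        explicit = fs.associate_tables(npc_panel, npc_tables, bonferroni_m=29)
        assert [r.significant_bonferroni for r in default] == [
            r.significant_bonferroni for r in explicit
        ]

    def test_bonferroni_implies_nominal(self, npc_results):
        for r in npc_results:
            if r.significant_bonferroni:
                assert r.significant_nominal

    def test_wald_ci_consistency(self, npc_results):
        """Woolf CI excludes 1 iff the Wald z-test on ln OR has p < 0.05."""
        for r in npc_results:
            if r.effect_type != "OR":
                continue
            t = r.table
            se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
            z = math.log(r.effect) / se
            wald_p = 2 * stats.norm.sf(abs(z))
            assert (r.ci_low > 1 or r.ci_high < 1) == (wald_p < 0.05)

    def test_degenerate_snp_does_not_abort_panel(self, toy_panel):
        tables = [AlleleTable(0, 0, 0, 0), AlleleTable(30, 10, 60, 40)]
        results = fs.associate_tables(toy_panel, tables)
        assert results[0].effect_type == "undefined"
        assert results[1].effect_type == "OR"
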