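"""The PAF formulas, pooling conventions, and the full study orchestration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attribkit.data_model import BurdenCounts, PAFEstimate, RoundingPolicy, Sex
from attribkit.paf_core import (
    attributable_counts,
    combine_pafs,
    levin_paf,
    multi_level_paf,
    pool_regions,
    pool_sexes,
    run_study,
    table_from_reported_pafs,
)
from conftest import estimate

BURDEN = BurdenCounts(
    deaths={Sex.male: 79_000, Sex.female: 60_000},
    incidence={Sex.male: 147_000, Sex.female: 107_000},
)


class TestLevin:
    @pytest.mark.parametrize(
        "p,rr,expected",
        [
            (0.574, 1.16, 0.0841),  # smoking, men
            (0.304, 1.32, 0.0887),  # physical inactivity, men
            (0.396, 1.24, 0.0868),  # alcohol, men
            (0.368, 1.27, 0.0904),  # physical inactivity, women
        ],
    )
    def test_published_binary_cells(self, p, rr, expected):
        assert levin_paf(p, rr) == pytest.approx(expected, abs=5e-5)

    def test_null_effect_is_zero(self):
        for p in (0.0, 0.3, 1.0):
            assert levin_paf(p, 1.0) == 0.0

    def test_protective_rr_gives_negative_paf(self):
        assert levin_paf(0.5, 0.8) < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            levin_paf(1.2, 1.1)
        with pytest.raises(ValueError):
            levin_paf(0.5, 0.0)


class TestMultiLevel:
    def test_overweight_obesity_women(self):
        paf = multi_level_paf([(0.1697, 1.25), (0.0341, 1.57)])
        assert paf == pytest.approx(0.0583, abs=5e-5)

    def test_vegetable_urban_women_quintiles(self):
        paf = multi_level_paf([(0.2, rr) for rr in (1.46, 1.27, 1.18, 1.10, 1.00)])
        assert paf == pytest.approx(0.168, abs=5e-4)

    def test_all_unit_rrs_give_zero(self):
        assert multi_level_paf([(0.2, 1.0)] * 5) == 0.0

    def test_prevalence_sum_above_one_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            multi_level_paf([(0.7, 1.2), (0.6, 1.3)])

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0), rr=st.floats(0.1, 5.0))
    def test_reduces_to_levin_for_single_level(self, p, rr):
        assert multi_level_paf([(p, rr)]) == levin_paf(p, rr)

    @settings(derandomize=True, max_examples=100)
    @given(
        ps=st.lists(st.floats(0.01, 0.19), min_size=2, max_size=5),
        rrs=st.lists(st.floats(1.0, 3.0), min_size=5, max_size=5),
        r0=st.floats(0.001, 0.05),
    )
    def test_expected_case_oracle_equivalence(self, ps, rrs, r0):
        """(E_obs - E_ref)/E_obs with E_obs = sum p_i r0 RR_i equals the formula
        to 1e-12 — the counterfactual-cohort identity behind the full shift."""
        ps = ps[: len(rrs)]
        ps.append(1.0 - sum(ps))  # reference level
        rrs = rrs[: len(ps) - 1] + [1.0]
        e_obs = sum(p * r0 * rr for p, rr in zip(ps, rrs))
        e_ref = r0
        oracle = (e_obs - e_ref) / e_obs
        assert multi_level_paf(list(zip(ps, rrs))) == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(p=st.floats(0.05, 0.6), rr=st.floats(1.05, 3.0), dp=st.floats(0.01, 0.1),
           drr=st.floats(0.01, 0.5))
    def test_strictly_increasing_in_p_and_rr(self, p, rr, dp, drr):
        base = levin_paf(p, rr)
        assert levin_paf(min(p + dp, 1.0), rr) > base
        assert levin_paf(p, rr + drr) > base


class TestCombine:
    def test_published_male_combination(self):
        pafs = [0.084, 0.087, 0.049, 0.089, 0.188, 0.062, 0.091]
        assert round(100 * combine_pafs(pafs), 1) == 49.8

    def test_identity_and_closed_form(self):
        assert combine_pafs([0.3]) == pytest.approx(0.3)
        assert combine_pafs([0.5, 0.5]) == pytest.approx(0.75)

    def test_paf_at_or_above_one_rejected(self):
        with pytest.raises(ValueError):
            combine_pafs([0.5, 1.0])

    @settings(derandomize=True, max_examples=100)
    @given(pafs=st.lists(st.floats(0.0, 0.9), min_size=1, max_size=8))
    def test_bounds_order_invariance_and_log_identity(self, pafs):
        c = combine_pafs(pafs)
        assert c <= sum(pafs) + 1e-12
        assert c >= max(pafs) - 1e-12
        assert combine_pafs(reversed(pafs)) == pytest.approx(c, abs=1e-12)
        log_form = 1.0 - math.exp(sum(math.log(1.0 - x) for x in pafs))
        assert c == pytest.approx(log_form, abs=1e-12)


class TestPooling:
    def test_fruit_men_region_pooling(self):
        urban = multi_level_paf([(0.2, rr) for rr in (1.12, 1.09, 1.06, 1.04, 1.00)])
        rural = multi_level_paf([(0.2, rr) for rr in (1.12, 1.09, 1.07, 1.06, 1.00)])
        pooled = pool_regions(urban, rural, 1 / 3)
        assert pooled == pytest.approx(0.0619, abs=5e-5)

    def test_meat_men_region_pooling(self):
        urban = multi_level_paf([(0.2, rr) for rr in (1.07, 1.12, 1.17, 1.27)])
        rural = multi_level_paf([(0.2, rr) for rr in (1.04, 1.08, 1.12, 1.20)])
        assert urban == pytest.approx(0.1119, abs=5e-5)
        assert pool_regions(urban, rural, 1 / 3) == pytest.approx(0.0912, abs=5e-5)

    def test_equal_pafs_invariant_under_weight(self):
        for w in (0.0, 0.25, 1.0):
            assert pool_regions(0.12, 0.12, w) == pytest.approx(0.12)

    def test_pool_sexes_smoking_total(self):
        male = PAFEstimate(factor="smoking", stratum="male", paf=0.0841,
                           ci=(0.049, 0.121), attributable_deaths=6636,
                           attributable_cases=12348)
        female = PAFEstimate(factor="smoking", stratum="female", paf=0.0041,
                             ci=(0.002, 0.006), attributable_deaths=240,
                             attributable_cases=428)
        total = pool_sexes(male, female, BURDEN)
        assert total.attributable_deaths == 6876
        assert total.attributable_cases == 12776
        assert total.paf_pct == 4.9
        assert min(male.paf, female.paf) <= total.paf <= max(male.paf, female.paf)

    def test_pool_sexes_factor_mismatch(self):
        a = PAFEstimate(factor="a", stratum="male", paf=0.1, ci=(0.1, 0.1),
                        attributable_deaths=0, attributable_cases=0)
        b = PAFEstimate(factor="b", stratum="female", paf=0.1, ci=(0.1, 0.1),
                        attributable_deaths=0, attributable_cases=0)
        with pytest.raises(ValueError, match="mismatch"):
            pool_sexes(a, b, BURDEN)


class TestAttributableCounts:
    def test_rounding_before_multiplication_reproduces_published_counts(self):
        # 0.08412 rounds to 0.084; 79,000 x 0.084 = 6,636 (unrounded would give 6,646)
        assert attributable_counts(0.08412, 79_000) == 6636
        assert attributable_counts(0.498, 147_000) == 73_206

    def test_zero_paf(self):
        assert attributable_counts(0.0, 139_000) == 0

    def test_full_precision_policy(self):
        policy = RoundingPolicy(enabled=False)
        assert attributable_counts(0.08412, 79_000, policy) == 6645  # 6645.48 rounds down

    def test_half_up_tie(self):
        # 0.5 * 1000 = 500 exactly at a tie when paf*counts ends in .5
        assert attributable_counts(0.0845, 1000) == 85  # rounds to 0.085 first


class TestRunStudy:
    def test_published_per_sex_cells(self, china_estimates):
        cells = {
            ("tobacco_smoking", "male"): (8.4, 6636, 12348),
            ("tobacco_smoking", "female"): (0.4, 240, 428),
            ("alcohol_drinking", "male"): (8.7, 6873, 12789),
            ("overweight_obesity", "male"): (4.9, 3871, 7203),
            ("overweight_obesity", "female"): (5.8, 3480, 6206),
            ("physical_inactivity", "male"): (8.9, 7031, 13083),
            ("physical_inactivity", "female"): (9.0, 5400, 9630),
            ("low_fruit_intake", "male"): (6.2, 4898, 9114),
            ("high_red_processed_meat", "male"): (9.1, 7189, 13377),
            ("high_red_processed_meat", "female"): (7.9, 4740, 8453),
        }
        for (factor, stratum), (pct, deaths, cases) in cells.items():
            est = estimate(china_estimates, factor, stratum)
            assert est.paf_pct == pct, (factor, stratum)
            assert est.attributable_deaths == deaths
            assert est.attributable_cases == cases

    def test_published_total_rows(self, china_estimates):
        totals = {
            "tobacco_smoking": (4.9, 6876, 12776),
            "alcohol_drinking": (5.4, 7533, 13966),
            "overweight_obesity": (5.3, 7351, 13409),
            "physical_inactivity": (8.9, 12431, 22713),
            "high_red_processed_meat": (8.6, 11929, 21830),
        }
        for factor, (pct, deaths, cases) in totals.items():
            est = estimate(china_estimates, factor, "total")
            assert est.paf_pct == pct
            assert est.attributable_deaths == deaths
            assert est.attributable_cases == cases

    def test_documented_nonreproducing_dietary_cells(self, china_estimates):
        """Three published dietary cells cannot be recovered from the printed
        quintile RRs with 20% prevalences and urban weight 1/3; the honest
        recomputation lands nearby but not on the printed value."""
        veg_m = estimate(china_estimates, "low_vegetable_intake", "male")
        assert veg_m.paf_pct == 18.5  # published: 18.8
        veg_f = estimate(china_estimates, "low_vegetable_intake", "female")
        assert veg_f.paf_pct == 16.9  # published: 16.8
        fruit_f = estimate(china_estimates, "low_fruit_intake", "female")
        assert fruit_f.paf_pct == 8.1  # published: 6.7

    def test_combined_rows_consistent_with_factor_rows(self, china_estimates):
        male = estimate(china_estimates, "combined", "male")
        factor_pafs = [
            round(estimate(china_estimates, f, "male").paf, 10)
            for f in ("tobacco_smoking", "alcohol_drinking", "overweight_obesity",
                      "physical_inactivity", "low_vegetable_intake",
                      "low_fruit_intake", "high_red_processed_meat")
        ]
        rounded = [round(p, 3) for p in factor_pafs]
        assert male.paf == pytest.approx(combine_pafs(rounded), abs=1e-12)
        total = estimate(china_estimates, "combined", "total")
        m, f = male, estimate(china_estimates, "combined", "female")
        assert total.attributable_deaths == m.attributable_deaths + f.attributable_deaths
        assert total.attributable_cases == m.attributable_cases + f.attributable_cases
        # combined burden lands within half a point of the published 45.5%
        assert total.paf_pct == pytest.approx(45.5, abs=0.5)

    def test_all_unit_rrs_give_all_zero(self, china):
        flat = china.model_copy(deep=True)
        for factor in flat.factors:
            for levels in factor.levels.values():
                for lv in levels:
                    lv.rr = 1.0
                    lv.rr_ci = (1.0, 1.0)
        ests = run_study(flat)
        assert all(e.paf == 0.0 for e in ests)
        assert all(e.attributable_deaths == 0 for e in ests)

    def test_negative_paf_rejected_with_clear_error(self, china):
        bad = china.model_copy(deep=True)
        lv = bad.factor("tobacco_smoking").levels[
            next(iter(bad.factor("tobacco_smoking").levels))
        ][0]
        lv.rr = 0.8
        lv.rr_ci = (0.7, 0.9)
        with pytest.raises(ValueError, match="negative PAF"):
            run_study(bad)

    def test_all_cis_contain_their_point(self, china_estimates):
        for est in china_estimates:
            assert est.ci[0] <= est.paf <= est.ci[1]


class TestReportedPafRoute:
    def test_published_headline_numbers(self, reported, china):
        """Applying the combination and pooling arithmetic to the published
        per-sex PAF column reproduces every headline burden number."""
        tab = table_from_reported_pafs(reported, china.burden).set_index("factor")
        comb = tab.loc["combined"]
        assert round(100 * comb["male_paf"], 1) == 49.8
        assert round(100 * comb["female_paf"], 1) == 39.6
        assert round(100 * comb["total_paf"], 1) == 45.5
        assert comb["total_deaths"] == 63_102
        assert comb["total_cases"] == 115_578
        assert round(100 * tab.loc["alcohol_drinking", "total_paf"], 1) == 5.4
        assert tab.loc["low_vegetable_intake", "total_deaths"] == 24_932
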