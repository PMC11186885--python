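"""Availability analytics: by-year curves, measure/region overlap counts,
the era-split conditional neocortex test, and follow-up/autopsy models."""

import numpy as np
import pandas as pd
import pytest

from tdpengine.availability import (
    availability_by_year,
    conditional_neocortex_availability,
    followup_autopsy_models,
    measure_venn,
    region_venn,
)
from tdpengine.simulate import (
    GeneratorConfig,
    InactivePopulationConfig,
    apply_missingness,
    generate_cohort,
    generate_inactive_population,
)
from tdpengine.stats import ContractError

from .conftest import make_record


def _clin(year=2020, dx="Alzheimer's disease"):
    return {"year_of_death": year, "etiologic_dx_raw": dx}


class TestAvailabilityByYear:
    def test_nine_of_ten_hippocampus(self):
        cohort = [make_record(hippocampus="absent",
                              clinical_kw=_clin()) for _ in range(9)]
        cohort.append(make_record(hippocampus="na", clinical_kw=_clin()))
        df = availability_by_year(cohort)
        row = df[(df.measure == "hippocampus") & (df.year == 2020)].iloc[0]
        assert row.proportion == pytest.approx(0.90)

    def test_all_assessed_gives_one(self):
        cohort = [make_record(spinal="absent", clinical_kw=_clin(2018))
                  for _ in range(5)]
        df = availability_by_year(cohort)
        assert (df.proportion == 1.0).all()

    def test_empty_cohort(self):
        assert availability_by_year([]).empty

    def test_order_invariance(self):
        cohort = [make_record(hippocampus="na" if i % 3 else "present",
                              clinical_kw=_clin(2015 + i % 4))
                  for i in range(40)]
        a = availability_by_year(cohort)
        b = availability_by_year(list(reversed(cohort)))
        pd.testing.assert_frame_equal(a, b)

    def test_rising_generator_trend_recovered(self):
        """With a rising logistic availability trend, yearly assessed
        fractions track the configured curve within sampling error."""
        cfg = GeneratorConfig(n=6000, n_centers=10, seed=21)
        cfg.missingness.center_sd = 0.0
        cfg.missingness.p_skip_neocortex_if_hipp_negative = 0.0
        cfg.missingness.p_no_stain = 0.0
        cohort, truth = generate_cohort(cfg)
        obs = apply_missingness(cohort, truth, cfg)
        df = availability_by_year(obs)
        sub = df[df.measure == "hippocampus"].set_index("year")
        base = cfg.missingness.base["hippocampus"]
        slope = cfg.missingness.slope["hippocampus"]
        for year, row in sub.iterrows():
            expect = 1 / (1 + np.exp(-(np.log(base / (1 - base))
                                       + slope * (year - 2014))))
            se = np.sqrt(expect * (1 - expect) / row.denominator)
            assert abs(row.proportion - expect) < 4 * se + 1e-9


class TestMeasureVenn:
    def test_published_availability_pattern_counts(self):
        cohort = []
        # all four measures available
        cohort += [make_record() for _ in range(30)]
        # ALS + HS-A only
        cohort += [make_record(amygdala="na", hippocampus="na", ec_itc="na",
                               neocortex="na", ftld_tdp="na")
                   for _ in range(15)]
        # only missing a regional assessment
        cohort += [make_record(amygdala="na", hippocampus="na", ec_itc="na",
                               neocortex="na") for _ in range(6)]
        # only missing the ALS assessment
        cohort += [make_record(mn_inclusion="not_assessed")
                   for _ in range(5)]
        vc = measure_venn(cohort)
        assert vc.count("regional_any", "ftld_tdp", "als", "hs_a") == 30
        assert vc.count("als", "hs_a") == 15
        assert vc.count("ftld_tdp", "als", "hs_a") == 6
        assert vc.count("regional_any", "ftld_tdp", "hs_a") == 5
        assert vc.total == 56

    def test_single_record(self):
        vc = measure_venn([make_record()])
        assert vc.intersection_all() == 1 and vc.total == 1

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        tri = ("present", "absent", "na")
        cohort = []
        patterns = []
        for _ in range(1000):
            kw = {k: tri[rng.integers(3)]
                  for k in ("amygdala", "hippocampus", "ec_itc",
                            "neocortex", "ftld_tdp")}
            mn = ("tdp43", "none", "not_assessed")[rng.integers(3)]
            hs = ("absent", "unilateral", "na")[rng.integers(3)]
            cohort.append(make_record(mn_inclusion=mn, hs_a=hs, **kw))
            patterns.append((
                any(kw[r] != "na" for r in
                    ("amygdala", "hippocampus", "ec_itc", "neocortex")),
                kw["ftld_tdp"] != "na", mn != "not_assessed", hs != "na"))
        vc = measure_venn(cohort)
        from collections import Counter
        expected = Counter(p for p in patterns if any(p))
        assert dict(vc.counts) == dict(expected)


class TestRegionVenn:
    def test_contract_error_without_regional(self):
        with pytest.raises(ContractError):
            region_venn([make_record(amygdala="na", hippocampus="na",
                                     ec_itc="na", neocortex="na")])

    def test_staging_trio_vs_all_four(self):
        cohort = [make_record() for _ in range(4)]                 # all four
        cohort += [make_record(ec_itc="na") for _ in range(3)]     # trio only
        cohort += [make_record(amygdala="na", ec_itc="na",
                               neocortex="na") for _ in range(2)]  # hipp only
        vc = region_venn(cohort)
        assert vc.extras["all_four"] == 4
        assert vc.extras["staging_trio"] == 7
        assert vc.total == 9

    def test_brute_force_recount(self):
        rng = np.random.default_rng(4)
        cohort = []
        for _ in range(300):
            kw = {k: ("present", "absent", "na")[rng.integers(3)]
                  for k in ("amygdala", "hippocampus", "ec_itc", "neocortex")}
            if all(v == "na" for v in kw.values()):
                kw["hippocampus"] = "absent"
            cohort.append(make_record(**kw))
        vc = region_venn(cohort)
        assert vc.n_in_any() == 300
        assert sum(vc.counts.values()) == vc.total


class TestConditionalNeocortex:
    def test_published_post_era_proportions(self):
        cohort = []
        # post 2019, hippocampus TDP-negative: 393/469 have neocortex assessed
        cohort += [make_record(hippocampus="absent",
                               neocortex="absent" if i < 393 else "na",
                               clinical_kw=_clin(2020)) for i in range(469)]
        # hippocampus TDP-positive: 241/256
        cohort += [make_record(hippocampus="present",
                               neocortex="absent" if i < 241 else "na",
                               clinical_kw=_clin(2020)) for i in range(256)]
        eras = conditional_neocortex_availability(cohort, split_year=2019)
        post = eras["post"]
        assert post.prop_hipp_negative == pytest.approx(393 / 469)
        assert post.prop_hipp_positive == pytest.approx(241 / 256)
        assert post.p_value < 0.001

    def test_identical_proportions_null(self):
        cohort = []
        for hipp in ("absent", "present"):
            cohort += [make_record(hippocampus=hipp,
                                   neocortex="absent" if i < 8 else "na",
                                   clinical_kw=_clin(2017))
                       for i in range(10)]
        eras = conditional_neocortex_availability(cohort)
        assert eras["pre"].chi2 == pytest.approx(0.0)
        assert eras["pre"].p_value == pytest.approx(1.0)

    def test_empty_stratum_reported_undefined(self):
        cohort = [make_record(hippocampus="absent", clinical_kw=_clin(2015))]
        eras = conditional_neocortex_availability(cohort)
        assert np.isnan(eras["pre"].prop_hipp_positive)
        assert np.isnan(eras["pre"].p_value)

    def test_non_ad_diagnoses_excluded(self):
        cohort = [make_record(hippocampus="present",
                              clinical_kw=_clin(2020, "FTLD Other"))]
        eras = conditional_neocortex_availability(cohort)
        assert eras["post"].table.sum() == 0


class TestFollowupAutopsyModels:
    def test_null_effects_or_near_one(self):
        cfg = InactivePopulationConfig(
            n=4000, n_centers=6, seed=5,
            followup_or={k: 1.0 for k in
                         ("FTLD", "CBD_PSP", "LB", "VASCULAR",
                          "OTHER_IMPAIRED", "NOT_IMPAIRED", "UNAVAILABLE")},
            autopsy_or={k: 1.0 for k in
                        ("FTLD", "CBD_PSP", "LB", "VASCULAR",
                         "OTHER_IMPAIRED", "NOT_IMPAIRED", "UNAVAILABLE")},
            center_sd=0.0)
        pop = generate_inactive_population(cfg)
        out = followup_autopsy_models(pop, multilevel=False)
        for r in out["followup"]["single_level"]:
            assert r.odds_ratio == pytest.approx(1.0, abs=0.45)

    def test_degenerate_category_non_estimable(self):
        pop = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(40)],
            "center_id": ["C1"] * 40,
            "dx_category": ["AD"] * 20 + ["FTLD"] * 20,
            "deceased": [True] * 10 + [False] * 10 + [True] * 20,
            "autopsied": [True] * 10 + [False] * 10 + [True] * 20,
        })
        out = followup_autopsy_models(pop, multilevel=False)
        (r,) = out["followup"]["single_level"]
        assert not r.estimable
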