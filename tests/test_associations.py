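"""Association analytics: group summary tables, adjusted and multilevel
regressions, category contrasts, pattern counts, and overlap tabulations."""

import numpy as np
import pytest

from tdpengine.associations import (
    adjusted_logistic,
    build_design,
    category_contrasts,
    multilevel_logistic,
    overlap_proportions,
    regional_pattern_counts,
    summarize_by_category,
)
from tdpengine.classify import Category, classify_cohort
from tdpengine.records import complete_case_filter
from tdpengine.simulate import GeneratorConfig, generate_cohort
from tdpengine.stats import two_by_two

from .conftest import make_record


def _mini_cohort():
    """Complete-case cohort with all four categories represented."""
    cohort = []
    for i in range(30):
        cohort.append(make_record(clinical_kw={
            "age_at_death": 75 + i % 10, "education": 12.0 + i % 7,
            "sex": "male" if i % 2 else "female",
            "interval_visit_death": 0.5 + (i % 5) * 0.8,
            "cognitive_status": "dementia" if i % 3 else "normal"}))
    for i in range(20):
        cohort.append(make_record(
            amygdala="present", hippocampus="present",
            clinical_kw={"age_at_death": 84 + i % 6, "education": 12.0 + i % 6,
                         "sex": "male" if i % 2 else "female",
                         "interval_visit_death": 0.4 + (i % 4) * 0.9,
                         "cognitive_status": "dementia" if i % 4
                         else "normal"}))
    for i in range(15):
        cohort.append(make_record(
            ftld_tdp="present", amygdala="present", hippocampus="present",
            ec_itc="present", neocortex="present",
            clinical_kw={"age_at_death": 65 + i % 12, "education": 13.0 + i % 5,
                         "sex": "male" if i % 2 else "female",
                         "interval_visit_death": 0.3 + (i % 3) * 1.1,
                         "cognitive_status": "dementia" if i % 3
                         else "normal"}))
    for i in range(5):
        cohort.append(make_record(
            amygdala="present", path_kw={"cbd": True},
            clinical_kw={"age_at_death": 78.0 + i, "education": 12.0 + i,
                         "sex": "male" if i % 2 else "female",
                         "interval_visit_death": 0.5 + i * 0.6,
                         "cognitive_status": "dementia" if i % 2
                         else "normal"}))
    return cohort, classify_cohort(cohort)


class TestSummaryTable:
    def test_group_sizes_and_cells(self):
        cohort, assignments = _mini_cohort()
        st = summarize_by_category(cohort, assignments)
        assert st.group_sizes == {"no_tdp43": 30, "other_tdp43": 5,
                                  "late_nc": 20, "als_ftld_tdp": 15}
        cells = st.cells
        age = cells[(cells.variable == "age_at_death")
                    & (cells.category == "late_nc")].iloc[0]
        assert age.n == 20 and 84 <= age["mean"] <= 90

    def test_categorical_percentages_sum_to_100(self):
        cohort, assignments = _mini_cohort()
        st = summarize_by_category(cohort, assignments)
        cells = st.cells[st.cells.variable == "cognitive_status"]
        for cat, grp in cells.groupby("category"):
            if grp.n.sum():
                assert grp.pct.sum() == pytest.approx(100.0)

    def test_identical_groups_rank_sum_p_one(self):
        cohort, assignments = _mini_cohort()
        for rec in cohort:
            rec.clinical.age_at_death = 80.0
        st = summarize_by_category(cohort, assignments)
        t = st.tests[(st.tests.variable == "age_at_death")]
        assert (t.p_value == 1.0).all()

    def test_empty_category_comparisons_skipped(self):
        cohort = [make_record(clinical_kw={"age_at_death": 80.0})
                  for _ in range(6)]
        st = summarize_by_category(cohort, classify_cohort(cohort))
        t = st.tests[st.tests.variable == "age_at_death"]
        assert t.p_value.isna().all()


class TestAdjustedLogistic:
    def test_unadjusted_reduces_to_two_by_two(self):
        """With no covariates, the category coefficient reproduces the
        cross-product odds ratio exactly."""
        cohort, assignments = _mini_cohort()
        _, results = adjusted_logistic(cohort, assignments, "dementia",
                                       adjusted=False)
        late = next(r for r in results
                    if r.comparison.startswith("late_nc"))
        dem = {c: [0, 0] for c in ("no_tdp43", "late_nc")}
        for rec, a in zip(cohort, assignments):
            if a.category.value in dem:
                dem[a.category.value][
                    0 if rec.clinical.cognitive_status.value == "dementia"
                    else 1] += 1
        tt = two_by_two([dem["late_nc"], dem["no_tdp43"]])
        assert late.odds_ratio == pytest.approx(tt.odds_ratio, rel=1e-6)

    def test_complete_case_bookkeeping(self):
        cohort, assignments = _mini_cohort()
        cohort[0].clinical.education = float("nan")
        X, y, _, n_missing = build_design(cohort, assignments, "dementia")
        assert len(y) + n_missing == len(cohort)

    def test_reference_switch_leaves_contrasts_invariant(self):
        cohort, assignments = _mini_cohort()
        fit1, _ = adjusted_logistic(cohort, assignments, "dementia")
        fit2, _ = adjusted_logistic(cohort, assignments, "dementia",
                                    reference=Category.ALS_FTLD_TDP)
        c1 = {c.comparison: c for c in category_contrasts(fit1)}
        # late vs other appears in both parameterizations
        c2 = {c.comparison: c for c in category_contrasts(fit2)}
        key = "cat_late_nc vs cat_other_tdp43"
        assert c1[key].p_value == pytest.approx(c2[key].p_value, abs=1e-8)
        assert c1[key].estimate == pytest.approx(c2[key].estimate, abs=1e-8)


class TestMultilevel:
    def test_single_center_degenerates(self):
        cohort, assignments = _mini_cohort()       # all records center C001
        mfit, _ = multilevel_logistic(cohort, assignments, "dementia",
                                      adjusted=False)
        sfit, _ = adjusted_logistic(cohort, assignments, "dementia",
                                    adjusted=False)
        assert np.allclose(mfit.params, sfit.params, atol=1e-8)
        assert "single-level" in mfit.note


class TestPatternCounts:
    def test_single_late_record(self):
        cohort = [make_record(amygdala="present")]
        assignments = classify_cohort(cohort)
        vc = regional_pattern_counts(cohort, assignments, Category.LATE_NC)
        assert vc.count("amygdala") == 1 and vc.total == 1

    def test_recount_oracle_on_generated_cohort(self):
        cfg = GeneratorConfig(n=800, n_centers=5, seed=13)
        cohort, truth = generate_cohort(cfg)
        complete = complete_case_filter(cohort)
        assignments = classify_cohort(complete)
        vc = regional_pattern_counts(complete, assignments, Category.LATE_NC)
        n_late_with_regions = sum(
            1 for a in assignments if a.category is Category.LATE_NC)
        assert vc.n_in_any() == n_late_with_regions   # LATE always has regions
        assert sum(vc.counts.values()) == vc.total


class TestOverlap:
    def test_triple_overlap_membership(self):
        rec = make_record(amygdala="present", hippocampus="present",
                          path_kw={"adnc": "high", "lewy_any": "present"})
        assignments = classify_cohort([rec])
        vc = overlap_proportions([rec], assignments)
        assert vc.count("late_nc", "adnc", "lewy") == 1

    def test_spectrum_and_late_disjoint(self):
        cfg = GeneratorConfig(n=600, n_centers=4, seed=17)
        cohort, _ = generate_cohort(cfg)
        assignments = classify_cohort(cohort)
        vc = overlap_proportions(cohort, assignments)
        for pat, c in vc.counts.items():
            both = pat[vc.set_labels.index("als_ftld_tdp")] and \
                pat[vc.set_labels.index("late_nc")]
            assert not both

    def test_exclusions(self):
        other = make_record(amygdala="present", path_kw={"cbd": True})
        missing_adnc = make_record(path_kw={"lewy_any": "present"})
        keep = make_record(path_kw={"adnc": "low", "lewy_any": "present"})
        cohort = [other, missing_adnc, keep]
        vc = overlap_proportions(cohort, classify_cohort(cohort))
        assert vc.total == 1
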