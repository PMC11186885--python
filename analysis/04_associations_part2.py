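#!/usr/bin/env python
"""Part II: complete-case association analytics.

Group summary table with rank-sum / chi-square comparisons, adjusted and
multilevel logistic regressions of each clinical / neuropathological
outcome on TDP-43 category with post-hoc contrasts, regional presence
pattern tables per category, and the ADNC / Lewy-body overlap tabulation.

Run:  python analysis/04_associations_part2.py
"""

import argparse
import math
import os

import pandas as pd

from tdpengine import associations as assoc
from tdpengine.classify import Category, classify_cohort
from tdpengine.io import parse_records
from tdpengine.records import complete_case_filter

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", default="results/cohort.csv")
ap.add_argument("--out", default="results")
ap.add_argument("--no-multilevel", action="store_true")
args = ap.parse_args()

cohort = parse_records(args.cohort)
complete = complete_case_filter(cohort)
assignments = classify_cohort(complete)
print(f"{len(complete)} complete cases")

summary = assoc.summarize_by_category(complete, assignments)
summary.cells.to_csv(os.path.join(args.out, "summary_cells.csv"),
                     index=False)
summary.tests.to_csv(os.path.join(args.out, "summary_tests.csv"),
                     index=False)

rows = []
for outcome in assoc.OUTCOMES:
    fits = {"single_level": assoc.adjusted_logistic(
        complete, assignments, outcome)}
    if not args.no_multilevel:
        fits["multilevel"] = assoc.multilevel_logistic(
            complete, assignments, outcome)
    for model, (fit, results) in fits.items():
        for r in results:
            rows.append({"outcome": outcome, "model": model,
                         "comparison": r.comparison,
                         "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "p_value": r.p_value,
                         "n_used": r.n_used, "estimable": r.estimable})
        for c in assoc.category_contrasts(fit, outcome=outcome):
            rows.append({"outcome": outcome, "model": model + "_contrast",
                         "comparison": c.comparison,
                         "odds_ratio": math.exp(c.estimate)
                         if c.estimable else math.nan,
                         "ci_low": math.nan, "ci_high": math.nan,
                         "p_value": c.p_value, "n_used": fit.n_used,
                         "estimable": c.estimable})
ors = pd.DataFrame(rows)
ors.to_csv(os.path.join(args.out, "odds_ratios.csv"), index=False)

print("\nadjusted ORs vs no TDP-43 (single level):")
head = ors[(ors.model == "single_level") & ors.estimable]
for outcome in ("dementia", "clinical_ad", "ppa", "bvftd", "hs_a", "adnc",
                "lewy"):
    sub = head[head.outcome == outcome]
    pieces = [f"{r.comparison.split(' vs ')[0]} {r.odds_ratio:.1f}"
              for r in sub.itertuples()]
    print(f"  {outcome}: " + ", ".join(pieces))

for cat in (Category.ALS_FTLD_TDP, Category.LATE_NC, Category.OTHER_TDP43):
    vc = assoc.regional_pattern_counts(complete, assignments, cat)
    vc.to_frame().to_csv(
        os.path.join(args.out, f"regional_patterns_{cat.value}.csv"),
        index=False)
    if vc.n_in_any():
        share = vc.intersection_all() / vc.n_in_any()
        print(f"{cat.value}: all-four-region share {share:.0%} "
              f"(of {vc.n_in_any()} with any regional TDP-43)")

overlap = assoc.overlap_proportions(complete, assignments)
overlap.to_frame().to_csv(os.path.join(args.out, "pathology_overlap.csv"),
                          index=False)
print(f"overlap tabulation over {overlap.total} records "
      f"(excluding other-TDP-43 and missing ADNC/LB)")
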