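#!/usr/bin/env python
"""Complete-case filtering and TDP-43 category / stage assignment.

Reads results/cohort.csv (from 01_simulate_cohort.py or any cohort in the
coded dialect), applies the complete-case filter, assigns categories, and
writes the per-participant assignment table plus rule traces.  When truth
labels are present it also reports the round-trip agreement.

Run:  python analysis/02_classify_cohort.py
"""

import argparse
import json
import os

import pandas as pd

from tdpengine.classify import assignments_to_frame, classify_cohort
from tdpengine.io import parse_records
from tdpengine.records import complete_case_filter

ap = argparse.ArgumentParser()
ap.add_argument("--cohort", default="results/cohort.csv")
ap.add_argument("--out", default="results")
args = ap.parse_args()

cohort = parse_records(args.cohort)
complete = complete_case_filter(cohort)
assignments = classify_cohort(complete)
af = assignments_to_frame(assignments)
af.to_csv(os.path.join(args.out, "assignments.csv"), index=False)
with open(os.path.join(args.out, "rule_traces.json"), "w") as fh:
    json.dump({a.participant_id: a.trace for a in assignments}, fh, indent=1)

n, nc = len(cohort), len(complete)
print(f"{n} records in; {nc} complete cases ({100 * nc / n:.0f}%)")
print(af.category.value_counts().to_string())
spectrum = af[af.category == "als_ftld_tdp"]
if len(spectrum):
    print("ALS/FTLD-TDP subtypes:")
    print(spectrum.subtype.value_counts().to_string())
late = af[af.category == "late_nc"]
if len(late):
    print("LATE-NC stages:")
    print(late.stage.value_counts().sort_index().to_string())

truth_path = os.path.join(os.path.dirname(args.cohort), "truth_labels.csv")
if os.path.exists(truth_path):
    lab = pd.read_csv(truth_path).set_index("participant_id")
    merged = af.join(lab, on="participant_id", rsuffix="_truth")
    agree = (merged.category == merged.category_truth).mean()
    print(f"agreement with generator truth: {agree:.1%}")
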