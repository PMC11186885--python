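"""End-to-end orchestration: parse or generate, filter, classify, analyze.

The pipeline mirrors the two-part structure of a registry audit: Part I
(availability analytics on the full cohort) and Part II (complete-case
classification and association analytics).  Every stage count is written
to a JSON-lines run log so records in = records classified + records
excluded, with named exclusion reasons.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import associations as assoc
from . import availability as avail
from .classify import (
    Category,
    CategoryAssignment,
    Subtype,
    assignments_to_frame,
    classify_cohort,
)
from .dialect import Dialect, load_dialect
from .io import parse_records, validation_report, write_records
from .records import ParticipantRecord, complete_case_filter
from .simulate import (
    GeneratorConfig,
    apply_missingness,
    dump_config,
    generate_cohort,
)


def pct(numerator: float, denominator: float) -> int:
    """Whole-percent rounding, half up — report parity with printed tables."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def fmt_or(value: float) -> str:
    """Odds ratios rendered to one decimal."""
    return f"{value:.1f}"


@dataclass
class PipelineConfig:
    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    dialect_path: str | None = None
    out_dir: str = "results"
    part1: bool = True
    part2: bool = True
    multilevel: bool = True
    split_year: int = 2019
    seed: int | None = None

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_csv or generator must be supplied")


@dataclass
class PipelineBundle:
    """In-memory artifact bundle; files are written under ``out_dir``."""

    out_dir: str
    n_input: int = 0
    n_complete: int = 0
    category_counts: dict[str, int] = field(default_factory=dict)
    subtype_counts: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[int, int] = field(default_factory=dict)
    assignments: list[CategoryAssignment] = field(default_factory=list)
    summary: assoc.SummaryTable | None = None
    or_table: pd.DataFrame | None = None
    availability_by_year: pd.DataFrame | None = None
    measure_venn: avail.VennCounts | None = None
    region_venn: avail.VennCounts | None = None
    era_tables: dict[str, avail.EraTable] | None = None
    overlap: avail.VennCounts | None = None
    pattern_venns: dict[str, avail.VennCounts] = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)


def _write(bundle: PipelineBundle, name: str, frame: pd.DataFrame) -> None:
    path = os.path.join(bundle.out_dir, name)
    frame.to_csv(path, index=False)
    bundle.manifest[name] = "complete"


def _log(bundle: PipelineBundle, stage: str, **counts) -> None:
    entry = {"stage": stage, **counts}
    bundle.log.append(entry)


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute parse/generate -> filter -> classify -> Part I -> Part II.

    Writes tidy CSV tables, the per-participant assignment table with rule
    traces, the JSON-lines run log, and a MANIFEST marking completeness.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    bundle = PipelineBundle(out_dir=config.out_dir)

    dialect = load_dialect(config.dialect_path) if config.dialect_path \
        else Dialect()
    if config.generator is not None:
        gen = config.generator
        if config.seed is not None:
            gen.seed = config.seed
        full, truth = generate_cohort(gen)
        cohort = apply_missingness(full, truth, gen)
        write_records(cohort, os.path.join(config.out_dir, "cohort.csv"),
                      dialect)
        write_records(truth.records,
                      os.path.join(config.out_dir, "truth_records.csv"),
                      dialect)
        truth.labels.to_csv(
            os.path.join(config.out_dir, "truth_labels.csv"), index=False)
        dump_config(gen, os.path.join(config.out_dir, "generator_config.yaml"))
        bundle.manifest["cohort.csv"] = "complete"
        _log(bundle, "generate", n=len(cohort), seed=gen.seed)
    else:
        cohort = parse_records(config.input_csv, dialect)
        _log(bundle, "parse", n=len(cohort))

    bundle.n_input = len(cohort)
    report = validation_report(cohort)
    with open(os.path.join(config.out_dir, "validation.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    bundle.manifest["validation.json"] = "complete"

    if config.part1:
        bundle.availability_by_year = avail.availability_by_year(cohort)
        _write(bundle, "availability_by_year.csv",
               bundle.availability_by_year)
        bundle.measure_venn = avail.measure_venn(cohort)
        _write(bundle, "measure_venn.csv", bundle.measure_venn.to_frame())
        with_regional = [
            r for r in cohort
            if avail.availability_profile(r).has_regional_any]
        if with_regional:
            bundle.region_venn = avail.region_venn(with_regional)
            _write(bundle, "region_venn.csv", bundle.region_venn.to_frame())
        bundle.era_tables = avail.conditional_neocortex_availability(
            cohort, split_year=config.split_year)
        era_rows = []
        for era, t in bundle.era_tables.items():
            era_rows.append({
                "era": era,
                "neo_assessed_hipp_negative": int(t.table[0, 0]),
                "neo_total_hipp_negative": int(t.table[0].sum()),
                "neo_assessed_hipp_positive": int(t.table[1, 0]),
                "neo_total_hipp_positive": int(t.table[1].sum()),
                "prop_hipp_negative": t.prop_hipp_negative,
                "prop_hipp_positive": t.prop_hipp_positive,
                "chi2": t.chi2, "p_value": t.p_value,
            })
        _write(bundle, "conditional_neocortex.csv", pd.DataFrame(era_rows))
        _log(bundle, "part1", n=len(cohort),
             n_with_regional=len(with_regional))

    complete = complete_case_filter(cohort)
    bundle.n_complete = len(complete)
    _log(bundle, "complete_case_filter", n_in=len(cohort),
         n_retained=len(complete), n_excluded=len(cohort) - len(complete),
         exclusion_reason="missing TDP-43 assessment(s)")

    if config.part2 and complete:
        assignments = classify_cohort(complete)
        bundle.assignments = assignments
        af = assignments_to_frame(assignments)
        _write(bundle, "assignments.csv", af)
        with open(os.path.join(config.out_dir, "rule_traces.json"), "w") as fh:
            json.dump({a.participant_id: a.trace for a in assignments}, fh)
        bundle.manifest["rule_traces.json"] = "complete"
        bundle.category_counts = {
            c.value: int((af["category"] == c.value).sum())
            for c in assoc.CATEGORY_ORDER}
        bundle.subtype_counts = {
            s.value: int((af["subtype"] == s.value).sum())
            for s in (Subtype.FTLD_ONLY, Subtype.BOTH, Subtype.ALS_ONLY)}
        bundle.stage_counts = {
            int(s): int((af["stage"] == s).sum()) for s in (1, 2, 3)}
        _log(bundle, "classify", **bundle.category_counts)

        bundle.summary = assoc.summarize_by_category(complete, assignments)
        _write(bundle, "summary_cells.csv", bundle.summary.cells)
        _write(bundle, "summary_tests.csv", bundle.summary.tests)

        or_rows = []
        for outcome in assoc.OUTCOMES:
            fits = {}
            fit, results = assoc.adjusted_logistic(
                complete, assignments, outcome)
            fits["single_level"] = (fit, results)
            if config.multilevel:
                mfit, mresults = assoc.multilevel_logistic(
                    complete, assignments, outcome)
                fits["multilevel"] = (mfit, mresults)
            for model, (f, results) in fits.items():
                for r in results:
                    or_rows.append({
                        "outcome": outcome, "model": model,
                        "comparison": r.comparison,
                        "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                        "ci_high": r.ci_high, "p_value": r.p_value,
                        "n_used": r.n_used, "estimable": r.estimable,
                        "note": r.note})
                for c in assoc.category_contrasts(f, outcome=outcome):
                    or_rows.append({
                        "outcome": outcome, "model": model + "_contrast",
                        "comparison": c.comparison,
                        "odds_ratio": math.exp(c.estimate)
                        if c.estimable else math.nan,
                        "ci_low": math.nan, "ci_high": math.nan,
                        "p_value": c.p_value, "n_used": f.n_used,
                        "estimable": c.estimable, "note": c.note})
        bundle.or_table = pd.DataFrame(or_rows)
        _write(bundle, "odds_ratios.csv", bundle.or_table)

        for cat in (Category.ALS_FTLD_TDP, Category.LATE_NC,
                    Category.OTHER_TDP43):
            vc = assoc.regional_pattern_counts(complete, assignments, cat)
            bundle.pattern_venns[cat.value] = vc
            _write(bundle, f"regional_patterns_{cat.value}.csv",
                   vc.to_frame())
        bundle.overlap = assoc.overlap_proportions(complete, assignments)
        _write(bundle, "pathology_overlap.csv", bundle.overlap.to_frame())
        _log(bundle, "part2", n_complete=len(complete))
    elif config.part2:
        _log(bundle, "part2", skipped=True,
             reason="no record passed the complete-case filter")

    with open(os.path.join(config.out_dir, "run_log.jsonl"), "w") as fh:
        for entry in bundle.log:
            fh.write(json.dumps(entry) + "\n")
    with open(os.path.join(config.out_dir, "MANIFEST.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2)
    return bundle


def render_summary(bundle: PipelineBundle) -> str:
    """Human-readable report: flow counts, category shares, subtype shares,
    and the headline odds ratios, with whole-percent and one-decimal-OR
    rounding.  Missing bundle components render as explicit gap markers."""
    lines: list[str] = []
    lines.append("TDP-43 category pipeline report")
    lines.append("=" * 34)
    lines.append(f"records in: {bundle.n_input}")
    if bundle.n_input:
        lines.append(
            f"complete cases: {bundle.n_complete} "
            f"({pct(bundle.n_complete, bundle.n_input)}%)")
    if bundle.category_counts:
        lines.append("")
        lines.append("TDP-43 categories (of complete cases):")
        for cat, n in bundle.category_counts.items():
            lines.append(f"  {cat}: {n} ({pct(n, bundle.n_complete)}%)")
        n_spectrum = sum(bundle.subtype_counts.values())
        if n_spectrum:
            lines.append("ALS/FTLD-TDP subtypes:")
            for sub, n in bundle.subtype_counts.items():
                lines.append(f"  {sub}: {n} ({pct(n, n_spectrum)}%)")
        n_late = sum(bundle.stage_counts.values())
        if n_late:
            lines.append("LATE-NC stages:")
            for s, n in bundle.stage_counts.items():
                lines.append(f"  stage {s}: {n} ({pct(n, n_late)}%)")
    else:
        lines.append("[no classification output]")
    if bundle.or_table is not None and len(bundle.or_table):
        lines.append("")
        lines.append("adjusted odds ratios (single level):")
        sub = bundle.or_table[bundle.or_table["model"] == "single_level"]
        for _, row in sub.iterrows():
            if not row["estimable"]:
                lines.append(f"  {row['outcome']} {row['comparison']}: "
                             "non-estimable")
                continue
            lines.append(
                f"  {row['outcome']} {row['comparison']}: "
                f"OR {fmt_or(row['odds_ratio'])} "
                f"[{fmt_or(row['ci_low'])}, {fmt_or(row['ci_high'])}]")
    else:
        lines.append("[no association output]")
    return "\n".join(lines) + "\n"
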