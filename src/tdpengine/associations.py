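"""Complete-case association analytics over the TDP-43 categories.

Covers the group-comparison table (mean (SD) / n (%) with rank-sum and
chi-square tests), adjusted and multilevel logistic regressions of clinical
diagnoses and co-pathologies on TDP-43 category, Wald post-hoc contrasts
between categories, regional-presence pattern counts, and the co-occurrence
tabulation of the TDP-43 spectrum groups with ADNC and Lewy bodies.

Dichotomizations are fixed: ADNC none/low vs intermediate/high, CAA and the
vessel/atrophy scales none/mild vs moderate/severe, Lewy bodies present in
any region, dementia vs normal/MCI, clinical AD vs not-AD/no-impairment.
No multiple-testing adjustment is applied anywhere; p-values are reported
unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import Category, CategoryAssignment
from .records import (
    BRAIN_REGIONS,
    ClinicalAD,
    CognitiveStatus,
    Dichotomous,
    ParticipantRecord,
    TriState,
    YesNoMissing,
)
from .availability import VennCounts, venn_counts
from .stats import (
    Contrast,
    ContractError,
    LogitFit,
    OddsResult,
    fit_logistic,
    fit_mixed_logistic,
    pearson_chi2,
    posthoc_contrasts,
    rank_sum_test,
)

CATEGORY_ORDER = (Category.NO_TDP43, Category.OTHER_TDP43,
                  Category.LATE_NC, Category.ALS_FTLD_TDP)

PAIRWISE = (
    (Category.LATE_NC, Category.NO_TDP43),
    (Category.LATE_NC, Category.ALS_FTLD_TDP),
    (Category.ALS_FTLD_TDP, Category.NO_TDP43),
)

# outcome -> record accessor returning 1 / 0 / None (missing)
def _dich(value: Dichotomous) -> int | None:
    if value is Dichotomous.NOT_ASSESSED:
        return None
    return 1 if value is Dichotomous.HIGH else 0


def _tri(value: TriState) -> int | None:
    if value is TriState.NOT_ASSESSED:
        return None
    return 1 if value is TriState.PRESENT else 0


def _ynm(value: YesNoMissing) -> int | None:
    if value is YesNoMissing.MISSING:
        return None
    return 1 if value is YesNoMissing.PRESENT else 0


OUTCOMES: dict[str, Callable[[ParticipantRecord], int | None]] = {
    "dementia": lambda r: (
        None if r.clinical.cognitive_status is CognitiveStatus.MISSING
        else int(r.clinical.cognitive_status is CognitiveStatus.DEMENTIA)),
    "clinical_ad": lambda r: (
        None if r.clinical.clinical_ad is ClinicalAD.MISSING
        else int(r.clinical.clinical_ad is ClinicalAD.AD)),
    "ppa": lambda r: _ynm(r.clinical.ppa),
    "bvftd": lambda r: _ynm(r.clinical.bvftd),
    "hs_a": lambda r: None if not r.path.hs_a.assessed
    else int(r.path.hs_a.present),
    "ftld_tau": lambda r: _tri(r.path.ftld_tau),
    "adnc": lambda r: _dich(r.path.adnc),
    "caa": lambda r: _dich(r.path.caa),
    "lewy": lambda r: _tri(r.path.lewy_any),
    "atherosclerosis": lambda r: _dich(r.path.atherosclerosis),
    "arteriolosclerosis": lambda r: _dich(r.path.arteriolosclerosis),
    "infarcts": lambda r: _tri(r.path.infarcts),
    "microinfarcts": lambda r: _tri(r.path.microinfarcts),
    "hemorrhages": lambda r: _tri(r.path.hemorrhages),
    "hipp_atrophy": lambda r: _dich(r.path.hipp_atrophy),
    "cortical_atrophy": lambda r: _dich(r.path.cortical_atrophy),
    "lobar_atrophy": lambda r: _tri(r.path.lobar_atrophy),
}

ADJUSTMENT_COVARIATES = ("age_at_death", "sex", "education",
                         "interval_visit_death")

CONTINUOUS_VARS = ("age_at_death", "education", "interval_visit_death",
                   "cdr_sb")
CATEGORICAL_VARS = ("sex", "apoe4", "ftd_mutation", "tdp_antibody",
                    "cognitive_status", "clinical_ad", "ppa", "bvftd",
                    "hs_a", "ftld_tau", "adnc", "caa", "lewy_any",
                    "atherosclerosis", "arteriolosclerosis", "infarcts",
                    "microinfarcts", "hemorrhages", "hipp_atrophy",
                    "cortical_atrophy", "lobar_atrophy")

_MISSING_TOKENS = {"missing", "not_assessed", "not_listed", None}


def _category_map(
    assignments: Sequence[CategoryAssignment],
) -> dict[str, Category]:
    return {a.participant_id: a.category for a in assignments}


def _cat_value(rec: ParticipantRecord, var: str):
    """Categorical display value with missing collapsed to None."""
    if var == "hs_a":
        h = rec.path.hs_a
        if not h.assessed:
            return None
        return "present" if h.present else "absent"
    if var == "ftd_mutation":
        return "yes" if rec.clinical.ftd_mutation else "no_unknown"
    for holder in (rec.clinical, rec.path):
        if hasattr(holder, var):
            v = getattr(holder, var)
            v = getattr(v, "value", v)
            return None if v in _MISSING_TOKENS else v
    raise KeyError(var)


@dataclass
class SummaryTable:
    """Group-comparison table: cells plus pairwise test p-values."""

    cells: pd.DataFrame       # variable, level, category, n, pct, mean, sd, n_missing
    tests: pd.DataFrame       # variable, comparison, test, p_value
    group_sizes: dict[str, int]


def summarize_by_category(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
) -> SummaryTable:
    """Participant characteristics and co-pathologies by TDP-43 category.

    Continuous variables are summarized as mean (SD) and compared with
    rank-sum tests; categorical as n (%) over non-missing records with
    Pearson chi-square tests, for the three standing pairwise comparisons.
    Comparisons touching an empty category are skipped.
    """
    cat_of = _category_map(assignments)
    by_cat: dict[Category, list[ParticipantRecord]] = {
        c: [] for c in CATEGORY_ORDER}
    for rec in cohort:
        c = cat_of.get(rec.participant_id)
        if c is not None:
            by_cat[c].append(rec)
    sizes = {c.value: len(by_cat[c]) for c in CATEGORY_ORDER}

    cells = []
    tests = []
    for var in CONTINUOUS_VARS:
        per_cat_values = {}
        for c in CATEGORY_ORDER:
            vals = np.array([getattr(r.clinical, var) for r in by_cat[c]],
                            dtype=float)
            ok = vals[~np.isnan(vals)]
            per_cat_values[c] = ok
            cells.append({
                "variable": var, "level": "", "category": c.value,
                "n": len(ok), "pct": np.nan,
                "mean": float(ok.mean()) if len(ok) else np.nan,
                "sd": float(ok.std(ddof=1)) if len(ok) > 1 else np.nan,
                "n_missing": int(np.isnan(vals).sum()),
            })
        for a, b in PAIRWISE:
            if len(per_cat_values[a]) and len(per_cat_values[b]):
                _, p = rank_sum_test(per_cat_values[a], per_cat_values[b])
            else:
                p = np.nan
            tests.append({"variable": var,
                          "comparison": f"{a.value} vs {b.value}",
                          "test": "rank_sum", "p_value": p})

    for var in CATEGORICAL_VARS:
        per_cat_counts: dict[Category, dict] = {}
        levels: list = []
        for c in CATEGORY_ORDER:
            vals = [_cat_value(r, var) for r in by_cat[c]]
            nonmiss = [v for v in vals if v is not None]
            counts = pd.Series(nonmiss).value_counts().to_dict()
            per_cat_counts[c] = counts
            for lev in counts:
                if lev not in levels:
                    levels.append(lev)
            per_cat_counts[c]["__missing__"] = len(vals) - len(nonmiss)
        levels.sort(key=str)
        for c in CATEGORY_ORDER:
            denom = sum(v for k, v in per_cat_counts[c].items()
                        if k != "__missing__")
            for lev in levels:
                n = per_cat_counts[c].get(lev, 0)
                cells.append({
                    "variable": var, "level": str(lev), "category": c.value,
                    "n": n, "pct": 100.0 * n / denom if denom else np.nan,
                    "mean": np.nan, "sd": np.nan,
                    "n_missing": per_cat_counts[c]["__missing__"],
                })
        for a, b in PAIRWISE:
            tab = np.array(
                [[per_cat_counts[g].get(lev, 0) for lev in levels]
                 for g in (a, b)], dtype=float)
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.size and tab.sum(axis=1).min() > 0 and tab.shape[1] > 1:
                _, p = pearson_chi2(tab)
            else:
                p = np.nan
            tests.append({"variable": var,
                          "comparison": f"{a.value} vs {b.value}",
                          "test": "chi_square", "p_value": p})

    return SummaryTable(pd.DataFrame(cells), pd.DataFrame(tests), sizes)


# ---------------------------------------------------------------------------
# regressions


def _sex_male(rec: ParticipantRecord) -> float:
    return 1.0 if rec.clinical.sex.value == "male" else 0.0


def build_design(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
    outcome: str,
    reference: Category = Category.NO_TDP43,
    adjusted: bool = True,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, int]:
    """Complete-case design matrix for one outcome.

    Returns (X, y, centers, n_missing); rows are complete cases with
    respect to the outcome and (when ``adjusted``) the four covariates.
    """
    fn = OUTCOMES[outcome]
    cat_of = _category_map(assignments)
    rows, ys, centers = [], [], []
    n_missing = 0
    for rec in cohort:
        cat = cat_of.get(rec.participant_id)
        if cat is None:
            continue
        y = fn(rec)
        cov = [rec.clinical.age_at_death, _sex_male(rec),
               rec.clinical.education, rec.clinical.interval_visit_death]
        if y is None or (adjusted and any(np.isnan(c) for c in cov)):
            n_missing += 1
            continue
        row = {"const": 1.0}
        for c in CATEGORY_ORDER:
            if c is reference:
                continue
            row[f"cat_{c.value}"] = 1.0 if cat is c else 0.0
        if adjusted:
            row.update(zip(ADJUSTMENT_COVARIATES, cov))
        rows.append(row)
        ys.append(float(y))
        centers.append(rec.center_id)
    X = pd.DataFrame(rows)
    return X, np.asarray(ys), np.asarray(centers), n_missing


def adjusted_logistic(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
    outcome: str,
    adjusted: bool = True,
    reference: Category = Category.NO_TDP43,
) -> tuple[LogitFit, list[OddsResult]]:
    """Logistic regression of one dichotomized outcome on TDP-43 category,
    adjusted for age at death, sex, education, and last-visit-to-death
    interval; reference group: no brain TDP-43."""
    X, y, _, _ = build_design(cohort, assignments, outcome,
                              reference=reference, adjusted=adjusted)
    if len(y) == 0:
        raise ContractError(f"no complete cases for outcome {outcome!r}")
    fit = fit_logistic(X, y)
    covs = tuple(ADJUSTMENT_COVARIATES) if adjusted else ()
    results = []
    for c in CATEGORY_ORDER:
        if c is reference:
            continue
        r = fit.term_or(f"cat_{c.value}", outcome=outcome,
                        comparison=f"{c.value} vs {reference.value}")
        r.covariates = covs
        results.append(r)
    return fit, results


def multilevel_logistic(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
    outcome: str,
    adjusted: bool = True,
    reference: Category = Category.NO_TDP43,
) -> tuple[LogitFit, list[OddsResult]]:
    """As :func:`adjusted_logistic` with a varying intercept per center.

    With a single center the model degenerates to the single-level fit
    (documented behavior, noted on the result)."""
    X, y, centers, _ = build_design(cohort, assignments, outcome,
                                    reference=reference, adjusted=adjusted)
    if len(y) == 0:
        raise ContractError(f"no complete cases for outcome {outcome!r}")
    fit = fit_mixed_logistic(X, y, centers)
    covs = tuple(ADJUSTMENT_COVARIATES) if adjusted else ()
    results = []
    for c in CATEGORY_ORDER:
        if c is reference:
            continue
        r = fit.term_or(f"cat_{c.value}", outcome=outcome,
                        comparison=f"{c.value} vs {reference.value}")
        r.covariates = covs
        results.append(r)
    return fit, results


CATEGORY_CONTRASTS = (
    (Category.LATE_NC, Category.ALS_FTLD_TDP),
    (Category.LATE_NC, Category.OTHER_TDP43),
    (Category.ALS_FTLD_TDP, Category.OTHER_TDP43),
)


def category_contrasts(fit: LogitFit, outcome: str = "") -> list[Contrast]:
    """Unadjusted Wald post-hoc contrasts between the TDP-43 categories."""
    pairs = [(f"cat_{a.value}", f"cat_{b.value}")
             for a, b in CATEGORY_CONTRASTS]
    return posthoc_contrasts(fit, pairs, outcome=outcome)


# ---------------------------------------------------------------------------
# pattern and overlap tabulations


def regional_pattern_counts(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
    category: Category,
) -> VennCounts:
    """Presence-pattern counts over the four brain regions for one category,
    among its records with TDP-43 in at least one brain region."""
    cat_of = _category_map(assignments)
    memberships = []
    for rec in cohort:
        if cat_of.get(rec.participant_id) is not category:
            continue
        pres = [getattr(rec.regional, r) is TriState.PRESENT
                for r in BRAIN_REGIONS]
        if any(pres):
            memberships.append(pres)
    return venn_counts(BRAIN_REGIONS, memberships)


OVERLAP_SETS = ("als_ftld_tdp", "late_nc", "adnc", "lewy")


def overlap_proportions(
    cohort: Sequence[ParticipantRecord],
    assignments: Sequence[CategoryAssignment],
) -> VennCounts:
    """Co-occurrence of the ALS/FTLD-TDP and LATE-NC groups with
    intermediate/high ADNC and any-region Lewy bodies, excluding the
    Other-TDP-43 group and records without ADNC or Lewy-body ratings.
    The two TDP-43 groups are mutually exclusive by construction."""
    cat_of = _category_map(assignments)
    memberships = []
    for rec in cohort:
        cat = cat_of.get(rec.participant_id)
        if cat is None or cat is Category.OTHER_TDP43:
            continue
        if not rec.path.adnc.assessed or not rec.path.lewy_any.assessed:
            continue
        memberships.append([
            cat is Category.ALS_FTLD_TDP,
            cat is Category.LATE_NC,
            rec.path.adnc is Dichotomous.HIGH,
            rec.path.lewy_any is TriState.PRESENT,
        ])
    return venn_counts(OVERLAP_SETS, memberships)
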