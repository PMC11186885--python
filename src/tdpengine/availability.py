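"""Availability analytics: who was assessed for what, and when.

Multicenter autopsy registries accumulate structured missingness — measures
enter the forms in different years, centers adopt stains unevenly, and some
assessments are skipped conditionally on other findings.  These routines
quantify that: follow-up/autopsy rates by presumptive diagnosis,
availability-by-year curves, set-membership (Venn) counts over measures and
regions, and the era-split test for conditional neocortical assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    BRAIN_REGIONS,
    DxCategory,
    ParticipantRecord,
    TriState,
    availability_profile,
    group_diagnosis,
)
from .stats import (
    ContractError,
    LogitFit,
    OddsResult,
    fit_logistic,
    fit_mixed_logistic,
    pearson_chi2,
)

MEASURES = (
    "spinal_cord", "amygdala", "hippocampus", "ec_itc", "neocortex",
    "regional_any", "ftld_tdp", "als", "hs_a", "antibody",
)


@dataclass
class VennCounts:
    """Counts of records per non-empty set-membership pattern."""

    set_labels: tuple[str, ...]
    counts: dict[tuple[bool, ...], int]
    total: int
    extras: dict[str, int] = field(default_factory=dict)

    def n_in_any(self) -> int:
        return sum(self.counts.values())

    def count(self, *members: str) -> int:
        """Count of the exact pattern whose members are ``members``."""
        pattern = tuple(lab in members for lab in self.set_labels)
        return self.counts.get(pattern, 0)

    def marginal(self, member: str) -> int:
        i = self.set_labels.index(member)
        return sum(c for pat, c in self.counts.items() if pat[i])

    def intersection_all(self) -> int:
        return self.counts.get(tuple([True] * len(self.set_labels)), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": "+".join(
                    lab for lab, m in zip(self.set_labels, pat) if m),
                "count": c,
                "proportion": c / self.n_in_any() if self.n_in_any() else np.nan,
            }
            for pat, c in sorted(self.counts.items(), reverse=True)
        ]
        return pd.DataFrame(rows, columns=["pattern", "count", "proportion"])


def venn_counts(
    set_labels: Sequence[str],
    memberships: Iterable[Sequence[bool]],
) -> VennCounts:
    counts: dict[tuple[bool, ...], int] = {}
    total = 0
    for row in memberships:
        total += 1
        pat = tuple(bool(v) for v in row)
        if any(pat):
            counts[pat] = counts.get(pat, 0) + 1
    return VennCounts(tuple(set_labels), counts, total)


def _measure_availability(rec: ParticipantRecord) -> dict[str, bool]:
    prof = availability_profile(rec)
    return {
        "spinal_cord": rec.regional.spinal_cord.assessed,
        "amygdala": prof.has_amygdala,
        "hippocampus": prof.has_hippocampus,
        "ec_itc": prof.has_ec_itc,
        "neocortex": prof.has_neocortex,
        "regional_any": prof.has_regional_any,
        "ftld_tdp": prof.has_ftld_tdp,
        "als": prof.has_als,
        "hs_a": prof.has_hs_a,
        "antibody": prof.has_antibody,
    }


def availability_by_year(
    cohort: Sequence[ParticipantRecord],
) -> pd.DataFrame:
    """Per measure and calendar year of death: the fraction of that year's
    autopsied deaths with the measure assessed.  Tidy frame with columns
    measure, year, numerator, denominator, proportion."""
    rows = []
    for rec in cohort:
        if not rec.clinical.autopsied or rec.clinical.year_of_death is None:
            continue
        avail = _measure_availability(rec)
        rows.append({"year": rec.clinical.year_of_death, **avail})
    if not rows:
        return pd.DataFrame(
            columns=["measure", "year", "numerator", "denominator",
                     "proportion"])
    df = pd.DataFrame(rows)
    out = []
    for (year,), grp in df.groupby(["year"]):
        for m in MEASURES:
            num = int(grp[m].sum())
            den = len(grp)
            out.append({"measure": m, "year": int(year), "numerator": num,
                        "denominator": den, "proportion": num / den})
    return pd.DataFrame(out).sort_values(["measure", "year"],
                                         ignore_index=True)


MEASURE_SETS = ("regional_any", "ftld_tdp", "als", "hs_a")


def measure_venn(cohort: Sequence[ParticipantRecord]) -> VennCounts:
    """Availability overlap across the four TDP-43-related measure families."""
    avail = [_measure_availability(r) for r in cohort]
    return venn_counts(
        MEASURE_SETS, ([a[m] for m in MEASURE_SETS] for a in avail))


def region_venn(cohort: Sequence[ParticipantRecord]) -> VennCounts:
    """Availability overlap across the four brain regions, for records with
    at least one regional assessment (precondition).  ``extras`` reports the
    all-four count and the staging-relevant trio
    (amygdala, hippocampus, neocortex)."""
    memberships = []
    trio = 0
    for rec in cohort:
        avail = _measure_availability(rec)
        if not avail["regional_any"]:
            raise ContractError(
                f"record {rec.participant_id} has no regional assessment")
        memberships.append([avail[r] for r in BRAIN_REGIONS])
        if avail["amygdala"] and avail["hippocampus"] and avail["neocortex"]:
            trio += 1
    vc = venn_counts(BRAIN_REGIONS, memberships)
    vc.extras["all_four"] = vc.intersection_all()
    vc.extras["staging_trio"] = trio
    return vc


@dataclass
class EraTable:
    """2x2 neocortex-availability by hippocampal TDP-43 status for one era."""

    era: str
    table: np.ndarray        # rows: hipp TDP absent, present; cols: neocortex assessed, not
    prop_hipp_negative: float
    prop_hipp_positive: float
    chi2: float
    p_value: float


def conditional_neocortex_availability(
    cohort: Sequence[ParticipantRecord],
    split_year: int = 2019,
    yates: bool = False,
) -> dict[str, EraTable]:
    """Era-split test for conditional neocortical TDP-43 assessment.

    Restricted to participants with a presumptive AD diagnosis whose
    hippocampus was assessed; eras split at death year >= ``split_year``
    ("during or after").  If staging practice makes pathologists skip the
    neocortex when the hippocampus is TDP-43-negative, the negative stratum
    shows lower availability — only in the later era.
    """
    rows = []
    for rec in cohort:
        if rec.clinical.year_of_death is None:
            continue
        if group_diagnosis(rec.clinical.etiologic_dx_raw) is not DxCategory.AD:
            continue
        hipp = rec.regional.hippocampus
        if not hipp.assessed:
            continue
        rows.append({
            "era": "post" if rec.clinical.year_of_death >= split_year
            else "pre",
            "hipp_present": hipp is TriState.PRESENT,
            "neo_assessed": rec.regional.neocortex.assessed,
        })
    df = pd.DataFrame(rows, columns=["era", "hipp_present", "neo_assessed"])
    out: dict[str, EraTable] = {}
    for era in ("pre", "post"):
        sub = df[df["era"] == era]
        tab = np.zeros((2, 2), dtype=int)
        for i, hp in enumerate((False, True)):
            s = sub[sub["hipp_present"] == hp]
            tab[i, 0] = int(s["neo_assessed"].sum())
            tab[i, 1] = len(s) - tab[i, 0]
        def _prop(row):
            return row[0] / row.sum() if row.sum() else np.nan
        if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
            chi2, p = np.nan, np.nan      # empty stratum: undefined, reported
        else:
            chi2, p = pearson_chi2(tab, yates=yates)
        out[era] = EraTable(era, tab, _prop(tab[0]), _prop(tab[1]), chi2, p)
    return out


@dataclass
class RateTable:
    """Numerator / denominator / proportion per stratum."""

    strata: tuple[str, ...]
    numerator: dict[str, int]
    denominator: dict[str, int]

    def proportion(self, stratum: str) -> float:
        d = self.denominator[stratum]
        return self.numerator[stratum] / d if d else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": list(self.strata),
                "numerator": [self.numerator[s] for s in self.strata],
                "denominator": [self.denominator[s] for s in self.strata],
                "proportion": [self.proportion(s) for s in self.strata],
            }
        )


def rate_table(frame: pd.DataFrame, by: str, outcome: str) -> RateTable:
    strata = tuple(str(s) for s in frame[by].unique())
    num = {}
    den = {}
    for s in strata:
        sub = frame[frame[by].astype(str) == s]
        num[s] = int(sub[outcome].sum())
        den[s] = len(sub)
    return RateTable(strata, num, den)


_DX_ORDER = [c for c in DxCategory if c is not DxCategory.AD]


def _dx_design(frame: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)
    present = [c for c in _DX_ORDER
               if (frame["dx_category"] == c.value).any()]
    for c in present:
        X[f"dx_{c.value}"] = (frame["dx_category"] == c.value).astype(float)
    return X


def followup_autopsy_models(
    population: pd.DataFrame,
    multilevel: bool = True,
) -> dict[str, dict[str, list[OddsResult]]]:
    """Follow-up-to-death and autopsy-rate logistic models by diagnosis
    category (reference: AD), single-level and, when requested and >=2
    centers exist, with a varying center intercept.

    ``population`` needs columns dx_category, center_id, deceased,
    autopsied.  A category with no outcome variation is reported
    non-estimable rather than fabricated.
    """
    out: dict[str, dict[str, list[OddsResult]]] = {}
    specs = [
        ("followup", population, "deceased"),
        ("autopsy", population[population["deceased"].astype(bool)], "autopsied"),
    ]
    for name, frame, outcome in specs:
        frame = frame.reset_index(drop=True)
        X = _dx_design(frame)
        y = frame[outcome].astype(float)
        fits: dict[str, LogitFit] = {"single_level": fit_logistic(X, y)}
        if multilevel and frame["center_id"].nunique() >= 2:
            fits["multilevel"] = fit_mixed_logistic(X, y, frame["center_id"])
        out[name] = {}
        for model, fit in fits.items():
            results = []
            for col in X.columns:
                if col == "const":
                    continue
                cat = col.removeprefix("dx_")
                results.append(fit.term_or(
                    col, outcome=name, comparison=f"{cat} vs AD"))
            out[name][model] = results
    return out
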