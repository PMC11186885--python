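"""Rule-based TDP-43 category assignment and LATE-NC staging.

Categories are assigned top-down with fixed precedence:

1. An FTLD-TDP designation or TDP-43 motor-neuron inclusions (ALS-TDP)
   place the record in the combined ALS/FTLD-TDP spectrum group,
   irrespective of any other pathology.
2. No TDP-43 in any brain region (and no designation from rule 1) means
   "No TDP-43" — spinal-cord-only TDP-43 stays in this group because the
   categories are defined on brain TDP-43; the spinal finding is noted in
   the rule trace.
3. Brain TDP-43 plus an exclusionary pathology (CBD, CTE, acute/chronic
   TBI, Huntington disease, Guam/Kii parkinsonism) or an FTD-related or
   autosomal-dominant-AD mutation rules out LATE-NC: "Other TDP-43".
4. Neocortical TDP-43 without TDP-43 in *both* the amygdala and the
   hippocampus is not an admissible LATE-NC distribution: "Other TDP-43".
5. Everything remaining is LATE-NC, staged 1-3: stage 2 requires amygdala
   and hippocampus involvement, stage 3 additionally the neocortex, and
   stage 1 is any other limbic pattern (amygdala, hippocampus and/or
   EC/ITC).

Classification is only defined on complete cases (all four brain regions,
the FTLD-TDP designation, the motor-neuron assessment, and HS-A assessed);
calling it on an incomplete record is a contract error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import pandas as pd

from .records import (
    BRAIN_REGIONS,
    MNInclusion,
    ParticipantRecord,
    RegionalTDP,
    TriState,
    is_complete_case,
)


class Category(str, Enum):
    NO_TDP43 = "no_tdp43"
    LATE_NC = "late_nc"
    ALS_FTLD_TDP = "als_ftld_tdp"
    OTHER_TDP43 = "other_tdp43"


class Subtype(str, Enum):
    FTLD_ONLY = "ftld_only"
    ALS_ONLY = "als_only"
    BOTH = "both"
    NA = "n/a"


#: exclusionary reasons, in the order they are checked
EXCLUSION_FLAGS = (
    "cbd", "cte", "tbi_acute", "tbi_chronic", "huntington", "guam_kii",
)


class ContractError(RuntimeError):
    """A precondition of the classification contract was violated."""


@dataclass
class CategoryAssignment:
    participant_id: str
    category: Category
    subtype: Subtype = Subtype.NA
    stage: int | None = None            # 1..3 iff category == LATE_NC
    other_reason: tuple[str, ...] = ()
    qc_warnings: tuple[str, ...] = ()
    trace: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert (self.stage is not None) == (self.category is Category.LATE_NC)
        assert (self.subtype is not Subtype.NA) == (
            self.category is Category.ALS_FTLD_TDP)
        assert bool(self.other_reason) == (
            self.category is Category.OTHER_TDP43)


def late_stage(regional: RegionalTDP) -> int:
    """LATE-NC stage from brain TDP-43 distribution.

    Requires at least one of amygdala / hippocampus / EC-ITC involved
    (the LATE-NC eligibility the category rules establish).
    """
    amyg = regional.amygdala is TriState.PRESENT
    hipp = regional.hippocampus is TriState.PRESENT
    ec = regional.ec_itc is TriState.PRESENT
    neo = regional.neocortex is TriState.PRESENT
    if not (amyg or hipp or ec):
        raise ContractError(
            "late_stage requires amygdala, hippocampus or EC/ITC involvement")
    if amyg and hipp and neo:
        return 3
    if amyg and hipp:
        return 2
    return 1


def als_ftld_subtype(record: ParticipantRecord) -> Subtype:
    """Split the ALS/FTLD-TDP spectrum group by which designation(s) fired."""
    ftld = record.path.ftld_tdp is TriState.PRESENT
    als = record.path.mn_inclusion is MNInclusion.TDP43
    if ftld and als:
        return Subtype.BOTH
    if ftld:
        return Subtype.FTLD_ONLY
    if als:
        return Subtype.ALS_ONLY
    raise ContractError("record carries neither FTLD-TDP nor ALS-TDP")


def classify_tdp(record: ParticipantRecord) -> CategoryAssignment:
    """Assign the TDP-43 category (and stage/subtype) for one complete case."""
    if not is_complete_case(record):
        raise ContractError(
            f"record {record.participant_id}: classification is undefined "
            "without all TDP-43 assessments (complete case)")

    trace: list[str] = []
    qc: list[str] = []
    reg = record.regional
    brain_present = reg.any_brain_present()
    spinal_present = reg.spinal_cord is TriState.PRESENT
    if spinal_present:
        trace.append("note: spinal cord TDP-43 present")

    # rule 1: designations dominate everything else
    ftld = record.path.ftld_tdp is TriState.PRESENT
    als = record.path.mn_inclusion is MNInclusion.TDP43
    if ftld or als:
        trace.append("rule1: ALS-TDP and/or FTLD-TDP designation")
        if not brain_present:
            qc.append("designated ALS/FTLD-TDP without brain regional TDP-43"
                      + ("" if spinal_present else " or spinal TDP-43"))
        return CategoryAssignment(
            participant_id=record.participant_id,
            category=Category.ALS_FTLD_TDP,
            subtype=als_ftld_subtype(record),
            qc_warnings=tuple(qc),
            trace=trace,
        )

    # rule 2: no brain TDP-43
    if not brain_present:
        trace.append("rule2: no brain TDP-43, no designation")
        return CategoryAssignment(
            participant_id=record.participant_id,
            category=Category.NO_TDP43,
            qc_warnings=tuple(qc),
            trace=trace,
        )

    # rule 3: LATE-NC-exclusionary pathologies and mutations
    reasons = [f for f in EXCLUSION_FLAGS if getattr(record.path, f)]
    if record.clinical.ftd_mutation:
        reasons.append("ftd_mutation")
    if record.clinical.adad_mutation:
        reasons.append("adad_mutation")
    if reasons:
        trace.append("rule3: exclusionary pathology/mutation: "
                     + ", ".join(reasons))
        return CategoryAssignment(
            participant_id=record.participant_id,
            category=Category.OTHER_TDP43,
            other_reason=tuple(reasons),
            qc_warnings=tuple(qc),
            trace=trace,
        )

    # rule 4: neocortical TDP-43 without both amygdala and hippocampus
    if reg.neocortex is TriState.PRESENT and not (
            reg.amygdala is TriState.PRESENT
            and reg.hippocampus is TriState.PRESENT):
        trace.append("rule4: neocortical TDP-43 without both amygdala "
                     "and hippocampal TDP-43")
        if not (reg.amygdala is TriState.PRESENT
                or reg.hippocampus is TriState.PRESENT
                or reg.ec_itc is TriState.PRESENT):
            trace.append("note: isolated neocortical TDP-43")
        return CategoryAssignment(
            participant_id=record.participant_id,
            category=Category.OTHER_TDP43,
            other_reason=("neocortical_pattern",),
            qc_warnings=tuple(qc),
            trace=trace,
        )

    # rule 5: LATE-NC, staged
    stage = late_stage(reg)
    trace.append(f"rule5: LATE-NC stage {stage}")
    return CategoryAssignment(
        participant_id=record.participant_id,
        category=Category.LATE_NC,
        stage=stage,
        qc_warnings=tuple(qc),
        trace=trace,
    )


def classify_cohort(
    cohort: Sequence[ParticipantRecord],
) -> list[CategoryAssignment]:
    return [classify_tdp(rec) for rec in cohort]


def assignments_to_frame(
    assignments: Sequence[CategoryAssignment],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [a.participant_id for a in assignments],
            "category": [a.category.value for a in assignments],
            "subtype": [a.subtype.value for a in assignments],
            "stage": [a.stage for a in assignments],
            "other_reason": ["|".join(a.other_reason) for a in assignments],
            "qc_warnings": ["|".join(a.qc_warnings) for a in assignments],
        }
    )
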