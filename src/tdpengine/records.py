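"""Core domain types for coded multicenter autopsy records.

The data model mirrors the coded neuropathology and clinical fields of
NACC-style (National Alzheimer's Coordinating Center) autopsy datasets:
tri-state regional TDP-43 assessments (present / absent / not assessed),
designation flags for FTLD-TDP and motor-neuron inclusions, hippocampal
sclerosis of aging (HS-A), co-pathologies, and last-visit clinical
information.  "Not assessed" is always distinct from "absent": the former
removes a record from complete-case analyses, the latter does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Sequence

import math

import pandas as pd


class TriState(str, Enum):
    """Outcome of a single pathology assessment."""

    PRESENT = "present"
    ABSENT = "absent"
    NOT_ASSESSED = "not_assessed"

    @property
    def assessed(self) -> bool:
        return self is not TriState.NOT_ASSESSED


class MNInclusion(str, Enum):
    """Motor-neuron inclusion type; TDP43 defines ALS-TDP."""

    TDP43 = "tdp43"
    FUS = "fus"
    SOD1 = "sod1"
    OTHER = "other"
    NONE = "none"
    NOT_ASSESSED = "not_assessed"

    @property
    def assessed(self) -> bool:
        return self is not MNInclusion.NOT_ASSESSED


class HSA(str, Enum):
    """Hippocampal sclerosis of aging, recorded with laterality."""

    ABSENT = "absent"
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"
    LATERALITY_UNKNOWN = "laterality_unknown"
    NOT_ASSESSED = "not_assessed"

    @property
    def assessed(self) -> bool:
        return self is not HSA.NOT_ASSESSED

    @property
    def present(self) -> bool:
        # presence regardless of laterality: many centers section one hemisphere
        return self in (HSA.UNILATERAL, HSA.BILATERAL, HSA.LATERALITY_UNKNOWN)


class Antibody(str, Enum):
    PHOSPHO = "phospho"
    NON_PHOSPHO = "non_phospho"
    OTHER = "other"
    NOT_LISTED = "not_listed"


class Dichotomous(str, Enum):
    """Two-level severity scales (ADNC, CAA, vascular, atrophy)."""

    LOW = "low"          # none/low or none/mild
    HIGH = "high"        # intermediate/high or moderate/severe
    NOT_ASSESSED = "not_assessed"

    @property
    def assessed(self) -> bool:
        return self is not Dichotomous.NOT_ASSESSED


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class CognitiveStatus(str, Enum):
    NORMAL = "normal"
    MCI_IMPAIRED = "mci_impaired"
    DEMENTIA = "dementia"
    MISSING = "missing"


class ClinicalAD(str, Enum):
    NO_IMPAIRMENT = "no_impairment"
    NOT_AD = "not_ad"
    AD = "ad"
    MISSING = "missing"


class YesNoMissing(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"


class DxCategory(str, Enum):
    """Eight-way grouping of the last presumptive etiologic diagnosis."""

    AD = "AD"
    FTLD = "FTLD"
    CBD_PSP = "CBD_PSP"
    LB = "LB"
    VASCULAR = "VASCULAR"
    OTHER_IMPAIRED = "OTHER_IMPAIRED"
    NOT_IMPAIRED = "NOT_IMPAIRED"
    UNAVAILABLE = "UNAVAILABLE"


BRAIN_REGIONS = ("amygdala", "hippocampus", "ec_itc", "neocortex")
STAGING_REGIONS = ("amygdala", "hippocampus", "neocortex")


@dataclass
class RegionalTDP:
    """Tri-state TDP-43 assessments for spinal cord and four brain regions."""

    spinal_cord: TriState = TriState.NOT_ASSESSED
    amygdala: TriState = TriState.NOT_ASSESSED
    hippocampus: TriState = TriState.NOT_ASSESSED
    ec_itc: TriState = TriState.NOT_ASSESSED
    neocortex: TriState = TriState.NOT_ASSESSED

    def __post_init__(self) -> None:
        _coerce_enums(self)

    def brain(self) -> dict[str, TriState]:
        return {r: getattr(self, r) for r in BRAIN_REGIONS}

    def any_brain_present(self) -> bool:
        return any(getattr(self, r) is TriState.PRESENT for r in BRAIN_REGIONS)

    def all_brain_assessed(self) -> bool:
        return all(getattr(self, r).assessed for r in BRAIN_REGIONS)


def _coerce_enums(obj) -> None:
    """Allow plain strings for enum-typed dataclass fields."""
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, str) and not isinstance(v, Enum):
            typ = _ENUM_FIELD_TYPES.get(type(obj), {}).get(f.name)
            if typ is not None:
                setattr(obj, f.name, typ(v))


@dataclass
class PathologyFindings:
    ftld_tdp: TriState = TriState.NOT_ASSESSED
    mn_inclusion: MNInclusion = MNInclusion.NOT_ASSESSED
    hs_a: HSA = HSA.NOT_ASSESSED
    tdp_antibody: Antibody = Antibody.NOT_LISTED
    ftld_tau: TriState = TriState.NOT_ASSESSED
    adnc: Dichotomous = Dichotomous.NOT_ASSESSED
    caa: Dichotomous = Dichotomous.NOT_ASSESSED
    lewy_any: TriState = TriState.NOT_ASSESSED
    atherosclerosis: Dichotomous = Dichotomous.NOT_ASSESSED
    arteriolosclerosis: Dichotomous = Dichotomous.NOT_ASSESSED
    infarcts: TriState = TriState.NOT_ASSESSED
    microinfarcts: TriState = TriState.NOT_ASSESSED
    hemorrhages: TriState = TriState.NOT_ASSESSED
    hipp_atrophy: Dichotomous = Dichotomous.NOT_ASSESSED
    cortical_atrophy: Dichotomous = Dichotomous.NOT_ASSESSED
    lobar_atrophy: TriState = TriState.NOT_ASSESSED
    cbd: bool = False
    cte: bool = False
    tbi_acute: bool = False
    tbi_chronic: bool = False
    huntington: bool = False
    guam_kii: bool = False

    def __post_init__(self) -> None:
        _coerce_enums(self)


@dataclass
class ClinicalProfile:
    age_at_death: float = math.nan
    sex: Sex = Sex.FEMALE
    education: float = math.nan
    interval_visit_death: float = math.nan
    apoe4: YesNoMissing = YesNoMissing.MISSING
    ftd_mutation: bool = False          # yes vs no/unknown
    adad_mutation: bool = False
    cognitive_status: CognitiveStatus = CognitiveStatus.MISSING
    cdr_sb: float = math.nan
    clinical_ad: ClinicalAD = ClinicalAD.MISSING
    ppa: YesNoMissing = YesNoMissing.MISSING
    bvftd: YesNoMissing = YesNoMissing.MISSING
    etiologic_dx_raw: str | None = None
    deceased: bool = True
    autopsied: bool = True
    year_of_death: int | None = None

    def __post_init__(self) -> None:
        _coerce_enums(self)
        if not math.isnan(self.cdr_sb) and not (0.0 <= self.cdr_sb <= 18.0):
            raise ValueError(f"cdr_sb out of range [0, 18]: {self.cdr_sb}")
        if (not math.isnan(self.interval_visit_death)
                and self.interval_visit_death < 0):
            raise ValueError("interval_visit_death must be >= 0")
        if self.autopsied and not self.deceased:
            raise ValueError("autopsied implies deceased")


_ENUM_FIELD_TYPES: dict[type, dict[str, type]] = {
    RegionalTDP: {f: TriState for f in
                  ("spinal_cord",) + BRAIN_REGIONS},
    PathologyFindings: {
        "ftld_tdp": TriState, "mn_inclusion": MNInclusion, "hs_a": HSA,
        "tdp_antibody": Antibody, "ftld_tau": TriState,
        "adnc": Dichotomous, "caa": Dichotomous, "lewy_any": TriState,
        "atherosclerosis": Dichotomous, "arteriolosclerosis": Dichotomous,
        "infarcts": TriState, "microinfarcts": TriState,
        "hemorrhages": TriState, "hipp_atrophy": Dichotomous,
        "cortical_atrophy": Dichotomous, "lobar_atrophy": TriState,
    },
    ClinicalProfile: {
        "sex": Sex, "apoe4": YesNoMissing,
        "cognitive_status": CognitiveStatus,
        "clinical_ad": ClinicalAD, "ppa": YesNoMissing,
        "bvftd": YesNoMissing,
    },
}


@dataclass
class ParticipantRecord:
    participant_id: str
    center_id: str
    regional: RegionalTDP = field(default_factory=RegionalTDP)
    path: PathologyFindings = field(default_factory=PathologyFindings)
    clinical: ClinicalProfile = field(default_factory=ClinicalProfile)

    def __post_init__(self) -> None:
        if not self.center_id:
            raise ValueError("center_id must be non-empty")


@dataclass(frozen=True)
class AvailabilityProfile:
    """Assessed-vs-not booleans for the TDP-43-related measures of one record."""

    has_regional_any: bool
    has_regional_all_brain: bool
    has_amygdala: bool
    has_hippocampus: bool
    has_ec_itc: bool
    has_neocortex: bool
    has_ftld_tdp: bool
    has_als: bool
    has_hs_a: bool
    has_antibody: bool


def availability_profile(record: ParticipantRecord) -> AvailabilityProfile:
    """Profile which TDP-43 measures were assessed for one record.

    Total function: an all-missing record yields an all-False profile.  An
    antibody coded "not listed" counts as unavailable because no stain type
    can be attributed to the assessments.
    """
    r = record.regional
    region_flags = {reg: getattr(r, reg).assessed for reg in BRAIN_REGIONS}
    return AvailabilityProfile(
        has_regional_any=any(region_flags.values()),
        has_regional_all_brain=all(region_flags.values()),
        has_amygdala=region_flags["amygdala"],
        has_hippocampus=region_flags["hippocampus"],
        has_ec_itc=region_flags["ec_itc"],
        has_neocortex=region_flags["neocortex"],
        has_ftld_tdp=record.path.ftld_tdp.assessed,
        has_als=record.path.mn_inclusion.assessed,
        has_hs_a=record.path.hs_a.assessed,
        has_antibody=record.path.tdp_antibody is not Antibody.NOT_LISTED,
    )


#: Editable mapping from raw presumptive-etiologic-diagnosis labels to the
#: eight diagnosis categories.  Unrecognized non-missing labels raise.
DEFAULT_DX_LABELS: dict[str, DxCategory] = {
    "Alzheimer's disease": DxCategory.AD,
    "FTLD Other": DxCategory.FTLD,
    "FTLD motor neuron disease": DxCategory.FTLD,
    "Corticobasal degeneration": DxCategory.CBD_PSP,
    "Primary progressive supranuclear palsy": DxCategory.CBD_PSP,
    "Lewy body dementia": DxCategory.LB,
    "Vascular dementia": DxCategory.VASCULAR,
    "Other impairment": DxCategory.OTHER_IMPAIRED,
    "Not impaired": DxCategory.NOT_IMPAIRED,
}


class UnknownDiagnosisLabel(ValueError):
    pass


def group_diagnosis(
    raw: str | None,
    labels: dict[str, DxCategory] | None = None,
) -> DxCategory:
    """Map a raw presumptive etiologic diagnosis label to its category.

    ``None`` / empty (no last-visit diagnosis) maps to ``UNAVAILABLE``;
    any other label must appear in the mapping table.
    """
    if raw is None or raw == "":
        return DxCategory.UNAVAILABLE
    table = DEFAULT_DX_LABELS if labels is None else labels
    try:
        return table[raw]
    except KeyError:
        raise UnknownDiagnosisLabel(
            f"unrecognized presumptive etiologic diagnosis label: {raw!r}"
        ) from None


def is_complete_case(record: ParticipantRecord) -> bool:
    """True when every TDP-43-related assessment required for category
    assignment was performed: all four brain regions, the FTLD-TDP
    designation, the motor-neuron inclusion assessment, and HS-A."""
    return (
        record.regional.all_brain_assessed()
        and record.path.ftld_tdp.assessed
        and record.path.mn_inclusion.assessed
        and record.path.hs_a.assessed
    )


def complete_case_filter(
    cohort: Sequence[ParticipantRecord],
) -> list[ParticipantRecord]:
    """Restrict a cohort to complete cases, preserving order.

    Spinal-cord assessment is *not* required: the category rules are defined
    on brain TDP-43.
    """
    return [rec for rec in cohort if is_complete_case(rec)]


def cohort_to_frame(cohort: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into an analysis DataFrame (one row per participant)."""
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "participant_id": rec.participant_id,
            "center_id": rec.center_id,
        }
        for f in fields(rec.regional):
            row[f.name] = getattr(rec.regional, f.name).value
        for f in fields(rec.path):
            v = getattr(rec.path, f.name)
            row[f.name] = v.value if isinstance(v, Enum) else v
        for f in fields(rec.clinical):
            v = getattr(rec.clinical, f.name)
            row[f.name] = v.value if isinstance(v, Enum) else v
        rows.append(row)
    return pd.DataFrame(rows)
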