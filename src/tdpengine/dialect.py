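"""Code dialect for the rectangular coded-CSV interchange format.

Columns follow NACC naming for the TDP-43 block (NPTDPA..NPTDPE regional
assessments, NPFTDTDP, NPALSMND, NPHIPSCL, NPTDPAN) with declared names for
the clinical and co-pathology fields.  The default code mapping is
0 = absent/No, 1 = present/Yes, 8 or blank = not assessed (HS-A: 1/2/3 =
unilateral / bilateral / laterality unknown; clinical missings use 9).
Every code table is overridable from a YAML dialect file, so site-specific
codings can be declared rather than hand-edited in data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import copy

import yaml

# kind -> {code string -> canonical value string}
DEFAULT_CODES: dict[str, dict[str, str]] = {
    "tristate": {"0": "absent", "1": "present", "8": "not_assessed",
                 "": "not_assessed"},
    "mn": {"0": "none", "1": "tdp43", "2": "fus", "3": "sod1", "4": "other",
           "8": "not_assessed", "": "not_assessed"},
    "hsa": {"0": "absent", "1": "unilateral", "2": "bilateral",
            "3": "laterality_unknown", "8": "not_assessed",
            "": "not_assessed"},
    "antibody": {"1": "phospho", "2": "non_phospho", "3": "other",
                 "8": "not_listed", "": "not_listed"},
    "dich": {"0": "low", "1": "high", "8": "not_assessed",
             "": "not_assessed"},
    "sex": {"1": "female", "2": "male"},
    "cogstat": {"0": "normal", "1": "mci_impaired", "2": "dementia",
                "9": "missing", "": "missing"},
    "clinad": {"0": "no_impairment", "1": "not_ad", "2": "ad",
               "9": "missing", "": "missing"},
    "ynm": {"0": "absent", "1": "present", "9": "missing", "": "missing"},
    "flag": {"0": "false", "1": "true", "": "false"},
}

# column name, dotted attribute path on ParticipantRecord, kind
COLUMNS: list[tuple[str, str, str]] = [
    ("NACCID", "participant_id", "str"),
    ("ADCID", "center_id", "str"),
    ("NPTDPA", "regional.spinal_cord", "tristate"),
    ("NPTDPB", "regional.amygdala", "tristate"),
    ("NPTDPC", "regional.hippocampus", "tristate"),
    ("NPTDPD", "regional.ec_itc", "tristate"),
    ("NPTDPE", "regional.neocortex", "tristate"),
    ("NPFTDTDP", "path.ftld_tdp", "tristate"),
    ("NPALSMND", "path.mn_inclusion", "mn"),
    ("NPHIPSCL", "path.hs_a", "hsa"),
    ("NPTDPAN", "path.tdp_antibody", "antibody"),
    ("FTLDTAU", "path.ftld_tau", "tristate"),
    ("ADNC", "path.adnc", "dich"),
    ("CAA", "path.caa", "dich"),
    ("LEWY", "path.lewy_any", "tristate"),
    ("ATHERO", "path.atherosclerosis", "dich"),
    ("ARTERIO", "path.arteriolosclerosis", "dich"),
    ("INFARCTS", "path.infarcts", "tristate"),
    ("MICROINF", "path.microinfarcts", "tristate"),
    ("HEMORR", "path.hemorrhages", "tristate"),
    ("HIPPATR", "path.hipp_atrophy", "dich"),
    ("CORTATR", "path.cortical_atrophy", "dich"),
    ("LOBATR", "path.lobar_atrophy", "tristate"),
    ("CBD", "path.cbd", "flag"),
    ("CTE", "path.cte", "flag"),
    ("TBIACUTE", "path.tbi_acute", "flag"),
    ("TBICHRON", "path.tbi_chronic", "flag"),
    ("HUNTINGTON", "path.huntington", "flag"),
    ("GUAMKII", "path.guam_kii", "flag"),
    ("AGEDEATH", "clinical.age_at_death", "float"),
    ("SEX", "clinical.sex", "sex"),
    ("EDUC", "clinical.education", "float"),
    ("INTLASTVD", "clinical.interval_visit_death", "float"),
    ("APOE4", "clinical.apoe4", "ynm"),
    ("FTDMUT", "clinical.ftd_mutation", "flag"),
    ("ADADMUT", "clinical.adad_mutation", "flag"),
    ("COGSTAT", "clinical.cognitive_status", "cogstat"),
    ("CDRSB", "clinical.cdr_sb", "float"),
    ("CLINAD", "clinical.clinical_ad", "clinad"),
    ("PPA", "clinical.ppa", "ynm"),
    ("BVFTD", "clinical.bvftd", "ynm"),
    ("ETDX", "clinical.etiologic_dx_raw", "optstr"),
    ("DECEASED", "clinical.deceased", "flag"),
    ("AUTOPSIED", "clinical.autopsied", "flag"),
    ("YEARDEATH", "clinical.year_of_death", "optint"),
]


@dataclass
class Dialect:
    """Code tables plus their inverses, ready for parse and re-emit."""

    codes: dict[str, dict[str, str]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_CODES))

    def __post_init__(self) -> None:
        # canonical emit code per value: the first non-blank code listed
        self.emit: dict[str, dict[str, str]] = {}
        for kind, table in self.codes.items():
            inv: dict[str, str] = {}
            for code, value in table.items():
                if code != "" and value not in inv:
                    inv[value] = code
            self.emit[kind] = inv

    def decode(self, kind: str, code: str) -> str:
        table = self.codes[kind]
        if code in table:
            return table[code]
        raise KeyError(code)

    def encode(self, kind: str, value: str) -> str:
        return self.emit[kind][value]


def load_dialect(path: str | None = None) -> Dialect:
    """Load a dialect, merging YAML ``codes:`` overrides onto the defaults."""
    if path is None:
        return Dialect()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    codes = copy.deepcopy(DEFAULT_CODES)
    for kind, table in (doc.get("codes") or {}).items():
        if kind not in codes:
            raise ValueError(f"unknown code kind in dialect file: {kind!r}")
        codes[kind].update({str(k): str(v) for k, v in table.items()})
    return Dialect(codes=codes)
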