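"""Seeded generator of NACC-like multicenter autopsy cohorts.

The generator emits coded participant records with known ground truth so
every pipeline stage (parsing, classification, availability profiling,
association models) is testable without access to the request-only real
data.  Defaults encode the published complete-case landscape of the NACC
TDP-43 block: category prevalences (62% no TDP-43, 27% LATE-NC, 9%
ALS/FTLD-TDP, 2% other TDP-43), category-specific ages at death, APOE4 and
co-pathology rates, and regional-presence pattern tables; all values are
overridable through :class:`GeneratorConfig`.

Missingness is generated measure-wise (availability patterns in real data
are not nested): each measure follows a logistic year-of-death trend with a
per-center random intercept, plus one outcome-conditional mechanism — from
a configurable split year onward, a TDP-43-negative hippocampus makes the
neocortical assessment skipped with probability ``p_skip`` (staging-driven
practice change).

Random substreams are allocated per center and consumed per participant in
cohort order, so enlarging one center never perturbs the records of
another.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import (
    Category,
    CategoryAssignment,
    Subtype,
    classify_tdp,
)
from .records import (
    BRAIN_REGIONS,
    HSA,
    Antibody,
    ClinicalAD,
    ClinicalProfile,
    CognitiveStatus,
    MNInclusion,
    ParticipantRecord,
    PathologyFindings,
    RegionalTDP,
    Sex,
    TriState,
    YesNoMissing,
    is_complete_case,
)

CATS = ("no_tdp43", "other_tdp43", "late_nc", "als_ftld_tdp")


def _per_cat(no, other, late, alsftld):
    return {"no_tdp43": no, "other_tdp43": other, "late_nc": late,
            "als_ftld_tdp": alsftld}


DEFAULT_PREVALENCES = _per_cat(0.62, 0.02, 0.27, 0.09)
DEFAULT_SUBTYPE_SPLIT = {"ftld_only": 0.79, "als_only": 0.05, "both": 0.16}

DEFAULT_AGE = _per_cat((78.9, 12.1), (81.0, 12.3), (84.0, 9.5), (71.5, 11.0))
DEFAULT_EDUCATION = _per_cat((15.8, 3.0), (15.2, 2.5), (15.8, 2.9),
                             (15.8, 2.9))
DEFAULT_INTERVAL = _per_cat((2.2, 2.4), (2.4, 3.1), (2.5, 2.6), (1.8, 2.0))
DEFAULT_CDRSB = _per_cat((8.6, 6.7), (10.1, 6.0), (10.9, 5.9), (12.3, 5.8))

# binary covariate / co-pathology rates per category
DEFAULT_RATES: dict[str, dict[str, float]] = {
    "female": _per_cat(0.48, 0.37, 0.52, 0.47),
    "apoe4": _per_cat(0.39, 0.33, 0.58, 0.32),
    "ftd_mutation": _per_cat(0.010, 0.0, 0.0, 0.23),
    "hs_a": _per_cat(0.049, 0.24, 0.27, 0.31),
    "ppa": _per_cat(0.076, 0.10, 0.045, 0.33),
    "bvftd": _per_cat(0.086, 0.17, 0.029, 0.41),
    "ftld_tau": _per_cat(0.22, 0.51, 0.16, 0.17),
    "adnc": _per_cat(0.63, 0.72, 0.85, 0.20),
    "caa": _per_cat(0.30, 0.32, 0.41, 0.12),
    "lewy": _per_cat(0.35, 0.37, 0.52, 0.15),
    "atherosclerosis": _per_cat(0.33, 0.29, 0.43, 0.28),
    "arteriolosclerosis": _per_cat(0.49, 0.59, 0.62, 0.46),
    "infarcts": _per_cat(0.14, 0.12, 0.15, 0.054),
    "microinfarcts": _per_cat(0.23, 0.17, 0.28, 0.13),
    "hemorrhages": _per_cat(0.072, 0.10, 0.057, 0.039),
    "hipp_atrophy": _per_cat(0.38, 0.51, 0.58, 0.66),
    "cortical_atrophy": _per_cat(0.42, 0.46, 0.48, 0.75),
    "lobar_atrophy": _per_cat(0.24, 0.22, 0.19, 0.60),
    "spinal_present": _per_cat(0.01, 0.05, 0.05, 0.45),
}

DEFAULT_COGSTAT = _per_cat(
    (0.17, 0.12, 0.71), (0.073, 0.098, 0.83),
    (0.059, 0.071, 0.87), (0.043, 0.038, 0.92))   # normal, mci, dementia
DEFAULT_CLINAD = _per_cat(
    (0.17, 0.27, 0.56), (0.073, 0.32, 0.61),
    (0.059, 0.12, 0.82), (0.043, 0.68, 0.28))     # no_imp, not_ad, ad
DEFAULT_ANTIBODY = _per_cat(
    (0.71, 0.284, 0.006), (0.76, 0.24, 0.0),
    (0.79, 0.203, 0.007), (0.62, 0.38, 0.0))      # phospho, non-phospho, other

# regional presence pattern tables (weights; normalized at load)
DEFAULT_PATTERNS: dict[str, dict[str, float]] = {
    "late_nc": {
        "amygdala": 0.18,
        "hippocampus": 0.03,
        "ec_itc": 0.03,
        "hippocampus+ec_itc": 0.04,
        "amygdala+ec_itc": 0.06,
        "amygdala+hippocampus": 0.07,
        "amygdala+hippocampus+ec_itc": 0.46,
        "amygdala+hippocampus+neocortex": 0.01,
        "amygdala+hippocampus+ec_itc+neocortex": 0.12,
    },
    "als_ftld_tdp": {
        "amygdala+hippocampus+ec_itc+neocortex": 0.78,
        "hippocampus+ec_itc+neocortex": 0.07,
        "amygdala+ec_itc+neocortex": 0.04,
        "amygdala+hippocampus+ec_itc": 0.06,
        "amygdala+hippocampus": 0.02,
        "hippocampus+ec_itc": 0.02,
        "ec_itc": 0.01,
    },
    "other_tdp43": {
        "amygdala+hippocampus+ec_itc+neocortex": 0.29,
        "neocortex": 0.06,
        "ec_itc+neocortex": 0.11,
        "amygdala+neocortex": 0.05,
        "hippocampus+neocortex": 0.05,
        "amygdala": 0.12,
        "amygdala+hippocampus": 0.10,
        "amygdala+hippocampus+ec_itc": 0.12,
        "hippocampus+ec_itc": 0.10,
    },
}

DEFAULT_OTHER_REASONS = {"cbd": 11, "cte": 6, "tbi_acute": 5,
                         "tbi_chronic": 3, "ftd_mutation": 6,
                         "adad_mutation": 5}

DEFAULT_DX_LABELS: dict[str, dict[str, float]] = {
    "no_tdp43": {"Alzheimer's disease": 0.55, "Lewy body dementia": 0.08,
                 "Vascular dementia": 0.03, "Other impairment": 0.12,
                 "Not impaired": 0.14, "": 0.05,
                 "Primary progressive supranuclear palsy": 0.02,
                 "FTLD Other": 0.01},
    "late_nc": {"Alzheimer's disease": 0.75, "Lewy body dementia": 0.06,
                "Other impairment": 0.06, "Not impaired": 0.05, "": 0.05,
                "Vascular dementia": 0.02, "FTLD Other": 0.01},
    "als_ftld_tdp": {"FTLD Other": 0.30, "FTLD motor neuron disease": 0.15,
                     "Alzheimer's disease": 0.25, "Other impairment": 0.12,
                     "Corticobasal degeneration": 0.07,
                     "Lewy body dementia": 0.03, "Not impaired": 0.03,
                     "": 0.05},
    "other_tdp43": {"Alzheimer's disease": 0.40, "FTLD Other": 0.15,
                    "Corticobasal degeneration": 0.10,
                    "Other impairment": 0.15, "Lewy body dementia": 0.05,
                    "Not impaired": 0.05, "": 0.10},
}


@dataclass
class MissingnessConfig:
    """Measure-wise availability model.

    ``base`` is the availability probability at ``ref_year``; ``slope`` the
    per-year log-odds trend; ``center_sd`` the SD of the per-center,
    per-measure logit intercept.  ``p_skip_neocortex_if_hipp_negative``
    applies only to deaths in ``post_split_year`` or later whose assessed
    hippocampus is TDP-43-negative.
    """

    base: dict[str, float] = field(default_factory=lambda: {
        "amygdala": 0.80, "hippocampus": 0.88, "ec_itc": 0.82,
        "neocortex": 0.82, "spinal_cord": 0.35, "ftld_tdp": 0.88,
        "als": 0.92, "hs_a": 0.95, "antibody": 0.88})
    slope: dict[str, float] = field(default_factory=lambda: {
        "amygdala": 0.18, "hippocampus": 0.18, "ec_itc": 0.18,
        "neocortex": 0.18, "spinal_cord": 0.05, "ftld_tdp": 0.15,
        "als": 0.0, "hs_a": 0.05, "antibody": 0.10})
    center_sd: float = 0.8
    ref_year: int = 2014
    post_split_year: int = 2019
    p_skip_neocortex_if_hipp_negative: float = 0.15
    # fraction of records with no TDP-43-specific stain at all: regional,
    # FTLD-TDP and antibody jointly unavailable (the ALS + HS-A-only class)
    p_no_stain: float = 0.15


@dataclass
class GeneratorConfig:
    n: int = 4326
    n_centers: int = 31
    seed: int = 0
    category_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    subtype_split: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SPLIT))
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE))
    education_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EDUCATION))
    interval_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTERVAL))
    cdrsb_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CDRSB))
    covariate_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_RATES))
    cogstat_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COGSTAT))
    clinad_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLINAD))
    antibody_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ANTIBODY))
    regional_pattern_tables: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_PATTERNS))
    other_reason_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OTHER_REASONS))
    dx_label_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_DX_LABELS))
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    years: tuple[int, int] = (2014, 2022)
    apoe_missing_rate: float = 0.10
    clinical_missing_rate: float = 0.02
    corruption_no_regional_rate: float = 0.0   # designated ALS/FTLD, no regional TDP
    center_prevalence_tilt: float = 0.0        # logit-SD tilt of category mix per center

    def validate(self) -> None:
        for name, vec in (("category_prevalences", self.category_prevalences),
                          ("subtype_split", self.subtype_split)):
            if abs(sum(vec.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1")
            if any(not 0 <= v <= 1 for v in vec.values()):
                raise ValueError(f"{name} rates must lie in [0, 1]")
        for var, rates in self.covariate_rates.items():
            for c, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate {var}[{c}]={v} outside [0, 1]")
        for cat, table in self.regional_pattern_tables.items():
            for pat in table:
                regions = set(pat.split("+")) if pat else set()
                unknown = regions - set(BRAIN_REGIONS)
                if unknown:
                    raise ValueError(
                        f"pattern {pat!r} names unknown regions {unknown}")
                if cat == "late_nc":
                    if not regions:
                        raise ValueError(
                            "late_nc pattern table contains the empty pattern")
                    if "neocortex" in regions and not (
                            {"amygdala", "hippocampus"} <= regions):
                        raise ValueError(
                            f"late_nc pattern {pat!r} is not an admissible "
                            "LATE-NC distribution")
                elif not regions:
                    raise ValueError(
                        f"{cat} pattern table contains the empty pattern")
        # a LATE-NC truth must classify back to LATE-NC: mutation carriers
        # are excluded by definition
        if self.covariate_rates["ftd_mutation"].get("late_nc", 0.0) != 0.0:
            raise ValueError(
                "ftd_mutation rate must be 0 for late_nc truths")


def load_generator_config(path: str) -> GeneratorConfig:
    """Load a YAML config; keys override the defaults field-wise."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    cfg = GeneratorConfig()
    for key, value in doc.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown generator config key: {key!r}")
        if key == "missingness":
            for mk, mv in value.items():
                if not hasattr(cfg.missingness, mk):
                    raise ValueError(f"unknown missingness key: {mk!r}")
                setattr(cfg.missingness, mk, mv)
        elif isinstance(getattr(cfg, key), dict) and isinstance(value, dict) \
                and key in ("covariate_rates", "regional_pattern_tables",
                            "dx_label_model"):
            getattr(cfg, key).update(value)
        else:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


def dump_config(cfg: GeneratorConfig, path: str) -> None:
    """Echo the fully resolved config (with seed) as YAML."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Pre-missingness records and true labels for a generated cohort."""

    records: list[ParticipantRecord]
    labels: pd.DataFrame      # participant_id, center_id, category, subtype, stage


def _choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    keys = list(table)
    p = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _truncnorm(rng, mean, sd, lo, hi):
    # rejection sampling: all configured bounds keep acceptance near 1,
    # and this is ~50x faster than scipy's truncnorm.rvs per draw
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _true_stage(regions: set[str]) -> int:
    if {"amygdala", "hippocampus", "neocortex"} <= regions:
        return 3
    if {"amygdala", "hippocampus"} <= regions:
        return 2
    return 1


def _gen_participant(rng: np.random.Generator, pid: str, center: str,
                     cfg: GeneratorConfig,
                     prevalences: dict[str, float]) -> tuple[
                         ParticipantRecord, str, str, int | None]:
    cat = _choice(rng, prevalences)

    # regional presence pattern
    if cat == "no_tdp43":
        regions: set[str] = set()
    else:
        pat = _choice(rng, cfg.regional_pattern_tables[cat])
        regions = set(pat.split("+")) if pat else set()

    clin = ClinicalProfile()
    subtype = "n/a"
    stage: int | None = None

    regional = RegionalTDP(
        spinal_cord=TriState.PRESENT
        if rng.random() < cfg.covariate_rates["spinal_present"][cat]
        else TriState.ABSENT,
        **{r: TriState.PRESENT if r in regions else TriState.ABSENT
           for r in BRAIN_REGIONS},
    )

    path = PathologyFindings(ftld_tdp=TriState.ABSENT,
                             mn_inclusion=MNInclusion.NONE)
    if cat == "als_ftld_tdp":
        subtype = _choice(rng, cfg.subtype_split)
        if subtype in ("ftld_only", "both"):
            path.ftld_tdp = TriState.PRESENT
        if subtype in ("als_only", "both"):
            path.mn_inclusion = MNInclusion.TDP43
        if cfg.corruption_no_regional_rate and \
                rng.random() < cfg.corruption_no_regional_rate:
            regions = set()
            for r in BRAIN_REGIONS:
                setattr(regional, r, TriState.ABSENT)
        clin.ftd_mutation = (
            rng.random() < cfg.covariate_rates["ftd_mutation"][cat])
    elif cat == "other_tdp43":
        violating = "neocortex" in regions and not (
            {"amygdala", "hippocampus"} <= regions)
        need_flag = not violating or rng.random() < 0.3
        if need_flag:
            reason = _choice(rng, {k: float(v) for k, v in
                                   cfg.other_reason_weights.items()})
            if reason == "ftd_mutation":
                clin.ftd_mutation = True
            elif reason == "adad_mutation":
                clin.adad_mutation = True
            else:
                setattr(path, reason, True)
    elif cat == "late_nc":
        stage = _true_stage(regions)
    else:  # no_tdp43: rare non-TDP motor-neuron inclusions
        u = rng.random()
        if u < 0.001:
            path.mn_inclusion = MNInclusion.FUS
        elif u < 0.002:
            path.mn_inclusion = MNInclusion.SOD1
        elif u < 0.004:
            path.mn_inclusion = MNInclusion.OTHER
        clin.ftd_mutation = (
            rng.random() < cfg.covariate_rates["ftd_mutation"][cat])

    rates = cfg.covariate_rates
    hs_present = rng.random() < rates["hs_a"][cat]
    if hs_present:
        path.hs_a = [HSA.UNILATERAL, HSA.BILATERAL, HSA.LATERALITY_UNKNOWN][
            rng.choice(3, p=[0.5, 0.3, 0.2])]
    else:
        path.hs_a = HSA.ABSENT
    ab = rng.choice(3, p=np.array(cfg.antibody_probs[cat])
                    / sum(cfg.antibody_probs[cat]))
    path.tdp_antibody = [Antibody.PHOSPHO, Antibody.NON_PHOSPHO,
                         Antibody.OTHER][ab]

    def tri(name):
        return TriState.PRESENT if rng.random() < rates[name][cat] \
            else TriState.ABSENT

    def dich(name):
        from .records import Dichotomous
        return Dichotomous.HIGH if rng.random() < rates[name][cat] \
            else Dichotomous.LOW

    path.ftld_tau = tri("ftld_tau")
    path.adnc = dich("adnc")
    path.caa = dich("caa")
    path.lewy_any = tri("lewy")
    path.atherosclerosis = dich("atherosclerosis")
    path.arteriolosclerosis = dich("arteriolosclerosis")
    path.infarcts = tri("infarcts")
    path.microinfarcts = tri("microinfarcts")
    path.hemorrhages = tri("hemorrhages")
    path.hipp_atrophy = dich("hipp_atrophy")
    path.cortical_atrophy = dich("cortical_atrophy")
    path.lobar_atrophy = tri("lobar_atrophy")

    clin.age_at_death = _truncnorm(rng, *cfg.age_params[cat], 40.0, 110.0)
    clin.sex = Sex.FEMALE if rng.random() < rates["female"][cat] else Sex.MALE
    clin.education = (math.nan if rng.random() < cfg.clinical_missing_rate
                      else _truncnorm(rng, *cfg.education_params[cat],
                                      0.0, 30.0))
    clin.interval_visit_death = _truncnorm(
        rng, *cfg.interval_params[cat], 0.0, 30.0)
    if rng.random() < cfg.apoe_missing_rate:
        clin.apoe4 = YesNoMissing.MISSING
    else:
        clin.apoe4 = (YesNoMissing.PRESENT
                      if rng.random() < rates["apoe4"][cat]
                      else YesNoMissing.ABSENT)
    cs = rng.choice(3, p=np.array(cfg.cogstat_probs[cat])
                    / sum(cfg.cogstat_probs[cat]))
    clin.cognitive_status = [CognitiveStatus.NORMAL,
                             CognitiveStatus.MCI_IMPAIRED,
                             CognitiveStatus.DEMENTIA][cs]
    clin.cdr_sb = (math.nan if rng.random() < cfg.clinical_missing_rate
                   else _truncnorm(rng, *cfg.cdrsb_params[cat], 0.0, 18.0))
    ca = rng.choice(3, p=np.array(cfg.clinad_probs[cat])
                    / sum(cfg.clinad_probs[cat]))
    clin.clinical_ad = [ClinicalAD.NO_IMPAIRMENT, ClinicalAD.NOT_AD,
                        ClinicalAD.AD][ca]
    for attr, rate in (("ppa", rates["ppa"][cat]),
                       ("bvftd", rates["bvftd"][cat])):
        if rng.random() < cfg.clinical_missing_rate:
            setattr(clin, attr, YesNoMissing.MISSING)
        else:
            setattr(clin, attr, YesNoMissing.PRESENT
                    if rng.random() < rate else YesNoMissing.ABSENT)
    clin.etiologic_dx_raw = _choice(rng, cfg.dx_label_model[cat]) or None
    clin.year_of_death = int(rng.integers(cfg.years[0], cfg.years[1] + 1))
    clin.deceased = True
    clin.autopsied = True

    rec = ParticipantRecord(participant_id=pid, center_id=center,
                            regional=regional, path=path, clinical=clin)
    return rec, cat, subtype, stage


def generate_cohort(
    cfg: GeneratorConfig,
) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Generate a multicenter cohort plus its ground truth (pre-missingness).

    Deterministic given ``cfg.seed``; centers get uneven sizes drawn from a
    Dirichlet weight vector.  Exclusionary flags are emitted only for
    other-TDP-43 truths, so classification recovers the truth exactly on
    complete cases.
    """
    cfg.validate()
    root = np.random.SeedSequence([int(cfg.seed), 0])
    struct_ss, *center_ss = root.spawn(1 + cfg.n_centers)
    struct_rng = np.random.default_rng(struct_ss)
    weights = struct_rng.dirichlet(np.full(cfg.n_centers, 4.0))
    sizes = struct_rng.multinomial(cfg.n, weights)

    prevalences_by_center = []
    for j in range(cfg.n_centers):
        prev = dict(cfg.category_prevalences)
        if cfg.center_prevalence_tilt > 0:
            logits = np.log(np.maximum(
                [prev[c] for c in CATS], 1e-12))
            logits = logits + struct_rng.normal(
                0.0, cfg.center_prevalence_tilt, size=len(CATS))
            p = np.exp(logits - logits.max())
            p /= p.sum()
            prev = dict(zip(CATS, p))
        prevalences_by_center.append(prev)

    cohort: list[ParticipantRecord] = []
    labels = []
    idx = 0
    for j in range(cfg.n_centers):
        rng = np.random.default_rng(center_ss[j])
        center = f"C{j + 1:03d}"
        for _ in range(sizes[j]):
            idx += 1
            pid = f"P{idx:06d}"
            rec, cat, subtype, stage = _gen_participant(
                rng, pid, center, cfg, prevalences_by_center[j])
            cohort.append(rec)
            labels.append({"participant_id": pid, "center_id": center,
                           "category": cat, "subtype": subtype,
                           "stage": stage})
    truth = GroundTruth(records=[copy.deepcopy(r) for r in cohort],
                        labels=pd.DataFrame(
                            labels, columns=["participant_id", "center_id",
                                             "category", "subtype", "stage"]))
    return cohort, truth


_MEASURE_FIELDS = {
    "amygdala": ("regional", "amygdala", TriState.NOT_ASSESSED),
    "hippocampus": ("regional", "hippocampus", TriState.NOT_ASSESSED),
    "ec_itc": ("regional", "ec_itc", TriState.NOT_ASSESSED),
    "neocortex": ("regional", "neocortex", TriState.NOT_ASSESSED),
    "spinal_cord": ("regional", "spinal_cord", TriState.NOT_ASSESSED),
    "ftld_tdp": ("path", "ftld_tdp", TriState.NOT_ASSESSED),
    "als": ("path", "mn_inclusion", MNInclusion.NOT_ASSESSED),
    "hs_a": ("path", "hs_a", HSA.NOT_ASSESSED),
    "antibody": ("path", "tdp_antibody", Antibody.NOT_LISTED),
}


def apply_missingness(
    cohort: Sequence[ParticipantRecord],
    truth: GroundTruth,
    cfg: GeneratorConfig,
) -> list[ParticipantRecord]:
    """Inject not-assessed values measure-wise; truth keeps the full values.

    Availability per measure follows the configured logistic year trend
    with per-center intercepts.  For deaths in or after the split year with
    an assessed, TDP-43-negative hippocampus, the neocortical assessment is
    additionally dropped with probability ``p_skip``.
    """
    mc = cfg.missingness
    out = [copy.deepcopy(r) for r in cohort]
    centers = sorted({r.center_id for r in out})
    root = np.random.SeedSequence([int(cfg.seed), 1])
    center_streams = dict(zip(centers, root.spawn(len(centers))))
    rngs = {c: np.random.default_rng(s) for c, s in center_streams.items()}
    intercepts = {
        c: {m: rngs[c].normal(0.0, mc.center_sd) for m in _MEASURE_FIELDS}
        for c in centers}

    stain_measures = {"amygdala", "hippocampus", "ec_itc", "neocortex",
                      "spinal_cord", "ftld_tdp", "antibody"}
    for rec in out:
        rng = rngs[rec.center_id]
        year = rec.clinical.year_of_death or mc.ref_year
        no_stain = rng.random() < mc.p_no_stain
        for m, (holder, attr, na) in _MEASURE_FIELDS.items():
            if no_stain and m in stain_measures:
                setattr(getattr(rec, holder), attr, na)
            base = mc.base[m]
            logit = math.log(base / (1 - base)) if 0 < base < 1 else (
                math.inf if base >= 1 else -math.inf)
            logit += mc.slope[m] * (year - mc.ref_year)
            logit += intercepts[rec.center_id][m]
            p_avail = 1.0 / (1.0 + math.exp(-logit)) if math.isfinite(logit) \
                else (1.0 if logit > 0 else 0.0)
            if rng.random() >= p_avail:
                setattr(getattr(rec, holder), attr, na)
        hipp = rec.regional.hippocampus
        if (year >= mc.post_split_year and hipp is TriState.ABSENT
                and rng.random() < mc.p_skip_neocortex_if_hipp_negative):
            rec.regional.neocortex = TriState.NOT_ASSESSED
    return out


@dataclass
class RoundTripReport:
    n_complete: int
    n_agree: int
    mismatches: list[tuple[str, str, str]]    # id, truth label, predicted
    confusion: pd.DataFrame

    @property
    def agreement(self) -> float:
        return self.n_agree / self.n_complete if self.n_complete else 1.0


def round_trip_check(
    cohort: Sequence[ParticipantRecord],
    truth: GroundTruth,
) -> RoundTripReport:
    """Classify the complete cases and compare category / subtype / stage
    to the generator's ground truth."""
    lab = truth.labels.set_index("participant_id")
    mism: list[tuple[str, str, str]] = []
    pairs = []
    n_complete = 0
    for rec in cohort:
        if not is_complete_case(rec):
            continue
        n_complete += 1
        a = classify_tdp(rec)
        row = lab.loc[rec.participant_id]
        t_label = (row["category"], row["subtype"],
                   None if pd.isna(row["stage"]) else int(row["stage"]))
        p_label = (a.category.value, a.subtype.value, a.stage)
        pairs.append((row["category"], a.category.value))
        if t_label != p_label:
            mism.append((rec.participant_id, str(t_label), str(p_label)))
    conf = pd.crosstab(
        pd.Series([t for t, _ in pairs], name="truth"),
        pd.Series([p for _, p in pairs], name="predicted"),
    ) if pairs else pd.DataFrame()
    return RoundTripReport(n_complete=n_complete,
                           n_agree=n_complete - len(mism),
                           mismatches=mism, confusion=conf)


# ---------------------------------------------------------------------------
# inactive-participant population for follow-up / autopsy models


DEFAULT_DX_MIX = {"AD": 0.45, "FTLD": 0.03, "CBD_PSP": 0.02, "LB": 0.05,
                  "VASCULAR": 0.03, "OTHER_IMPAIRED": 0.12,
                  "NOT_IMPAIRED": 0.20, "UNAVAILABLE": 0.10}
DEFAULT_FOLLOWUP_OR = {"FTLD": 2.0, "CBD_PSP": 3.5, "LB": 1.9,
                       "VASCULAR": 0.75, "OTHER_IMPAIRED": 0.43,
                       "NOT_IMPAIRED": 0.26, "UNAVAILABLE": 0.35}
DEFAULT_AUTOPSY_OR = {"FTLD": 1.8, "CBD_PSP": 1.8, "LB": 1.2,
                      "VASCULAR": 0.70, "OTHER_IMPAIRED": 1.0,
                      "NOT_IMPAIRED": 0.63, "UNAVAILABLE": 0.71}


@dataclass
class InactivePopulationConfig:
    """Planted-effect model for the no-longer-active participant table."""

    n: int = 31105
    n_centers: int = 45
    seed: int = 0
    dx_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DX_MIX))
    followup_base_rate: float = 0.50       # AD reference follow-up-to-death
    autopsy_base_rate: float = 0.58        # AD reference autopsy | deceased
    followup_or: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLLOWUP_OR))
    autopsy_or: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AUTOPSY_OR))
    center_sd: float = 0.3


def generate_inactive_population(
    cfg: InactivePopulationConfig,
) -> pd.DataFrame:
    """Inactive-participant table with planted follow-up / autopsy odds
    ratios per diagnosis category (reference AD) and per-center logit
    intercepts; columns participant_id, center_id, dx_category, deceased,
    autopsied."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 2]))
    cats = list(cfg.dx_mix)
    p = np.array([cfg.dx_mix[c] for c in cats], dtype=float)
    p /= p.sum()
    dx = rng.choice(cats, size=cfg.n, p=p)
    centers = rng.integers(0, cfg.n_centers, size=cfg.n)
    u_f = rng.normal(0.0, cfg.center_sd, size=cfg.n_centers)
    u_a = rng.normal(0.0, cfg.center_sd, size=cfg.n_centers)

    def logit(x):
        return math.log(x / (1 - x))

    lf = np.full(cfg.n, logit(cfg.followup_base_rate))
    la = np.full(cfg.n, logit(cfg.autopsy_base_rate))
    for c, or_ in cfg.followup_or.items():
        lf[dx == c] += math.log(or_)
    for c, or_ in cfg.autopsy_or.items():
        la[dx == c] += math.log(or_)
    lf += u_f[centers]
    la += u_a[centers]
    deceased = rng.random(cfg.n) < 1.0 / (1.0 + np.exp(-lf))
    autopsied = deceased & (rng.random(cfg.n) < 1.0 / (1.0 + np.exp(-la)))
    return pd.DataFrame({
        "participant_id": [f"I{i:06d}" for i in range(1, cfg.n + 1)],
        "center_id": [f"C{c + 1:03d}" for c in centers],
        "dx_category": dx,
        "deceased": deceased,
        "autopsied": autopsied,
    })
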