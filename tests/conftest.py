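"""Shared fixtures: terse builders for coded participant records."""

from __future__ import annotations

import itertools

import pytest

from tdpengine.records import (
    HSA,
    Antibody,
    ClinicalProfile,
    MNInclusion,
    ParticipantRecord,
    PathologyFindings,
    RegionalTDP,
    TriState,
)

_TRI = {"present": TriState.PRESENT, "absent": TriState.ABSENT,
        "na": TriState.NOT_ASSESSED}
_HSA = {"absent": HSA.ABSENT, "unilateral": HSA.UNILATERAL,
        "bilateral": HSA.BILATERAL, "unknown": HSA.LATERALITY_UNKNOWN,
        "na": HSA.NOT_ASSESSED}

_COUNTER = itertools.count(1)


def make_record(
    pid: str | None = None,
    center: str = "C001",
    spinal="na",
    amygdala="absent",
    hippocampus="absent",
    ec_itc="absent",
    neocortex="absent",
    ftld_tdp="absent",
    mn_inclusion="none",
    hs_a="absent",
    antibody="phospho",
    path_kw: dict | None = None,
    clinical_kw: dict | None = None,
) -> ParticipantRecord:
    """One participant record from compact string arguments.

    Tri-state arguments accept "present"/"absent"/"na"; HS-A additionally
    the laterality levels; extra pathology / clinical fields go through
    ``path_kw`` / ``clinical_kw``.
    """
    if pid is None:
        pid = f"T{next(_COUNTER):06d}"
    path = PathologyFindings(
        ftld_tdp=_TRI[ftld_tdp],
        mn_inclusion=MNInclusion(mn_inclusion),
        hs_a=_HSA[hs_a],
        tdp_antibody=Antibody(antibody),
        **(path_kw or {}),
    )
    return ParticipantRecord(
        participant_id=pid,
        center_id=center,
        regional=RegionalTDP(
            spinal_cord=_TRI[spinal],
            amygdala=_TRI[amygdala],
            hippocampus=_TRI[hippocampus],
            ec_itc=_TRI[ec_itc],
            neocortex=_TRI[neocortex],
        ),
        path=path,
        clinical=ClinicalProfile(**(clinical_kw or {})),
    )


@pytest.fixture
def record_factory():
    return make_record
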