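"""Reading and writing cohorts in the coded-CSV dialect."""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .dialect import COLUMNS, Dialect
from .records import (
    HSA,
    Antibody,
    ClinicalAD,
    ClinicalProfile,
    CognitiveStatus,
    Dichotomous,
    MNInclusion,
    ParticipantRecord,
    PathologyFindings,
    RegionalTDP,
    Sex,
    TriState,
    YesNoMissing,
    is_complete_case,
)

_ENUM_FOR_KIND = {
    "tristate": TriState,
    "mn": MNInclusion,
    "hsa": HSA,
    "antibody": Antibody,
    "dich": Dichotomous,
    "sex": Sex,
    "cogstat": CognitiveStatus,
    "clinad": ClinicalAD,
    "ynm": YesNoMissing,
}


class ParseError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def _set_path(rec_parts: dict, path: str, value) -> None:
    if "." in path:
        holder, attr = path.split(".", 1)
        rec_parts[holder][attr] = value
    else:
        rec_parts[path] = value


def parse_records(
    path: str,
    dialect: Dialect | None = None,
) -> list[ParticipantRecord]:
    """Parse a coded cohort CSV into participant records.

    Unknown / blank codes map to not-assessed or missing per the dialect;
    row order is preserved.  Raises :class:`ParseError` naming the offending
    row and column for an unmappable code, and :class:`ValidationError` for
    duplicate participant IDs.
    """
    d = dialect or Dialect()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records: list[ParticipantRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = dict(zip(df.columns, row))
        parts: dict = {"regional": {}, "path": {}, "clinical": {}}
        for col, attr_path, kind in COLUMNS:
            if col not in raw:
                continue
            cell = raw[col].strip()
            if kind == "str":
                value: object = cell
            elif kind == "optstr":
                value = cell or None
            elif kind == "float":
                value = float(cell) if cell else math.nan
            elif kind == "optint":
                value = int(cell) if cell else None
            else:
                try:
                    decoded = d.decode(kind, cell)
                except KeyError:
                    raise ParseError(
                        f"row {i}, column {col}: unmappable code {cell!r}"
                    ) from None
                if kind == "flag":
                    value = decoded == "true"
                else:
                    value = _ENUM_FOR_KIND[kind](decoded)
            _set_path(parts, attr_path, value)
        pid = parts.get("participant_id", "")
        if pid in seen:
            raise ValidationError(f"duplicate participant_id: {pid!r}")
        seen.add(pid)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                center_id=parts.get("center_id", ""),
                regional=RegionalTDP(**parts["regional"]),
                path=PathologyFindings(**parts["path"]),
                clinical=ClinicalProfile(**parts["clinical"]),
            )
        )
    return records


def _get_path(rec: ParticipantRecord, path: str):
    obj = rec
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def _fmt_float(x: float) -> str:
    if math.isnan(x):
        return ""
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_records(
    cohort: Sequence[ParticipantRecord],
    path: str,
    dialect: Dialect | None = None,
) -> None:
    """Re-emit a cohort in the coded dialect; inverse of :func:`parse_records`."""
    d = dialect or Dialect()
    rows = []
    for rec in cohort:
        row: dict[str, str] = {}
        for col, attr_path, kind in COLUMNS:
            v = _get_path(rec, attr_path)
            if kind == "str":
                row[col] = str(v)
            elif kind == "optstr":
                row[col] = "" if v is None else str(v)
            elif kind == "float":
                row[col] = _fmt_float(v)
            elif kind == "optint":
                row[col] = "" if v is None else str(int(v))
            elif kind == "flag":
                row[col] = d.encode(kind, "true" if v else "false")
            else:
                row[col] = d.encode(kind, v.value)
        rows.append(row)
    pd.DataFrame(rows, columns=[c for c, _, _ in COLUMNS]).to_csv(
        path, index=False)


def validation_report(cohort: Sequence[ParticipantRecord]) -> dict:
    """Summary counts used by the pipeline's JSON validation report."""
    n = len(cohort)
    complete = sum(is_complete_case(r) for r in cohort)
    return {
        "n_records": n,
        "n_centers": len({r.center_id for r in cohort}),
        "n_complete_case": complete,
        "n_autopsied": sum(r.clinical.autopsied for r in cohort),
        "n_with_year_of_death": sum(
            r.clinical.year_of_death is not None for r in cohort),
    }
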