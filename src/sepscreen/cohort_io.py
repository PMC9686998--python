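"""Cohort file formats.

One row per patient, explicit empty-string NA token, ICD-10 codes as a
semicolon-delimited list of ``code|label`` pairs. A ``#``-prefixed header
comment records the seed and band-table checksum for provenance. A
JSON-lines alternative carries the same fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Avpu, Icd10Code, LabPanel, PaO2Unit, PatientRecord, VitalSet

_VITAL_COLS = ("respiratory_rate", "spo2", "supplemental_o2", "fio2",
               "temperature", "systolic_bp", "heart_rate", "gcs", "avpu")
_LAB_COLS = ("pao2", "pao2_unit", "lab_fio2", "platelets", "bilirubin",
             "map", "vasopressor", "creatinine")
_OUTCOME_COLS = ("suspected_infection", "icu_admission", "death_28d")

COLUMNS = ("id",) + _VITAL_COLS + _LAB_COLS + ("icd10_codes",) + _OUTCOME_COLS


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, Avpu):
        return value.name
    if isinstance(value, PaO2Unit):
        return value.value
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def record_to_row(r: PatientRecord) -> dict:
    row = {"id": r.id}
    for c in _VITAL_COLS:
        row[c] = _fmt(getattr(r.vitals, c))
    labs = r.labs
    row.update({
        "pao2": _fmt(labs.pao2),
        "pao2_unit": _fmt(labs.pao2_unit) if labs.pao2 is not None else "",
        "lab_fio2": _fmt(labs.fio2),
        "platelets": _fmt(labs.platelets),
        "bilirubin": _fmt(labs.bilirubin),
        "map": _fmt(labs.map),
        "vasopressor": _fmt(labs.vasopressor),
        "creatinine": _fmt(labs.creatinine),
    })
    row["icd10_codes"] = ";".join(f"{c.code}|{c.label}" for c in r.icd10_codes)
    for c in _OUTCOME_COLS:
        row[c] = _fmt(getattr(r, c))
    return row


def _parse(value: str, kind):
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    if kind is bool:
        return {"true": True, "false": False}[str(value).strip().lower()]
    if kind is Avpu:
        return Avpu.parse(value)
    return kind(value)


def row_to_record(row: dict) -> PatientRecord:
    vitals = VitalSet(
        respiratory_rate=_parse(row.get("respiratory_rate"), lambda v: int(float(v))),
        spo2=_parse(row.get("spo2"), float),
        supplemental_o2=_parse(row.get("supplemental_o2"), bool),
        fio2=_parse(row.get("fio2"), float),
        temperature=_parse(row.get("temperature"), float),
        systolic_bp=_parse(row.get("systolic_bp"), float),
        heart_rate=_parse(row.get("heart_rate"), float),
        gcs=_parse(row.get("gcs"), lambda v: int(float(v))),
        avpu=_parse(row.get("avpu"), Avpu),
    )
    unit = _parse(row.get("pao2_unit"), str)
    labs = LabPanel(
        pao2=_parse(row.get("pao2"), float),
        pao2_unit=PaO2Unit(unit) if unit else PaO2Unit.MMHG,
        fio2=_parse(row.get("lab_fio2"), float),
        platelets=_parse(row.get("platelets"), float),
        bilirubin=_parse(row.get("bilirubin"), float),
        map=_parse(row.get("map"), float),
        vasopressor=_parse(row.get("vasopressor"), bool),
        creatinine=_parse(row.get("creatinine"), float),
    )
    raw_codes = row.get("icd10_codes") or ""
    if isinstance(raw_codes, float):
        raw_codes = ""
    codes = tuple(
        Icd10Code(*(pair.split("|", 1) + [""])[:2])
        for pair in str(raw_codes).split(";") if pair
    )
    return PatientRecord(
        id=str(row["id"]),
        vitals=vitals,
        labs=labs,
        icd10_codes=codes,
        suspected_infection=_parse(row.get("suspected_infection"), bool) or False,
        icu_admission=_parse(row.get("icu_admission"), bool) or False,
        death_28d=_parse(row.get("death_28d"), bool) or False,
    )


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path,
                     seed: Optional[int] = None, config_checksum: str = "") -> None:
    """Write a cohort CSV with a provenance comment line."""
    path = Path(path)
    header = f"# sepscreen cohort v1 seed={seed if seed is not None else 'NA'} bands={config_checksum or 'NA'}\n"
    frame = pd.DataFrame([record_to_row(r) for r in records], columns=list(COLUMNS))
    with open(path, "w", newline="") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    frame = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    return [row_to_record(row) for row in frame.to_dict("records")]


def write_cohort_jsonl(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(record_to_row(r)) + "\n")


def read_cohort_jsonl(path: str | Path) -> list[PatientRecord]:
    with open(path) as fh:
        return [row_to_record(json.loads(line)) for line in fh if line.strip()]
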