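"""Cohort CSV reading/writing and record/DataFrame conversion.

The cohort schema is one row per subject-year:

    subject_id,year,age,sex,sbp,dbp,glucose,hba1c,ldl,creatinine,
    dipstick,bmi,waist,on_bp_med,on_dm_med,on_lipid_med

with dipstick serialized as ``neg|trace|1+|2+`` (grades above 2+ must be
truncated to 2+ before entry) and booleans as 0/1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .cohort import CheckupRecord
from .staging import Dipstick

log = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "subject_id", "year", "age", "sex", "sbp", "dbp", "glucose", "hba1c",
    "ldl", "creatinine", "dipstick", "bmi", "waist",
    "on_bp_med", "on_dm_med", "on_lipid_med",
]
_BOOL_COLUMNS = ["on_bp_med", "on_dm_med", "on_lipid_med"]


def records_to_frame(records) -> pd.DataFrame:
    """Record collection -> DataFrame in schema order (dipstick as label)."""
    rows = [{
        **{c: getattr(r, c) for c in COHORT_COLUMNS if c != "dipstick"},
        "dipstick": r.dipstick.label,
    } for r in records]
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[CheckupRecord]:
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(CheckupRecord(
                subject_id=int(row.subject_id), year=int(row.year),
                age=float(row.age), sex=str(row.sex), sbp=float(row.sbp),
                dbp=float(row.dbp), glucose=float(row.glucose),
                hba1c=float(row.hba1c), ldl=float(row.ldl),
                creatinine=float(row.creatinine),
                dipstick=Dipstick.from_label(str(row.dipstick)),
                bmi=float(row.bmi), waist=float(row.waist),
                on_bp_med=bool(int(row.on_bp_med)),
                on_dm_med=bool(int(row.on_dm_med)),
                on_lipid_med=bool(int(row.on_lipid_med))))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed row {idx + 2} (1-based, incl. "
                             f"header): {exc}") from exc
    return records


def write_cohort_csv(records, path) -> None:
    """Write records to CSV; floats at full precision for lossless round trip."""
    df = records_to_frame(records)
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype(int)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_cohort_csv(path) -> list[CheckupRecord]:
    """Read a cohort CSV, validating schema and dipstick labels.

    Unknown or missing columns are rejected; a malformed cell raises an
    error naming the row and offending value.  An empty file yields an
    empty collection with a warning.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        log.warning("cohort file %s is empty", path)
        return []
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and len(df.columns) <= 1:
        log.warning("cohort file %s has no data rows", path)
        return []
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if extra or missing:
        raise ValueError(
            f"cohort CSV schema mismatch in {path}: unknown columns {extra}, "
            f"missing columns {missing}")
    return frame_to_records(df[COHORT_COLUMNS])
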