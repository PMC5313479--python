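"""Tabular I/O: cohort CSV schema, record parsing, score/report writers.

Cohort CSVs are UTF-8, comma-separated, "." decimal; missing values are
empty cells.  One column per lab marker (by marker id) and per item id;
unknown columns are preserved but ignored by scoring.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import InstrumentDefinition
from .scoring import PatientRecord

MANDATORY_COLUMNS = (
    "subject_id", "group", "weight_current", "weight_preillness",
)


class CohortSchemaError(ValueError):
    pass


def check_cohort_schema(
    cohort: pd.DataFrame, instrument: InstrumentDefinition | None = None
) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"missing mandatory columns: {', '.join(missing)}")


def read_cohort_csv(
    path: str | Path, instrument: InstrumentDefinition | None = None
) -> pd.DataFrame:
    """Read and type-check a cohort table.

    Numeric columns that fail to parse raise with the offending column
    named; per-cell problems become NaN only for genuinely empty cells.
    """
    path = Path(path)
    if not path.exists():
        raise CohortSchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    check_cohort_schema(df, instrument)
    numeric_like = [
        c for c in df.columns
        if c not in ("subject_id", "group", "sex", "tumor_site")
    ]
    for col in numeric_like:
        cleaned = df[col].replace("", np.nan)
        try:
            df[col] = pd.to_numeric(cleaned)
        except (ValueError, TypeError):
            # leave as strings; scoring flags the offending rows
            df[col] = cleaned
    return df


def _cell(row, name):
    if name not in row:
        return None
    value = row[name]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        return float(value)  # raises ValueError for unparseable cells
    return value


def record_from_row(
    row: pd.Series, instrument: InstrumentDefinition
) -> PatientRecord:
    """Build a PatientRecord from one cohort-table row."""
    labs = {}
    for rule in instrument.marker_rules():
        value = _cell(row, rule.marker_id)
        if value is not None:
            labs[rule.marker_id] = float(value)
    responses = {}
    for item in instrument.items():
        value = _cell(row, item.item_id)
        if value is not None:
            responses[item.item_id] = int(value)
    lbm = _cell(row, "lbm_depleted")
    ecog = _cell(row, "ecog")
    clin = _cell(row, "clinician_rating")
    sex = row.get("sex")
    return PatientRecord(
        subject_id=str(row["subject_id"]),
        group=str(row.get("group", "cancer")),
        sex=str(sex) if isinstance(sex, str) and sex else None,
        age=_cell(row, "age"),
        weight_current=_cell(row, "weight_current"),
        weight_preillness=_cell(row, "weight_preillness"),
        lbm_depleted=None if lbm is None else bool(lbm),
        labs=labs,
        responses=responses,
        ecog=None if ecog is None else int(ecog),
        clinician_rating=None if clin is None else int(clin),
    )


def write_scores_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)


def write_scores_jsonl(scores: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for record in scores.to_dict(orient="records"):
            fh.write(json.dumps(record, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(payload, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
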