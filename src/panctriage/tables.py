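"""Reading and writing the five linked tables as RFC-4180 CSV (UTF-8,
ISO-8601 dates), with row-level validation that reports file, line and
field on failure."""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd

#: table name -> (columns, date columns, numeric columns, optional columns)
TABLE_SCHEMAS: dict[str, tuple[list[str], list[str], list[str], list[str]]] = {
    "patients": (
        ["patient_id", "sex", "birth_date", "bmi", "seifa_percentile"],
        ["birth_date"],
        ["bmi", "seifa_percentile"],
        ["bmi", "seifa_percentile"],
    ),
    "encounters": (["patient_id", "encounter_date", "reason_text"], ["encounter_date"], [], []),
    "pathology": (
        ["patient_id", "result_date", "analyte", "value", "units"],
        ["result_date"],
        ["value"],
        [],
    ),
    "prescriptions": (["patient_id", "script_date", "medication_name"], ["script_date"], [], []),
    "registry": (["patient_id", "diagnosis_date", "icd10_code"], ["diagnosis_date"], [], []),
}


class TableParseError(ValueError):
    """Malformed row in a table file; message cites file, line and field."""


def write_tables(tables: dict[str, pd.DataFrame], directory) -> dict[str, Path]:
    """Write each table to ``<directory>/<name>.csv``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, (columns, _, _, _) in TABLE_SCHEMAS.items():
        if name not in tables:
            continue
        df = tables[name].reindex(columns=columns)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
        paths[name] = path
    return paths


def read_tables(directory) -> dict[str, pd.DataFrame]:
    """Read and validate every present table file in ``directory``."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, (columns, date_cols, num_cols, optional) in TABLE_SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise TableParseError(f"{path}: missing column(s) {missing}")
        df = df[columns]
        for col in date_cols:
            for idx, raw in df[col].items():
                try:
                    _dt.date.fromisoformat(raw)
                except ValueError as err:
                    # +2: header line plus 1-based indexing
                    raise TableParseError(
                        f"{path}: line {idx + 2}, field {col!r}: bad date {raw!r}"
                    ) from err
        for col in num_cols:
            blank_ok = col in optional
            for idx, raw in df[col].items():
                if raw == "" and blank_ok:
                    continue
                try:
                    float(raw)
                except ValueError as err:
                    raise TableParseError(
                        f"{path}: line {idx + 2}, field {col!r}: bad number {raw!r}"
                    ) from err
            df[col] = pd.to_numeric(df[col].replace("", None))
        tables[name] = df
    return tables


def tables_equal(a: dict[str, pd.DataFrame], b: dict[str, pd.DataFrame]) -> bool:
    """Value equality across table dicts, treating None and NaN as equal and
    comparing numbers numerically regardless of dtype."""
    if set(a) != set(b):
        return False
    for name in a:
        columns, _, num_cols, _ = TABLE_SCHEMAS[name]
        da, db = a[name].reindex(columns=columns), b[name].reindex(columns=columns)
        if len(da) != len(db):
            return False
        for col in columns:
            if col in num_cols:
                xa = pd.to_numeric(da[col], errors="coerce")
                xb = pd.to_numeric(db[col], errors="coerce")
                if not ((xa.isna() == xb.isna()).all() and
                        (xa.fillna(0.0) - xb.fillna(0.0)).abs().max() <= 1e-9):
                    return False
            else:
                sa = da[col].astype(str).replace("nan", "").replace("None", "")
                sb = db[col].astype(str).replace("nan", "").replace("None", "")
                if not (sa.values == sb.values).all():
                    return False
    return True
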