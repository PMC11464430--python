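"""CSV schemas and validated table reading.

All inputs are plain UTF-8, comma-separated, dot-decimal CSV with a header
row.  Parsing is strict: a missing column, a non-numeric cell (including a
stray thousands separator such as ``2,400``) or a duplicated key raises an
error naming the offending row and column — values are never coerced
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

import yaml


@dataclass(frozen=True)
class TableSchema:
    name: str
    numeric_columns: tuple[str, ...]
    other_columns: tuple[str, ...] = ()
    key_columns: tuple[str, ...] = ()

    @property
    def required(self) -> tuple[str, ...]:
        return self.other_columns + self.numeric_columns


CALIBRATION_SCHEMA = TableSchema(
    name="calibration",
    numeric_columns=("level_ng_per_ml", "analyte_area", "is_area"),
    other_columns=("sample_id", "replicate"),
)

TIMECOURSE_SCHEMA = TableSchema(
    name="timecourse",
    numeric_columns=("time_min", "conc_ng_per_ml"),
    other_columns=("replicate",),
    key_columns=("time_min", "replicate"),
)

QC_SCHEMA = TableSchema(
    name="qc",
    numeric_columns=("level_ng_per_ml", "conc_ng_per_ml"),
    other_columns=("replicate",),
)

LEVEL_SUMMARY_SCHEMA = TableSchema(
    name="level_summary",
    numeric_columns=("nominal_ng_per_ml", "mean_ng_per_ml", "sd_ng_per_ml", "recovery_percent"),
)

GREENNESS_SCHEMA = TableSchema(
    name="greenness",
    numeric_columns=("criterion", "score", "weight"),
)


class TableFormatError(ValueError):
    """Raised when an input CSV violates its schema."""


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema.

    Numeric columns are parsed cell-by-cell so that errors can name the
    exact (row, column) location; row numbers refer to the data rows of the
    file (header = row 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path}: file is empty") from None
    missing = [c for c in schema.required if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}; found {list(raw.columns)}")
    unknown = [c for c in raw.columns if c not in schema.required]
    if unknown:
        raise TableFormatError(f"{path}: unknown column(s) {unknown} for {schema.name} schema")
    if raw.empty:
        raise TableFormatError(f"{path}: no data rows")
    out = raw.copy()
    for col in schema.numeric_columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise TableFormatError(
                f"{path}: non-numeric value {raw.loc[bad.idxmax(), col]!r} in column {col!r}, data row {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 1
            raise TableFormatError(f"{path}: empty cell in column {col!r}, data row {row}")
        out[col] = converted
    if schema.key_columns:
        dups = out.duplicated(subset=list(schema.key_columns))
        if dups.any():
            row = int(dups.idxmax()) + 1
            key = tuple(out.loc[dups.idxmax(), list(schema.key_columns)])
            raise TableFormatError(f"{path}: duplicate key {key} for {schema.key_columns}, data row {row}")
    return out


def read_config(path: str | Path) -> dict:
    """Load a YAML/JSON run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TableFormatError(f"{path}: configuration must be a mapping")
    return cfg
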