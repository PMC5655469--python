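"""Schema-validated CSV input/output.

All tables travel as small CSV files with header rows.  Readers accept
UTF-8 with or without a BOM and any line-ending convention, and normalise
age-band dash characters, so files edited in spreadsheets round-trip
cleanly.  Schema violations are reported with 1-based file row numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .errors import SchemaError
from .strata import ETHNICITIES, SEXES, normalize_band


def _check_probability(value: float) -> bool:
    return 0.0 <= value <= 1.0


def _check_nonneg(value: float) -> bool:
    return value >= 0


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "str" | "float" | "int"
    check: Callable[[object], bool] | None = None
    allowed: tuple[str, ...] | None = None
    describe: str = ""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


_BAND = ColumnSpec("age_band", "str", describe="5-year age band label")
_ETH = ColumnSpec("ethnicity", "str", allowed=ETHNICITIES)
_SEX = ColumnSpec("sex", "str", allowed=SEXES)

LIFE_TABLE_SCHEMA = TableSchema(
    "life_table",
    (_ETH, _SEX, _BAND,
     ColumnSpec("p_death_5yr", "float", _check_probability, describe="probability in [0,1]")),
)
POPULATION_SCHEMA = TableSchema(
    "population",
    (_ETH, _SEX, _BAND, ColumnSpec("count", "int", _check_nonneg, describe="count >= 0")),
)
PREVALENCE_SCHEMA = TableSchema(
    "prevalence",
    (_ETH, _SEX, _BAND,
     ColumnSpec("prevalence", "float", _check_probability, describe="proportion in [0,1]")),
)
PAIN_CURVE_SCHEMA = TableSchema(
    "pain_curve",
    (_BAND,
     ColumnSpec("p_in_pain", "float", _check_probability, describe="proportion in [0,1]")),
)
UTILITY_SCHEMA = TableSchema(
    "utilities",
    (_BAND,
     ColumnSpec("level", "str", allowed=("none", "moderate", "severe")),
     ColumnSpec("value", "float", _check_probability, describe="utility in [0,1]"),
     ColumnSpec("value_set", "str", allowed=("vas", "transformed"))),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema.

    Raises :class:`SchemaError` naming the offending column and file row
    (header = row 1) on wrong columns, non-numeric cells, disallowed labels
    or out-of-range values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{schema.name} file not found: {path}")
    frame = pd.read_csv(path, encoding="utf-8-sig", dtype=str, skipinitialspace=True)
    missing = set(schema.column_names) - set(frame.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {sorted(missing)}; "
            f"expected header {schema.column_names}"
        )
    frame = frame[schema.column_names].copy()

    for col in schema.columns:
        series = frame[col.name].astype(str).str.strip()
        if col.name == "age_band":
            series = series.map(normalize_band)
        if col.kind in ("float", "int"):
            numeric = pd.to_numeric(series, errors="coerce")
            bad = numeric.isna()
            if bad.any():
                row = int(bad.idxmax()) + 2
                raise SchemaError(
                    f"{path}: column {col.name!r} row {row}: "
                    f"non-numeric value {series[bad.idxmax()]!r}"
                )
            if col.check is not None:
                invalid = ~numeric.map(col.check)
                if invalid.any():
                    row = int(invalid.idxmax()) + 2
                    raise SchemaError(
                        f"{path}: column {col.name!r} row {row}: value "
                        f"{numeric[invalid.idxmax()]} not a valid {col.describe}"
                    )
            # astype(float) round-trips %.17g exactly; pandas' fast csv
            # float parser does not.
            frame[col.name] = (
                numeric.astype(int) if col.kind == "int" else series.astype(float)
            )
        else:
            if col.allowed is not None:
                invalid = ~series.isin(col.allowed)
                if invalid.any():
                    row = int(invalid.idxmax()) + 2
                    raise SchemaError(
                        f"{path}: column {col.name!r} row {row}: "
                        f"{series[invalid.idxmax()]!r} not in {col.allowed}"
                    )
            frame[col.name] = series
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with LF endings (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees binary round-trip of doubles through the CSV
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8",
                 float_format="%.17g")
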