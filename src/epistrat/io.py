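"""CSV schemas and validated table reading/writing.

All tabular interchange uses headered CSV.  Each schema names its columns,
dtypes and row-level invariants; violations are reported with the offending
row number (1-based, counting the header as line 1) and field.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "validate_table", "TableError"]


class TableError(ValueError):
    """A table failed schema validation."""


def _enum(allowed: tuple[str, ...]) -> Callable[[pd.Series], pd.Series]:
    def check(col: pd.Series) -> pd.Series:
        return ~col.isin(allowed)

    check.message = f"must be one of {sorted(allowed)}"  # type: ignore[attr-defined]
    return check


def _bounded(lo=None, hi=None, strict_lo=False):
    def check(col: pd.Series) -> pd.Series:
        bad = ~np.isfinite(col)
        if lo is not None:
            bad |= (col <= lo) if strict_lo else (col < lo)
        if hi is not None:
            bad |= col > hi
        return bad

    parts = []
    if lo is not None:
        parts.append(f"> {lo}" if strict_lo else f">= {lo}")
    if hi is not None:
        parts.append(f"<= {hi}")
    check.message = "must be " + " and ".join(parts)  # type: ignore[attr-defined]
    return check


# schema: column -> (dtype, row_check or None); extra table-level checks separate
SCHEMAS: dict[str, dict] = {
    "growth": {
        "columns": {
            "embryo_id": (str, None),
            "stage": (float, _bounded(lo=0, strict_lo=True)),
            "axis": (str, _enum(("sagittal", "orthogonal"))),
            "length_mm": (float, _bounded(lo=0, strict_lo=True)),
        },
    },
    "density": {
        "columns": {
            "animal_id": (str, None),
            "stage": (float, _bounded(lo=0, strict_lo=True)),
            "layer": (str, _enum(("basal", "suprabasal"))),
            "axis": (str, _enum(("sagittal", "orthogonal"))),
            "density_per_100um": (float, _bounded(lo=0)),
        },
    },
    "edu": {
        "columns": {
            "animal_id": (str, None),
            "stage": (float, _bounded(lo=0, strict_lo=True)),
            "layer": (str, _enum(("basal", "suprabasal"))),
            "n_positive": (int, _bounded(lo=0)),
            "n_total": (int, _bounded(lo=0, strict_lo=True)),
        },
    },
    "angles": {
        "columns": {
            "animal_id": (str, None),
            "genotype": (str, None),
            "stage": (float, _bounded(lo=0, strict_lo=True)),
            "angle_deg": (float, _bounded(lo=0, hi=90)),
        },
    },
    "trajectory": {
        "columns": {
            "replicate": (int, _bounded(lo=0)),
            "time": (float, None),
            "b": (float, _bounded(lo=0)),
            "s": (float, _bounded(lo=0)),
            "total": (float, _bounded(lo=0)),
        },
    },
    "cellnumber": {
        "columns": {
            "stage": (float, _bounded(lo=0, strict_lo=True)),
            "layer": (str, _enum(("basal", "suprabasal", "total"))),
            "index": (float, _bounded(lo=0)),
            "index_se": (float, _bounded(lo=0)),
        },
    },
}


def validate_table(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    """Coerce dtypes and enforce the named schema's invariants."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    cols = SCHEMAS[schema]["columns"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableError(f"{schema} table missing columns: {missing}")
    out = df.copy()
    for col, (dtype, check) in cols.items():
        try:
            out[col] = out[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise TableError(
                f"{schema}.{col}: cannot coerce to {dtype.__name__}: {exc}"
            ) from None
        if check is not None:
            bad = check(out[col])
            if bad.any():
                i = int(np.where(bad)[0][0])
                raise TableError(
                    f"{schema}.{col} invalid at data row {i + 1} "
                    f"(value {out[col].iloc[i]!r}): {check.message}"
                )
    if schema == "edu":
        bad = out["n_positive"] > out["n_total"]
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise TableError(
                f"edu: n_positive > n_total at data row {i + 1} "
                f"({out['n_positive'].iloc[i]} > {out['n_total'].iloc[i]})"
            )
    return out


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a headered CSV and validate it against the named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> Path:
    """Write a CSV (validating first when a schema is given)."""
    if schema is not None:
        df = validate_table(df, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
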