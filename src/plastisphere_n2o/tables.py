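"""Schema-checked CSV table IO shared by all stages.

Fixed dialect: comma separator, period decimal, UTF-8, LF, header row
required.  A schema is a mapping of column name to "str", "int" or
"float"; extra columns pass through untouched.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "SCHEMAS"]

#: Column schemas for the pipeline's interchange tables.
SCHEMAS: dict[str, dict[str, str]] = {
    "isotopes": {
        "sample_id": "str",
        "group": "str",
        "d15N_alpha": "float",
        "d15N_beta": "float",
        "d18O": "float",
    },
    "ipt": {"sample_id": "str", "t29": "float", "t30": "float", "fn": "float"},
    "acetylene": {
        "sample_id": "str",
        "n2o_without_c2h2": "float",
        "n2o_with_c2h2": "float",
    },
    "ct": {"sample_id": "str", "gene": "str", "ct": "float"},
}

_DTYPES = {"str": "object", "int": "int64", "float": "float64"}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_table(path: str | Path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV and validate it against a column schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, encoding="utf-8")
    if schema:
        missing = set(schema) - set(df.columns)
        if missing:
            raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
        for col, kind in schema.items():
            if kind == "str":
                df[col] = df[col].astype(str)
                continue
            try:
                df[col] = df[col].astype(_DTYPES[kind])
            except (ValueError, KeyError) as exc:
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad.index[0]) if len(bad) else "?"
                raise SchemaError(
                    f"{path.name}: column {col!r} is not {kind} (first bad row {row})"
                ) from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a CSV in the fixed dialect; creates parent directories."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, encoding="utf-8", lineterminator="\n")
    return path
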