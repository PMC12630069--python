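"""Versioned CSV persistence for shift tables, range-shift maps and summaries.

Every table written by the package starts with a one-line schema header so a
reader can refuse files written under a different schema, and round-trips
field-wise: ``read(write(x)) == x`` including NaN-flagged entries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SCHEMA_VERSION",
    "SchemaVersionError",
    "TableParseError",
    "write_table",
    "read_table",
]

SCHEMA_VERSION = 1
_HEADER = "# protonrv-schema"


class SchemaVersionError(ValueError):
    """File was written under a different table schema."""


class TableParseError(ValueError):
    """File is not a readable package table (truncated or foreign)."""


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{_HEADER} {SCHEMA_VERSION}\n")
        # %.17g guarantees float round-trips bit-exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        with open(path) as fh:
            first = fh.readline().strip()
    except OSError as exc:
        raise TableParseError(f"cannot read {path}: {exc}") from exc
    if not first.startswith(_HEADER):
        raise TableParseError(f"{path} lacks the schema header {_HEADER!r}")
    try:
        version = int(first.split()[-1])
    except ValueError as exc:
        raise TableParseError(f"{path}: malformed schema header {first!r}") from exc
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path} uses schema {version}, this package reads schema {SCHEMA_VERSION}"
        )
    try:
        df = pd.read_csv(path, skiprows=1, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TableParseError(f"{path} is truncated: no table body") from exc
    if df.empty and df.columns.size == 0:
        raise TableParseError(f"{path} is truncated: no columns")
    return df
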