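"""Delimited-text table I/O with ``#key=value`` metadata comments.

Every on-disk artifact the package consumes or produces is a plain text
table: a block of leading ``#key=value`` comment lines carrying scalar
metadata, one header line, then comma- or tab-separated rows.  Keeping the
metadata inside the file makes each fixture self-contained and the
write/read cycle lossless.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["TableSchema", "read_table", "write_table", "parse_meta_value"]


@dataclass(frozen=True)
class TableSchema:
    """Column contract for :func:`read_table`.

    required:  columns that must be present (order not enforced)
    optional:  columns kept when present
    monotone:  columns that must be strictly increasing
    positive:  columns that must be strictly positive
    """

    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    monotone: tuple[str, ...] = ()
    positive: tuple[str, ...] = ()
    min_rows: int = 1


def parse_meta_value(text: str):
    """Best-effort typed parse of a metadata value (int, float, or str)."""
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def _format_meta_value(value) -> str:
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_table(path, schema: TableSchema | None = None):
    """Read a delimited table and its ``#key=value`` metadata.

    The delimiter (comma or tab) is sniffed from the header line.  Returns
    ``(DataFrame, meta_dict)``.  Raises :class:`SchemaError` naming the
    offending column when the schema is violated.
    """
    path = Path(path)
    meta: dict = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            payload = line[1:].strip()
            if "=" in payload:
                key, _, value = payload.partition("=")
                meta[key.strip()] = parse_meta_value(value.strip())
        elif line.strip():
            break
        else:
            body_start = i + 1
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise SchemaError(f"{path}: no table body found")
    header = lines[body_start]
    sep = "\t" if "\t" in header else ","
    try:
        df = pd.read_csv(_io.StringIO(body), sep=sep)
    except Exception as exc:  # noqa: BLE001 - re-raise typed
        raise SchemaError(f"{path}: unparseable table body ({exc})") from exc
    if schema is not None:
        _validate(df, schema, str(path))
    return df, meta


def _validate(df: pd.DataFrame, schema: TableSchema, origin: str) -> None:
    for col in schema.required:
        if col not in df.columns:
            raise SchemaError(f"{origin}: missing required column '{col}'")
    if len(df) < schema.min_rows:
        raise SchemaError(
            f"{origin}: table has {len(df)} rows, needs >= {schema.min_rows}")
    for col in schema.required:
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise SchemaError(f"{origin}: non-finite values in column '{col}'")
    for col in schema.monotone:
        if col in df.columns:
            values = df[col].to_numpy(dtype=float)
            if not np.all(np.diff(values) > 0):
                raise SchemaError(
                    f"{origin}: column '{col}' must be strictly increasing")
    for col in schema.positive:
        if col in df.columns:
            if not np.all(df[col].to_numpy(dtype=float) > 0):
                raise SchemaError(
                    f"{origin}: column '{col}' must be strictly positive")


def write_table(path, df: pd.DataFrame, meta: dict | None = None,
                sep: str = ",", float_format: str = "%.10g") -> None:
    """Write a table with metadata comments; deterministic byte-for-byte
    for identical inputs (fixed float formatting, '\\n' line endings)."""
    path = Path(path)
    chunks = []
    for key, value in (meta or {}).items():
        chunks.append(f"#{key}={_format_meta_value(value)}\n")
    chunks.append(df.to_csv(index=False, sep=sep, float_format=float_format,
                            lineterminator="\n"))
    path.write_text("".join(chunks))


def table_text(df: pd.DataFrame, meta: dict | None = None,
               sep: str = ",", float_format: str = "%.10g") -> str:
    """Serialized form of a table, as :func:`write_table` would emit it."""
    buf = []
    for key, value in (meta or {}).items():
        buf.append(f"#{key}={_format_meta_value(value)}\n")
    buf.append(df.to_csv(index=False, sep=sep, float_format=float_format,
                         lineterminator="\n"))
    return "".join(buf)
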