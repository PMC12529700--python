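"""Typed delimited-table I/O and run manifests.

All interchange is comma-separated UTF-8 text with ISO-8601 calendar
dates. Each schema maps column names to logical types (``str``, ``int``,
``float``, ``date``); reading checks that every schema column is present
(extra columns pass through untouched) and writing is the exact inverse,
so write -> read round-trips.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError

SLAUGHTER_SCHEMA = {
    "animal_id": "str", "breed_code": "str", "sire_breed_code": "str",
    "animal_class": "str", "sex": "str", "date_of_birth": "date",
    "date_of_death": "date", "liveweight": "float", "value": "float",
}

MARKET_SCHEMA = {
    "sale_date": "date", "animal_category": "str", "breed_code": "str",
    "sex": "str", "price": "float",
}

EVENTS_SCHEMA = {
    "animal_id": "str", "event_kind": "str", "herd_id": "str",
    "event_date": "date", "sex": "str", "breed_code": "str",
    "date_of_birth": "date",
}

CPI_SCHEMA = {"period": "str", "index": "float"}


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a delimited table, enforcing and typing the schema columns."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(missing, path=path)
    for col, typ in schema.items():
        if typ == "date":
            df[col] = pd.to_datetime(df[col]).dt.date
        elif typ == "float":
            df[col] = pd.to_numeric(df[col], errors="coerce")
        elif typ == "int":
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def write_table(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a table as CSV; with a schema, verify the columns first."""
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(missing, path=path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, manifest: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
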