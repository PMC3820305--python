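"""Readers, writers and run configuration shared by the CLI and library.

CSV is the canonical event format (one row per sampled cell per assay
time); times are stored in days as decimals (12 h = 0.5 d) with day 0 the
start of differentiation induction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .markers import MARKER_COLUMNS
from .simulate import EVENT_COLUMNS


class SchemaError(ValueError):
    """Raised when a table does not match its expected schema."""


def read_event_table(path) -> pd.DataFrame:
    """Read and validate an event-table CSV.

    Marker fields are coerced to 0/1 integers; a missing column, a
    non-binary marker value or a negative time raises a SchemaError naming
    the offending row/column.
    """
    table = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing column(s): {missing}")
    for col in MARKER_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-binary marker value in column {col!r}, row {row}")
        table[col] = vals.astype(int)
    if (table["time_days"] < 0).any():
        row = int(np.flatnonzero((table["time_days"] < 0).to_numpy())[0])
        raise SchemaError(f"negative time_days at row {row}")
    return table


def write_event_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_daily_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"time", "n_assayed", "n_differentiated"} - set(table.columns)
    if missing:
        raise SchemaError(f"daily counts missing column(s): {sorted(missing)}")
    if ((table["n_differentiated"] < 0)
            | (table["n_differentiated"] > table["n_assayed"])).any():
        raise SchemaError("need 0 <= n_differentiated <= n_assayed")
    return table


def read_survival_records(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = {"time", "event"} - set(table.columns)
    if missing:
        raise SchemaError(f"survival records missing column(s): {sorted(missing)}")
    return table


def load_config(path, allowed_keys: Iterable[str] | None = None) -> dict:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise SchemaError("config file must contain a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return dict(cfg)


def write_resolved_config(cfg: Mapping[str, Any], outdir) -> Path:
    """Write the fully resolved configuration next to the run outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "resolved_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
    return path


def write_json(obj: Any, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    if hasattr(obj, "_asdict"):
        return obj._asdict()
    raise TypeError(f"cannot serialise {type(obj)!r}")
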