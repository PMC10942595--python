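"""CSV schemas, validated table I/O, and JSON result reports.

CSV dialect: comma-separated, UTF-8, "." decimal, header required.  Units
are encoded in column names (dose_uM, time_h, conc_nM) so unit mistakes
fail loudly at the schema check rather than silently downstream.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding import BindingTrace

__all__ = ["SCHEMAS", "read_table", "write_table", "write_report",
           "traces_to_frame", "frame_to_traces"]

#: documented schemas: column name -> required dtype kind ("num" or "any")
SCHEMAS: Mapping[str, Mapping[str, str]] = {
    "dose_response": {"dose_uM": "num", "replicate": "num", "response_au": "num"},
    "inhibition": {"dose_mM": "num", "response_au": "num"},
    "traces": {"time_s": "num", "conc_nM": "num", "phase": "any",
               "role": "any", "signal_au": "num"},
    "plate": {"time_h": "num", "well": "any", "od600": "num", "green_au": "num",
              "red_au": "num", "dose_uM": "num", "replicate": "num",
              "is_blank": "any"},
    "totals": {"time_h": "num", "dose_uM": "num", "replicate": "num",
               "total_green": "num", "total_red": "num"},
    "cells": {"cell_id": "num", "protein_count": "num"},
    "foldmap": {"kon_r": "num", "koff": "num", "fold": "num"},
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises with the offending column (and first offending row for a
    malformed numeric cell).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    columns = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    for col, kind in columns.items():
        if kind != "num" or df.empty:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path.name}: malformed numeric cell at row {row}, column {col!r}"
            )
        df[col] = converted
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _config_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_report(result: dict, path: str | Path, seed: int | None = None,
                 config: dict | None = None) -> dict:
    """Write a JSON result report carrying provenance (version, config hash, seed)."""
    from . import __version__

    report = {
        "package_version": __version__,
        "seed": seed,
        "config": config or {},
        "config_hash": _config_hash(config or {}),
        "result": result,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report


def traces_to_frame(traces: Iterable[BindingTrace]) -> pd.DataFrame:
    """Serialize binding traces to the traces.csv schema."""
    frames = []
    for t in traces:
        frames.append(pd.DataFrame({
            "time_s": t.time_s, "conc_nM": t.analyte_conc,
            "phase": t.phase, "role": t.role, "signal_au": t.signal,
        }))
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[BindingTrace]:
    """Rebuild binding traces from the traces.csv schema."""
    traces = []
    for (conc, phase, role), sub in df.groupby(["conc_nM", "phase", "role"],
                                               sort=False):
        sub = sub.sort_values("time_s")
        traces.append(BindingTrace(
            sub["time_s"].to_numpy(dtype=float),
            sub["signal_au"].to_numpy(dtype=float),
            str(phase), float(conc), str(role),
        ))
    return traces
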