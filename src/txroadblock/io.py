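"""Reproducible tabular and config I/O.

All tables are UTF-8 tab-separated with '#'-prefixed provenance header
lines (command, seed, parameter hash) and floats at 6 significant digits,
so re-running a command with the same config and seed reproduces
byte-identical numeric columns.  Configs are flat key:value text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "write_config",
    "read_config",
    "params_hash",
]


def params_hash(obj) -> str:
    """Short stable hash of a parameter mapping (for provenance headers)."""
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(command: Optional[str], seed: Optional[int],
                  params: Optional[dict]) -> list:
    lines = []
    if command:
        lines.append(f"# command: {command}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if params is not None:
        lines.append(f"# params-hash: {params_hash(params)}")
    return lines


def write_table(df: pd.DataFrame, path, *, command: Optional[str] = None,
                seed: Optional[int] = None,
                params: Optional[dict] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header_lines(command, seed, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_config(d: dict, path, *, command: Optional[str] = None,
                 seed: Optional[int] = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _header_lines(command, seed, d):
            fh.write(line + "\n")
        for k, v in d.items():
            fh.write(f"{k}: {v}\n")


def read_config(path) -> dict:
    """Flat key:value text -> dict with int/float coercion where possible."""
    out = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, value = line.partition(":")
        value = value.strip()
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        out[key.strip()] = value
    return out
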