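"""Delimited-text I/O helpers.

Tab-separated UTF-8 tables with '.' decimal are the canonical interchange
format; every table is id-indexed (area ids, receptor names, sample ids),
never positionally indexed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd


def write_table(df: pd.DataFrame | pd.Series, path: str | Path, *, comment: str | None = None) -> Path:
    """Write a table as TSV, optionally preceded by '#'-prefixed header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")
    return path


def read_table(path: str | Path, *, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", index_col=index_col, comment="#")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8")
    return path
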