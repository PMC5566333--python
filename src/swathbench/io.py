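"""Tab-separated file dialect shared by all pipeline stages.

One dialect everywhere: tab-separated, UTF-8, '.' decimal separator, no
quoting, a single header line, optionally preceded by '#'-prefixed comment
lines carrying provenance (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .simulate import FRAG_COLS, SUB_SCORE_COLS

__all__ = [
    "SchemaError",
    "read_peakgroups",
    "write_peakgroups",
    "read_table",
    "write_table",
    "config_hash",
]

PEAKGROUP_COLUMNS = ["run_id", "peptide_query_id", "protein_id", "decoy", *SUB_SCORE_COLS, *FRAG_COLS, "ms1_area", "rt"]
SIS_COLUMNS = [
    "run_id", "site_id", "day", "sample_id", "replicate_index",
    "peptide_id", "group_id", "nominal_fmol", "ms_level", "area", "sn",
]


class SchemaError(ValueError):
    """A required column is missing or a row is malformed."""


def config_hash(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, required: list[str] | None = None, **kwargs) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed row ({exc})") from exc
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_peakgroups(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    write_table(df[PEAKGROUP_COLUMNS], path, provenance)


def read_peakgroups(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=PEAKGROUP_COLUMNS)
    bad = ~df["decoy"].isin([0, 1, True, False])
    if bad.any():
        raise SchemaError(f"{path}: decoy flag must be 0/1 (first bad line {int(bad.idxmax()) + 2})")
    df["decoy"] = df["decoy"].astype(bool)
    return df


def write_sis(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    write_table(df[SIS_COLUMNS], path, provenance)


def read_sis(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=SIS_COLUMNS)


def write_matrix(matrix: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Unit x run matrix; empty cells for missing values."""
    write_table(matrix, path, provenance, index=True)


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0])
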