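"""CSV schemas and round-trip safe readers/writers.

Dialect is fixed for bit-exact round-trips: UTF-8, comma separator,
header row, '.' decimal, booleans written as 0/1. Provenance (source,
seed) travels as '#'-prefixed comment lines above the header.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

from .geometry import FEATURE_COLUMNS, TumorFeatures
from .grading import FLAG_NAMES

__all__ = [
    "FEATURES_SCHEMA",
    "COHORT_SCHEMA",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
    "write_cohort_csv",
    "read_cohort_csv",
]

FEATURES_SCHEMA = ("subject_id",) + FEATURE_COLUMNS
COHORT_SCHEMA = (
    ("subject_id",)
    + FLAG_NAMES
    + ("score", "complexity", "complete_resection", "clavien_dindo")
)
_BOOL_FEATURES = ("corpus_callosum_involved", "bilateral", "eloquent_involved")


def features_to_frame(records: dict[str, TumorFeatures]) -> pd.DataFrame:
    """Assemble per-subject measurements into the features table."""
    rows = [{"subject_id": sid, **f.as_dict()} for sid, f in records.items()]
    df = pd.DataFrame(rows, columns=list(FEATURES_SCHEMA))
    for col in _BOOL_FEATURES:
        df[col] = df[col].astype(int)
    return df


def _write(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    buf = io.StringIO()
    prov = df.attrs.get("provenance")
    if prov:
        for key, value in prov.items():
            buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, index=False, float_format=float_format)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_features_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in FEATURES_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"features table lacks columns: {missing}")
    out = df.copy()
    for col in _BOOL_FEATURES:
        out[col] = out[col].astype(int)
    _write(out, path)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURES_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: features CSV lacks columns {missing}")
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    required = [c for c in COHORT_SCHEMA if c not in ("complete_resection", "clavien_dindo")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")
    _write(df, path)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"clavien_dindo": "string"})
    missing = [c for c in ("subject_id", "complexity") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: cohort CSV lacks columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject_ids {dupes}")
    return df
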