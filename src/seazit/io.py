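"""Flat-file readers and writers for the pipeline's tabular formats.

Wells CSV: the fixed columns ``plate_id,run_date,well,substance_id,
conc_uM,alive_24,alive_120`` followed by one boolean column per recording
name; an empty cell means the phenotype was not assessed (dead embryo).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core_model import RecordingDef, WELL_BASE_COLUMNS

__all__ = [
    "read_wells_csv",
    "write_wells_csv",
    "read_manifest_csv",
    "read_recordings_csv",
    "recordings_from_frame",
]


def _parse_bool(v):
    if pd.isna(v) or v == "":
        return pd.NA
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


def read_wells_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "substance_id": str})
    for col in ("alive_24", "alive_120"):
        df[col] = df[col].map(_parse_bool).astype(bool)
    for col in df.columns:
        if col not in WELL_BASE_COLUMNS:
            df[col] = pd.array(
                [_parse_bool(v) for v in df[col]], dtype="boolean"
            )
    df["conc_uM"] = df["conc_uM"].astype(float)
    return df


def write_wells_csv(wells: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    wells.to_csv(path, index=False)


def read_manifest_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    return df


def recordings_from_frame(df: pd.DataFrame) -> list[RecordingDef]:
    return [
        RecordingDef(
            lab_id=str(r.get("lab_id", "")),
            recording_name=str(r["recording_name"]),
            is_binarized_quantitative=bool(
                r.get("is_binarized_quantitative", False) in (True, "True", "true", 1, "1")
            ),
        )
        for _, r in df.iterrows()
    ]


def read_recordings_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
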