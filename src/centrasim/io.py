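"""CSV contracts between pipeline stages.

All tables are UTF-8 CSV with a header row, '.' decimal separator, flags
encoded 0/1 and residence as a lowercase token.  The travel matrix is
stored long (patient_id, center_id, minutes).  Writers prepend '# key:
value' metadata comment lines (seed, config hash); readers skip them.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "write_patients", "read_patients",
    "write_centers", "read_centers",
    "write_matrix", "read_matrix",
]

FLAG_COLS_PATIENTS = ("age65", "comorbidity", "low_ses")
FLAG_COLS_CENTERS = ("robotic", "teaching", "media", "radiotherapy_on_site")


def config_hash(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path, metadata: dict | None = None,
              index: bool = False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_patients(patients: pd.DataFrame, path, metadata=None) -> None:
    out = patients.copy()
    for c in FLAG_COLS_PATIENTS:
        out[c] = out[c].astype(int)
    out = out[["id", "x_km", "y_km", "age65", "comorbidity", "low_ses",
               "residence", "chosen_center"]]
    write_csv(out, path, metadata)


def read_patients(path) -> pd.DataFrame:
    df = read_csv(path)
    for c in FLAG_COLS_PATIENTS:
        df[c] = df[c].astype(bool)
    df["residence"] = df["residence"].astype(str)
    df["chosen_center"] = df["chosen_center"].astype("Int64")
    return df


def write_centers(centers: pd.DataFrame, path, metadata=None) -> None:
    out = centers.copy()
    for c in FLAG_COLS_CENTERS:
        out[c] = out[c].astype(int)
    out = out[["id", "x_km", "y_km", "robotic", "teaching", "media",
               "radiotherapy_on_site", "annual_volume"]]
    write_csv(out, path, metadata)


def read_centers(path) -> pd.DataFrame:
    df = read_csv(path)
    for c in FLAG_COLS_CENTERS:
        df[c] = df[c].astype(bool)
    return df


def write_matrix(matrix: pd.DataFrame, path, metadata=None) -> None:
    long = matrix.stack().rename("minutes").reset_index()
    long.columns = ["patient_id", "center_id", "minutes"]
    write_csv(long, path, metadata)


def read_matrix(path) -> pd.DataFrame:
    long = read_csv(path)
    wide = long.pivot(index="patient_id", columns="center_id", values="minutes")
    if wide.isna().any().any():
        raise ValueError("travel matrix has missing patient-center pairs")
    if (wide.to_numpy() < 0).any() or not np.isfinite(wide.to_numpy()).all():
        raise ValueError("travel times must be finite and nonnegative")
    return wide
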