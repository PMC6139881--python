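"""Readers/writers for tabular artifacts and provenance envelopes."""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd

from .fitting import DATASET_COLUMNS, ExperimentalDataset
from .params import SITE_LENGTH_UM

PACKAGE_VERSION = "0.1.0"

TRAJECTORY_COLUMNS = ["motor_id", "time_s", "position_sites", "active",
                      "bound"]


def load_dataset_csv(path) -> ExperimentalDataset:
    """Read a concentration-series CSV (schema: c_nM, l_um, l_se, tau_s,
    tau_se, V_um_s, V_se, lam_um_s, lam_se; empty cells allowed)."""
    df = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: malformed header, missing columns {sorted(missing)}")
    for col in DATASET_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()
                     & df[col].notna()]
            row = int(bad.index[0]) if len(bad) else "?"
            raise ValueError(
                f"{path}: non-numeric cell in column {col}, row {row}")
    return ExperimentalDataset(df[DATASET_COLUMNS].copy())


def save_dataset_csv(dataset: ExperimentalDataset, path) -> None:
    dataset.table.to_csv(path, index=False)


def save_trajectories_csv(traj: pd.DataFrame, path,
                          a: float = SITE_LENGTH_UM) -> None:
    """Write a trajectory table; a header comment records the site length
    (nm per site) so positions can be converted to physical units."""
    with open(path, "w") as fh:
        fh.write(f"# site_length_nm={a * 1e3}\n")
        cols = [c for c in TRAJECTORY_COLUMNS if c in traj.columns]
        traj[cols].to_csv(fh, index=False)


def load_trajectories_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def result_envelope(command: str, seed, config: dict, payload: dict) -> dict:
    """Wrap a summary record with the provenance needed to reproduce it."""
    return {
        "command": command,
        "package": "kintraffic",
        "version": PACKAGE_VERSION,
        "seed": seed,
        "config": _jsonable(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "payload": _jsonable(payload),
    }


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_envelope(envelope: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(envelope, fh, indent=2)
        fh.write("\n")
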