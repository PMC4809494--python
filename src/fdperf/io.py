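"""File formats and run manifests.

All files are plain CSV/JSON: times in decimal hours since FD start, phase
in degrees, reaction times in milliseconds.  Observation tables are
long-format with one row per measurement; floats are written with 17
significant digits so a write/read round trip preserves values to 1e-12.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_observations",
    "write_observations",
    "write_pairs",
    "read_pairs",
    "write_manifest",
]

OBSERVATION_KINDS = ("vas", "pvt", "add", "dsst", "melatonin")
OBS_COLUMNS = ["participant_id", "kind", "t_elapsed", "value", "sd_ms", "lapses"]
FLOAT_FMT = "%.17g"


def _validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("participant_id", "kind", "t_elapsed", "value")
               if c not in df.columns]
    if missing:
        raise ValueError(f"observations missing columns: {missing}")
    bad = set(df["kind"].unique()) - set(OBSERVATION_KINDS)
    if bad:
        raise ValueError(f"unknown observation kinds: {sorted(bad)}")
    vas = df[df["kind"] == "vas"]
    if len(vas) and ((vas["value"] < 0) | (vas["value"] > 100)).any():
        raise ValueError("VAS alertness values must lie in [0, 100]")
    pvt = df[df["kind"] == "pvt"]
    if len(pvt) and (pvt["value"] <= 0).any():
        raise ValueError("PVT session means must be positive (ms)")
    for (pid, kind), g in df.groupby(["participant_id", "kind"], sort=False):
        t = g["t_elapsed"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"non-monotone t_elapsed for participant {pid}, kind {kind}")
    return df


def write_observations(records: pd.DataFrame, path) -> None:
    """Write a long-format observation table (validated first)."""
    df = records.copy()
    for col in OBS_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    _validate_observations(df)
    df[OBS_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format observation table."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"empty observation file: {path}")
        return pd.DataFrame(columns=OBS_COLUMNS)
    df["participant_id"] = df["participant_id"].astype(str)
    return _validate_observations(df)


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serializable config."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(path, config: dict, seed: int) -> dict:
    """Write the run manifest (package version, seed, config and its hash)."""
    from . import __version__

    manifest = {
        "package": "fdperf",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(config),
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
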