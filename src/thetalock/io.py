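"""File formats: flat-binary LFP with JSON sidecar, spike/cycle tables.

LFP is stored as a flat binary array (float32 or int16) next to a JSON
header carrying the sampling rate, dtype, channel count and channel
roles. Spike and cycle tables are tab-separated text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_cycle_table",
    "read_lfp",
    "read_spike_table",
    "write_cycle_table",
    "write_lfp",
    "write_spike_table",
]


def write_lfp(path, data: np.ndarray, fs: float, dtype: str = "float32",
              channel_roles: list[str] | None = None) -> None:
    """Write LFP as flat binary + JSON header (<path>.json)."""
    path = Path(path)
    arr = np.atleast_2d(np.asarray(data))
    if dtype not in ("float32", "int16"):
        raise ValueError("write_lfp: dtype must be float32 or int16")
    scale = 1.0
    if dtype == "int16":
        peak = np.abs(arr).max() or 1.0
        scale = 32000.0 / peak
        out = (arr * scale).astype(np.int16)
    else:
        out = arr.astype(np.float32)
    out.T.tofile(path)  # sample-major interleaved
    header = {
        "fs": fs,
        "dtype": dtype,
        "n_channels": arr.shape[0],
        "n_samples": arr.shape[1],
        "scale": scale,
        "channel_roles": channel_roles or ["reference"] * arr.shape[0],
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=2))


def read_lfp(path) -> tuple[np.ndarray, dict]:
    """Read flat-binary LFP; returns (channels x samples float array, header)."""
    path = Path(path)
    hpath = Path(str(path) + ".json")
    if not hpath.exists():
        raise FileNotFoundError(f"read_lfp: missing header {hpath}")
    header = json.loads(hpath.read_text())
    raw = np.fromfile(path, dtype=header["dtype"])
    nch = header["n_channels"]
    data = raw.reshape(-1, nch).T.astype(float)
    if header.get("scale", 1.0) != 1.0:
        data = data / header["scale"]
    return data, header


def write_spike_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_spike_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"unit", "time_s"}
    if not need.issubset(df.columns):
        raise ValueError(f"read_spike_table: need columns {sorted(need)}")
    return df


def write_cycle_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cycle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"start", "trough", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"read_cycle_table: need columns {sorted(need)}")
    return df
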