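"""CSV interchange for spike rasters and event tables, plus run manifests.

Rasters travel as sparse CSV with columns (trial, neuron, time) listing the
spikes, 0-based, preceded by a comment line carrying the dense shape.
Event tables use columns (t, x, y, polarity) with the sensor size in the
comment line.  Both round-trip bit-exactly (events up to ordering, which
the reader normalises by sorting on t).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time

import numpy as np
import pandas as pd

__all__ = [
    "write_raster_csv",
    "read_raster_csv",
    "write_event_csv",
    "read_event_csv",
    "write_manifest",
]

_RASTER_COLS = ["trial", "neuron", "time"]
_EVENT_COLS = ["t", "x", "y", "polarity"]


def write_raster_csv(raster: np.ndarray, path: str) -> None:
    """Write a binary raster of shape (trials, n, T) or (n, T)."""
    r = np.asarray(raster)
    if r.ndim == 2:
        r = r[None]
    if r.ndim != 3 or not np.isin(r, (0, 1)).all():
        raise ValueError("raster must be binary with shape (trials, neurons, time)")
    trials, n, T = r.shape
    tr, ne, ti = np.nonzero(r)
    with open(path, "w") as fh:
        fh.write(f"# raster trials={trials} neurons={n} time={T} (0-based indices)\n")
        fh.write(",".join(_RASTER_COLS) + "\n")
        for a, b, c in zip(tr, ne, ti):
            fh.write(f"{a},{b},{c}\n")


def read_raster_csv(path: str) -> np.ndarray:
    """Read a raster CSV back into a dense (trials, neurons, time) array."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# raster"):
            raise ValueError(f"{path}: missing raster shape header")
        meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
        df = pd.read_csv(fh)
    if list(df.columns) != _RASTER_COLS:
        raise ValueError(
            f"{path}: expected columns {_RASTER_COLS}, found {list(df.columns)}"
        )
    shape = (int(meta["trials"]), int(meta["neurons"]), int(meta["time"]))
    r = np.zeros(shape)
    if len(df):
        bad = df[df.isna().any(axis=1)]
        if len(bad):
            raise ValueError(f"{path}: malformed row at line {bad.index[0] + 3}")
        dup = df.duplicated()
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                f"{path}: duplicate (trial, neuron, time) row "
                f"({first['trial']}, {first['neuron']}, {first['time']})"
            )
        idx = df.to_numpy(dtype=int)
        if (idx < 0).any() or (idx >= np.array(shape)).any():
            raise ValueError(f"{path}: index outside declared shape {shape}")
        r[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    return r


def write_event_csv(events: pd.DataFrame, path: str, sensor_size=(16, 16)) -> None:
    ev = events[_EVENT_COLS]
    W, H = sensor_size
    if len(ev) and ((ev["x"] < 0).any() or (ev["x"] >= W).any()
                    or (ev["y"] < 0).any() or (ev["y"] >= H).any()):
        raise ValueError(f"event coordinates outside sensor {sensor_size}")
    with open(path, "w") as fh:
        fh.write(f"# events sensor_w={W} sensor_h={H}\n")
        ev.to_csv(fh, index=False)


def read_event_csv(path: str) -> tuple[pd.DataFrame, tuple]:
    """Read events; rows are sorted by t on the way in."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# events"):
            raise ValueError(f"{path}: missing event header")
        meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
        df = pd.read_csv(fh)
    if list(df.columns) != _EVENT_COLS:
        raise ValueError(
            f"{path}: expected columns {_EVENT_COLS}, found {list(df.columns)}"
        )
    sensor = (int(meta["sensor_w"]), int(meta["sensor_h"]))
    if len(df) and ((df["x"] < 0).any() or (df["x"] >= sensor[0]).any()
                    or (df["y"] < 0).any() or (df["y"] >= sensor[1]).any()):
        raise ValueError(f"{path}: coordinates outside declared sensor {sensor}")
    return df.sort_values("t", kind="stable").reset_index(drop=True), sensor


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path: str, command: str, config: dict, seed,
                   outputs: list | None = None) -> dict:
    """Reproducibility manifest: command, config snapshot, seeds, hashes."""
    import nsnn

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "outputs": {p: _hash_file(p) for p in (outputs or [])},
        "versions": {
            "nsnn": nsnn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
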