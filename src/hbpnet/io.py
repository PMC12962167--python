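"""Plain-text readers and writers for traces, labels and results.

Pulse traces travel as CSV (columns ``time_s, amplitude``) with a JSON
sidecar holding the sampling rate and units; heartbeat-probability maps as
CSV (``frame_index, probability``); heart-rate estimates and metric reports
as JSON records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pulse import HbpMap, PulseTrace

__all__ = ["write_pulse_csv", "read_pulse_csv", "write_hbp_csv",
           "read_hbp_csv", "write_json", "read_json"]


def write_pulse_csv(trace: PulseTrace, path, units: str = "a.u.") -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "amplitude": trace.samples}).to_csv(
        path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"fs": trace.fs, "units": units}))


def read_pulse_csv(path, fs: float | None = None) -> PulseTrace:
    """Read a trace; the rate comes from the sidecar unless given explicitly."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            fs = float(json.loads(sidecar.read_text())["fs"])
        else:
            dt = np.diff(df["time_s"].to_numpy())
            if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-3):
                raise ValueError(
                    f"{path}: no sidecar and time grid is not uniform")
            fs = 1.0 / float(dt[0])
    t0 = float(df["time_s"].iloc[0])
    return PulseTrace(df["amplitude"].to_numpy(float), fs, t0)


def write_hbp_csv(hbp: HbpMap, path) -> None:
    pd.DataFrame({"frame_index": np.arange(len(hbp)),
                  "probability": hbp.values}).to_csv(path, index=False)


def read_hbp_csv(path, fps: float) -> HbpMap:
    df = pd.read_csv(path)
    return HbpMap(df["probability"].to_numpy(float), fps)


def write_json(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def _default(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        raise TypeError(f"cannot serialize {type(v)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def read_json(path):
    return json.loads(Path(path).read_text())
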