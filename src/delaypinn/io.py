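"""CSV / JSON / YAML input and output for traces, truth records and configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .traces import TimeTraceSet

__all__ = ["read_traces", "write_traces", "read_truth", "write_truth",
           "load_config", "save_config"]


def read_traces(path: str | Path) -> TimeTraceSet:
    """Parse a trace CSV: header row, first column ``time`` (hours, strictly
    increasing), then one column per trace.  Missing or non-numeric cells
    raise descriptive errors; nothing is imputed."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one trace")
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be named 'time', "
                         f"got {df.columns[0]!r}")
    for col in df.columns:
        bad = df[col].isna() | ~df[col].apply(np.isreal)
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad |= coerced.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric or missing value at data row {row + 1}, "
                f"column {col!r}"
            )
    time = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        i = int(np.argmax(np.diff(time) <= 0))
        raise ValueError(f"{path}: time must be strictly increasing "
                         f"(violated between rows {i + 1} and {i + 2})")
    traces = df.drop(columns="time").to_numpy(dtype=float).T
    return TimeTraceSet(grid=time, traces=traces)


def write_traces(traces: TimeTraceSet, path: str | Path) -> None:
    data = {"time": traces.grid}
    width = max(3, len(str(traces.n_traces)))
    for i in range(traces.n_traces):
        data[f"trace_{i + 1:0{width}d}"] = traces.traces[i]
    pd.DataFrame(data).to_csv(path, index=False)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
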