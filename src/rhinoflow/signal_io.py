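"""Stable on-disk formats for recordings, labeled cycle sets, and thresholds.

Recordings and cycles share a single CSV schema ``time_s,pressure_pa,flow_cm3s``.
Labeled cycle sets are a directory of cycle CSVs plus a JSON manifest.
Threshold sets are flat JSON objects.  All floats are written with 17
significant digits so that read(write(x)) round-trips to full precision.
"""

from __future__ import annotations

import json
import os
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    LabeledCycle,
    RawRecording,
    RespiratoryCycle,
    ThresholdSet,
    default_thresholds,
)

__all__ = [
    "CSV_COLUMNS",
    "read_recording",
    "write_recording",
    "read_labeled_cycles",
    "write_labeled_cycles",
    "read_thresholds",
    "write_thresholds",
]

CSV_COLUMNS = ("time_s", "pressure_pa", "flow_cm3s")
_TIME_TOL_S = 1e-6
_FLOAT_FMT = "%.17g"


def _read_channels(path, sampling_rate_hz: float) -> Tuple[np.ndarray, np.ndarray, float]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no samples") from exc
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no samples")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    expected = t[0] + np.arange(len(t)) / sampling_rate_hz
    if np.max(np.abs(t - expected)) > _TIME_TOL_S:
        raise FormatError(
            f"{path}: time column inconsistent with sampling rate "
            f"{sampling_rate_hz} Hz"
        )
    return (
        df["pressure_pa"].to_numpy(dtype=float),
        df["flow_cm3s"].to_numpy(dtype=float),
        float(t[0]),
    )


def read_recording(path, sampling_rate_hz: float = 100.0) -> RawRecording:
    """Read a two-channel recording CSV, validating the time grid."""
    pressure, flow, t0 = _read_channels(path, sampling_rate_hz)
    return RawRecording(
        pressure=pressure, flow=flow, sampling_rate_hz=sampling_rate_hz, t0_s=t0
    )


def _write_channels(path, time_s, pressure, flow) -> None:
    df = pd.DataFrame(
        {"time_s": time_s, "pressure_pa": pressure, "flow_cm3s": flow}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_recording(rec: RawRecording, path) -> None:
    _write_channels(path, rec.time_s, rec.pressure, rec.flow)


def write_labeled_cycles(cycles: Sequence[LabeledCycle], directory) -> str:
    """Write one CSV per labeled cycle plus a JSON manifest; return manifest path."""
    if len(cycles) == 0:
        raise ValueError("labeled cycle list is empty")
    os.makedirs(directory, exist_ok=True)
    entries = []
    for i, lc in enumerate(cycles):
        fname = f"cycle_{i:04d}.csv"
        cyc = lc.cycle
        t = (cyc.start_index + np.arange(len(cyc))) / cyc.sampling_rate_hz
        _write_channels(os.path.join(directory, fname), t, cyc.pressure, cyc.flow)
        entries.append(
            {
                "file": fname,
                "truth_label": lc.truth_label,
                "scenario": lc.scenario,
                "seed": lc.seed,
                "start_index": cyc.start_index,
                "sampling_rate_hz": cyc.sampling_rate_hz,
            }
        )
    manifest_path = os.path.join(directory, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"cycles": entries}, fh, indent=2)
    return manifest_path


def read_labeled_cycles(manifest_path) -> List[LabeledCycle]:
    """Read back a labeled cycle set written by :func:`write_labeled_cycles`."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if "cycles" not in manifest:
        raise FormatError(f"{manifest_path}: not a labeled-cycle manifest")
    directory = os.path.dirname(os.path.abspath(manifest_path))
    out: List[LabeledCycle] = []
    for entry in manifest["cycles"]:
        fs = float(entry["sampling_rate_hz"])
        pressure, flow, _ = _read_channels(os.path.join(directory, entry["file"]), fs)
        cycle = RespiratoryCycle(
            pressure=pressure,
            flow=flow,
            sampling_rate_hz=fs,
            start_index=int(entry["start_index"]),
        )
        out.append(
            LabeledCycle(
                cycle=cycle,
                truth_label=entry["truth_label"],
                scenario=entry["scenario"],
                seed=entry.get("seed"),
            )
        )
    return out


_THRESHOLD_KEYS = (
    "minft_hz",
    "maxft_hz",
    "minpvt_pa",
    "maxpvt_pa",
    "minfvt_cm3s",
    "maxfvt_cm3s",
)


def read_thresholds(path: Optional[str] = None) -> ThresholdSet:
    """Read a threshold JSON; with ``path=None`` return the default optimum."""
    if path is None:
        return default_thresholds()
    with open(path) as fh:
        data = json.load(fh)
    missing = [k for k in _THRESHOLD_KEYS if k not in data]
    if missing:
        raise FormatError(f"{path}: missing threshold keys {missing}")
    return ThresholdSet(**{k: float(data[k]) for k in _THRESHOLD_KEYS})


def write_thresholds(ts: ThresholdSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(ts.as_dict(), fh, indent=2)
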