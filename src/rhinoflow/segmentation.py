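"""Respiratory-cycle segmentation from DC-removed recordings.

Segmentation is driven by the flow channel.  A cycle starts once five
consecutive retained flow samples sum to a positive value (samples scanned
while the running sum is non-positive are dropped, so a cycle always opens
on a positive sample).  A cycle ends at the sample pair (x_prev, x_last)
with x_prev * x_last < 0 and x_prev < 0: the cycle closes at x_prev and
x_last seeds the next candidate cycle.  Pressure is sliced by the same
indices.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Sequence

import numpy as np

from .core import RawRecording, RespiratoryCycle

__all__ = [
    "remove_dc",
    "detect_cycle_start",
    "detect_cycle_end",
    "segment_cycles",
]

START_WINDOW = 5  # consecutive flow samples summed for start detection
DEFAULT_MIN_CYCLE_S = 0.5
DEFAULT_BASELINE_WINDOW_S = 2.0


def remove_dc(
    rec: RawRecording, baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S
) -> RawRecording:
    """Subtract the per-channel mean of the first ``baseline_window_s`` seconds."""
    n_window = int(round(baseline_window_s * rec.sampling_rate_hz))
    if len(rec) < n_window:
        raise ValueError(
            f"recording ({len(rec)} samples) shorter than baseline window "
            f"({n_window} samples)"
        )
    return replace(
        rec,
        pressure=rec.pressure - np.mean(rec.pressure[:n_window]),
        flow=rec.flow - np.mean(rec.flow[:n_window]),
    )


def detect_cycle_start(buffer: Sequence[float]) -> bool:
    """Start rule: five consecutive flow samples with a positive sum."""
    if len(buffer) != START_WINDOW:
        raise ValueError(f"start detection needs exactly {START_WINDOW} samples")
    return float(np.sum(buffer)) > 0.0


def detect_cycle_end(x_prev: float, x_last: float) -> bool:
    """End rule: negative-to-positive flow crossing (exact zeros do not cross)."""
    return x_prev * x_last < 0.0 and x_prev < 0.0


def segment_cycles(
    rec: RawRecording,
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S,
) -> List[RespiratoryCycle]:
    """Scan a DC-removed recording and emit disjoint respiratory cycles.

    The scan is incremental (one sample at a time), mirroring a streaming
    recorder: a pending buffer accumulates candidate inspiratory samples and
    is cleared whenever its running sum (over at most the last 5 samples)
    drops to zero or below; recording is confirmed once the buffer holds 5
    samples whose sum is positive.  At end of input an open cycle is flushed
    only if it already reached its expiratory phase (last sample negative),
    which makes segmentation idempotent on its own output.
    """
    flow = rec.flow
    n = len(flow)
    fs = rec.sampling_rate_hz
    min_len = int(round(min_cycle_s * fs))
    cycles: List[RespiratoryCycle] = []

    def emit(start: int, stop: int) -> None:
        # stop is inclusive index of the last sample of the cycle
        length = stop - start + 1
        if length >= max(min_len, 1):
            cycles.append(
                RespiratoryCycle(
                    pressure=rec.pressure[start : stop + 1].copy(),
                    flow=flow[start : stop + 1].copy(),
                    sampling_rate_hz=fs,
                    start_index=start,
                )
            )

    recording = False
    start_idx = 0  # first index of pending/recorded data
    i = 0
    while i < n:
        x = flow[i]
        if not recording:
            # pending buffer is flow[start_idx .. i]
            if i - start_idx + 1 > START_WINDOW:
                start_idx = i - START_WINDOW + 1
            window = flow[start_idx : i + 1]
            if float(np.sum(window)) <= 0.0:
                # not inspiratory: discard pending samples
                start_idx = i + 1
            elif i - start_idx + 1 == START_WINDOW:
                recording = True
        else:
            if detect_cycle_end(flow[i - 1], x):
                emit(start_idx, i - 1)
                recording = False
                start_idx = i
                continue  # re-examine x as the seed of the next candidate
        i += 1

    if recording and flow[n - 1] < 0.0:
        emit(start_idx, n - 1)
    return cycles
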