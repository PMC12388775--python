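"""Core domain types shared across the pipeline.

All channel data are held as 1-D float64 numpy arrays.  Pressure is in Pa,
flow in cm^3/s (identical to mL/s), and time in seconds.  Positive flow is
inspiration; negative flow is expiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "FormatError",
    "NoDominantFrequencyError",
    "SCENARIOS",
    "INTERFERENCE_SCENARIOS",
    "RawRecording",
    "RespiratoryCycle",
    "ThresholdSet",
    "LabeledCycle",
    "ResampledCycle",
    "default_thresholds",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact does not match the expected schema."""


class NoDominantFrequencyError(ValueError):
    """Raised when a series has no energy outside the DC bin."""


#: Interference scenarios plus "none" (an undisturbed cycle).
SCENARIOS = ("none", "saturated_or_weak", "not_worn_properly", "multiple_breaths")
INTERFERENCE_SCENARIOS = SCENARIOS[1:]


def _as_channel(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class RawRecording:
    """A synchronized two-channel pressure/flow recording at fixed rate."""

    pressure: np.ndarray
    flow: np.ndarray
    sampling_rate_hz: float = 100.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.pressure = _as_channel(self.pressure, "pressure")
        self.flow = _as_channel(self.flow, "flow")
        if len(self.pressure) != len(self.flow):
            raise ValueError("pressure and flow must have equal length")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.pressure)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sampling_rate_hz


@dataclass
class RespiratoryCycle:
    """One segmented inspiration+expiration span of both channels."""

    pressure: np.ndarray
    flow: np.ndarray
    sampling_rate_hz: float = 100.0
    start_index: int = 0

    def __post_init__(self) -> None:
        self.pressure = _as_channel(self.pressure, "pressure")
        self.flow = _as_channel(self.flow, "flow")
        if len(self.pressure) != len(self.flow):
            raise ValueError("pressure and flow must have equal length")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.pressure)

    @property
    def n_samples(self) -> int:
        return len(self.pressure)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate_hz


@dataclass(frozen=True)
class ThresholdSet:
    """The six FFT/VPP bounds of the effectiveness decision rule.

    Defaults are the optimum found by the threshold grid search:
    frequency window 0.12-0.6 Hz, pressure peak-to-peak window 300-1000 Pa,
    flow peak-to-peak window 100-1650 cm^3/s.
    """

    minft_hz: float = 0.12
    maxft_hz: float = 0.6
    minpvt_pa: float = 300.0
    maxpvt_pa: float = 1000.0
    minfvt_cm3s: float = 100.0
    maxfvt_cm3s: float = 1650.0

    def __post_init__(self) -> None:
        pairs = [
            ("minft_hz", "maxft_hz", self.minft_hz, self.maxft_hz),
            ("minpvt_pa", "maxpvt_pa", self.minpvt_pa, self.maxpvt_pa),
            ("minfvt_cm3s", "maxfvt_cm3s", self.minfvt_cm3s, self.maxfvt_cm3s),
        ]
        for lo_name, hi_name, lo, hi in pairs:
            if lo < 0:
                raise ValueError(f"{lo_name} must be >= 0, got {lo}")
            if not lo < hi:
                raise ValueError(f"{lo_name} ({lo}) must be < {hi_name} ({hi})")

    def as_dict(self) -> dict:
        return {
            "minft_hz": self.minft_hz,
            "maxft_hz": self.maxft_hz,
            "minpvt_pa": self.minpvt_pa,
            "maxpvt_pa": self.maxpvt_pa,
            "minfvt_cm3s": self.minfvt_cm3s,
            "maxfvt_cm3s": self.maxfvt_cm3s,
        }


def default_thresholds() -> ThresholdSet:
    """The grid-search optimum threshold set used throughout as default."""
    return ThresholdSet()


@dataclass
class LabeledCycle:
    """A respiratory cycle with its ground-truth label and scenario tag."""

    cycle: RespiratoryCycle
    truth_label: str
    scenario: str = "none"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.truth_label not in ("effective", "ineffective"):
            raise ValueError(f"unknown truth_label {self.truth_label!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.scenario == "none") != (self.truth_label == "effective"):
            raise ValueError(
                "scenario must be 'none' if and only if truth_label is 'effective'"
            )


@dataclass
class ResampledCycle:
    """A cycle spline-resampled onto a fixed-length grid (2000 points)."""

    pressure: np.ndarray
    flow: np.ndarray
    source_length: int
    delta_t: float
    duration_s: float

    def __post_init__(self) -> None:
        self.pressure = _as_channel(self.pressure, "pressure")
        self.flow = _as_channel(self.flow, "flow")
        if len(self.pressure) != len(self.flow):
            raise ValueError("pressure and flow must have equal length")
        if not self.delta_t > 0:
            raise ValueError("delta_t must be positive")

    def __len__(self) -> int:
        return len(self.pressure)
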