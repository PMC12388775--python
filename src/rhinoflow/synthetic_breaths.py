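"""Seeded synthetic breath generator.

Produces labeled respiratory cycles with the statistical structure of real
pressure-flow recordings: effective cycles are asymmetric raised-sine flow
half-waves (positive inspiration, negative expiration) with pressure coupled
through the quadratic-magnitude law p = k * v * |v|, plus three interference
paradigms (saturated/weak, not-worn-properly, multiple breaths).  Output is a
pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LabeledCycle, RawRecording, RespiratoryCycle, SCENARIOS

__all__ = [
    "SyntheticSpec",
    "generate_effective_cycle",
    "generate_ineffective_cycle",
    "generate_cycle",
    "generate_recording",
    "draw_effective_spec",
]

SAMPLING_RATE_HZ = 100.0

# Saturation clip level: stand-in sensor full scale (no published value).
DEFAULT_CLIP_LEVEL_PA = 600.0
DEFAULT_SATURATION_OVERDRIVE = 2.0
# Burst defaults for the multiple-breaths paradigm; 1.2 Hz sits above the
# 0.6 Hz frequency ceiling so the spectral signature is realizable.
DEFAULT_BURST_FREQ_HZ = 1.2
DEFAULT_BURST_AMP_FRAC = 0.5
# Low-frequency drift for the not-worn paradigm; the half-wave cycle it
# produces peaks near 2.2x this value, safely below the 0.12 Hz floor.
DEFAULT_DRIFT_FREQ_HZ = 0.04
# Weak-breath / one-signed pressure cap: keeps peak-to-peak safely below the
# 300 Pa minimum so these cycles are rejected with certainty.
_WEAK_VPP_CAP_PA = 280.0


@dataclass
class SyntheticSpec:
    """Parameters for one synthetic respiratory cycle."""

    frequency_hz: float = 0.3
    pressure_amp_pa: float = 250.0  # half peak-to-peak target
    flow_amp_cm3s: float = 400.0  # half peak-to-peak target
    insp_fraction: float = 0.45
    noise_sigma_frac: float = 0.02
    dc_offset_pa: float = 0.0
    dc_offset_cm3s: float = 0.0
    scenario: str = "none"
    scenario_params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be positive")
        if self.pressure_amp_pa < 0 or self.flow_amp_cm3s < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0.0 < self.insp_fraction < 1.0:
            raise ValueError("insp_fraction must be in (0, 1)")
        if self.noise_sigma_frac < 0:
            raise ValueError("noise_sigma_frac must be >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _base_waveforms(spec: SyntheticSpec) -> Tuple[np.ndarray, np.ndarray, int]:
    """Noise-free flow and pressure for one cycle, plus the inspiratory length.

    Flow is two raised-sine half-waves with unequal durations whose amplitudes
    balance inspired and expired volume (zero net flow), so the peak-to-peak
    excursions sum to twice ``flow_amp_cm3s`` while the waveform stays
    mean-free.  Pressure follows the quadratic-magnitude coupling
    p = k * v * |v| scaled so pressure peak-to-peak is twice
    ``pressure_amp_pa``.
    """
    period_s = 1.0 / spec.frequency_hz
    n = int(round(period_s * SAMPLING_RATE_HZ))
    n_insp = int(round(spec.insp_fraction * n))
    n_insp = min(max(n_insp, 1), n - 1)
    n_exp = n - n_insp
    # volume balance: amp_i * n_insp == amp_e * n_exp, amp_i + amp_e == 2 * A
    amp_i = 2.0 * spec.flow_amp_cm3s * n_exp / n
    amp_e = 2.0 * spec.flow_amp_cm3s * n_insp / n
    t_insp = np.arange(n_insp)
    t_exp = np.arange(n_exp)
    flow = np.concatenate(
        [
            amp_i * np.sin(np.pi * (t_insp + 0.5) / n_insp),
            -amp_e * np.sin(np.pi * (t_exp + 0.5) / n_exp),
        ]
    )
    if spec.flow_amp_cm3s > 0:
        # pressure VPP = k * (amp_i^2 + amp_e^2) -> target 2 * pressure_amp
        k = 2.0 * spec.pressure_amp_pa / (amp_i**2 + amp_e**2)
        pressure = k * flow * np.abs(flow)
    else:
        pressure = np.zeros_like(flow)
    return flow, pressure, n_insp


_NOISE_SMOOTH_SIGMA = 5.0  # samples; sensor noise is band-limited, not white


def _smooth_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Band-limited Gaussian noise with sample standard deviation ``sigma``.

    White noise convolved with a Gaussian kernel; smoothness keeps the
    signal-plus-noise locally monotone at flow zero-crossings, as an
    oversampled analog front end would.
    """
    half = int(4 * _NOISE_SMOOTH_SIGMA)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / _NOISE_SMOOTH_SIGMA) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))  # unit output variance
    white = rng.normal(0.0, 1.0, size=n + 2 * half)
    return sigma * np.convolve(white, kernel, mode="valid")


def _add_noise(
    flow: np.ndarray,
    pressure: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    # noise scales with the realized channel amplitude (falls back to the
    # spec target for a silent channel)
    amp_p = np.max(np.abs(pressure), initial=0.0) or spec.pressure_amp_pa
    amp_f = np.max(np.abs(flow), initial=0.0) or spec.flow_amp_cm3s
    sig_p = spec.noise_sigma_frac * amp_p
    sig_f = spec.noise_sigma_frac * amp_f
    pressure = pressure + _smooth_noise(rng, len(pressure), sig_p) if sig_p > 0 else pressure
    flow = flow + _smooth_noise(rng, len(flow), sig_f) if sig_f > 0 else flow
    return flow, pressure


def generate_effective_cycle(spec: SyntheticSpec) -> LabeledCycle:
    """Generate one undisturbed cycle; duration 1/frequency_hz at 100 Hz."""
    if spec.scenario != "none":
        raise ValueError("generate_effective_cycle requires scenario == 'none'")
    if spec.noise_sigma_frac >= 1.0 or spec.pressure_amp_pa <= 0:
        raise ValueError("degenerate spec: pressure swing below the noise floor")
    rng = np.random.default_rng(spec.seed)
    flow, pressure, _ = _base_waveforms(spec)
    flow, pressure = _add_noise(flow, pressure, spec, rng)
    cycle = RespiratoryCycle(
        pressure=pressure + spec.dc_offset_pa,
        flow=flow + spec.dc_offset_cm3s,
        sampling_rate_hz=SAMPLING_RATE_HZ,
    )
    return LabeledCycle(cycle=cycle, truth_label="effective", scenario="none", seed=spec.seed)


def _saturated_or_weak(spec: SyntheticSpec, rng: np.random.Generator):
    params = spec.scenario_params
    variant = params.get("variant", "saturated")
    flow, pressure, _ = _base_waveforms(spec)
    if variant == "saturated":
        clip = float(params.get("clip_level", DEFAULT_CLIP_LEVEL_PA))
        overdrive = float(params.get("overdrive", DEFAULT_SATURATION_OVERDRIVE))
        peak = np.max(np.abs(pressure))
        if peak > 0:
            scale = overdrive * clip / peak
            pressure = np.clip(pressure * scale, -clip, clip)
            flow = flow * np.sqrt(scale)  # same quadratic coupling, no flow clip
    elif variant == "weak":
        # breathing too shallow for the 150 Pa reference pressure
        peak = np.max(np.abs(pressure))
        cap = _WEAK_VPP_CAP_PA / 2.0
        if peak > cap:
            scale = cap / peak
            pressure = pressure * scale
            flow = flow * np.sqrt(scale)
    else:
        raise ValueError(f"unknown saturated_or_weak variant {variant!r}")
    return flow, pressure


def _not_worn_properly(spec: SyntheticSpec, rng: np.random.Generator):
    params = spec.scenario_params
    variant = params.get("variant", "drift")
    if variant == "zeroed":
        flow, pressure, _ = _base_waveforms(spec)
        channel = params.get("zeroed_channel", "pressure")
        if channel == "pressure":
            pressure = np.zeros_like(pressure)
        elif channel == "flow":
            flow = np.zeros_like(flow)
        else:
            raise ValueError(f"unknown zeroed_channel {channel!r}")
        return flow, pressure, {"skip_noise_channel": channel}
    if variant == "one_signed":
        # a lost phase: rectified weakly-coupled signals, all samples one sign
        flow, pressure, _ = _base_waveforms(spec)
        sign = -1.0 if params.get("missing_phase", "expiratory") == "inspiratory" else 1.0
        flow = sign * np.abs(flow)
        pressure = sign * np.abs(pressure)
        vpp = np.max(pressure) - np.min(pressure)
        if vpp > _WEAK_VPP_CAP_PA:  # poor seal attenuates pressure coupling
            pressure = pressure * (_WEAK_VPP_CAP_PA / vpp)
        return flow, pressure, {}
    if variant == "drift":
        # ambient low-frequency fluctuation instead of breath signal; the
        # cycle spans one half-wave of the drift (what the segmenter would
        # carve out of slowly drifting data), so the spectral peak sits at
        # the drift frequency, left of the valid band
        drift_freq = float(params.get("drift_freq_hz", DEFAULT_DRIFT_FREQ_HZ))
        n = int(round(SAMPLING_RATE_HZ / (2.0 * drift_freq)))
        t = np.arange(n)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        hump = np.sin(np.pi * (t + 0.5) / n)
        pressure = sign * spec.pressure_amp_pa * hump
        flow = sign * spec.flow_amp_cm3s * hump
        return flow, pressure, {}
    raise ValueError(f"unknown not_worn_properly variant {variant!r}")


def _multiple_breaths(spec: SyntheticSpec, rng: np.random.Generator):
    params = spec.scenario_params
    burst_freq = float(params.get("burst_freq_hz", DEFAULT_BURST_FREQ_HZ))
    amp_frac = float(params.get("burst_amp_frac", DEFAULT_BURST_AMP_FRAC))
    phase = params.get("burst_phase", "inspiratory")
    flow, pressure, n_insp = _base_waveforms(spec)
    n = len(flow)
    window = np.zeros(n)
    if phase in ("inspiratory", "both"):
        window[:n_insp] = 1.0
    if phase in ("expiratory", "both"):
        window[n_insp:] = 1.0
    if phase not in ("inspiratory", "expiratory", "both"):
        raise ValueError(f"unknown burst_phase {phase!r}")
    t = np.arange(n) / SAMPLING_RATE_HZ
    burst = amp_frac * spec.flow_amp_cm3s * np.sin(2.0 * np.pi * burst_freq * t)
    # superimposed breaths reduce the main peak and add high-frequency energy
    flow = (1.0 - 0.5 * amp_frac) * flow + window * burst
    if spec.flow_amp_cm3s > 0:
        k = spec.pressure_amp_pa / spec.flow_amp_cm3s**2
        pressure = k * flow * np.abs(flow)
    return flow, pressure


def generate_ineffective_cycle(spec: SyntheticSpec) -> LabeledCycle:
    """Generate one disturbed cycle under the spec's interference scenario."""
    if spec.scenario == "none":
        raise ValueError("generate_ineffective_cycle requires an interference scenario")
    rng = np.random.default_rng(spec.seed)
    skip_channel = None
    if spec.scenario == "saturated_or_weak":
        flow, pressure = _saturated_or_weak(spec, rng)
    elif spec.scenario == "not_worn_properly":
        flow, pressure, extra = _not_worn_properly(spec, rng)
        skip_channel = extra.get("skip_noise_channel")
    elif spec.scenario == "multiple_breaths":
        flow, pressure = _multiple_breaths(spec, rng)
    else:  # pragma: no cover - guarded by SyntheticSpec validation
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    noisy_flow, noisy_pressure = _add_noise(flow, pressure, spec, rng)
    # zeroed channels stay exactly zero (sensor disconnected, no noise floor)
    if skip_channel == "pressure":
        noisy_pressure = pressure
    elif skip_channel == "flow":
        noisy_flow = flow
    cycle = RespiratoryCycle(
        pressure=noisy_pressure + spec.dc_offset_pa,
        flow=noisy_flow + spec.dc_offset_cm3s,
        sampling_rate_hz=SAMPLING_RATE_HZ,
    )
    return LabeledCycle(
        cycle=cycle, truth_label="ineffective", scenario=spec.scenario, seed=spec.seed
    )


def generate_cycle(spec: SyntheticSpec) -> LabeledCycle:
    """Dispatch on the spec's scenario."""
    if spec.scenario == "none":
        return generate_effective_cycle(spec)
    return generate_ineffective_cycle(spec)


def draw_effective_spec(
    rng: np.random.Generator,
    freq_range=(0.2, 0.5),
    pressure_vpp_range=(350.0, 900.0),
    flow_vpp_range=(150.0, 1500.0),
    noise_sigma_frac: float = 0.02,
) -> SyntheticSpec:
    """Draw a random effective-cycle spec strictly inside the default margins."""
    return SyntheticSpec(
        frequency_hz=float(rng.uniform(*freq_range)),
        pressure_amp_pa=float(rng.uniform(*pressure_vpp_range)) / 2.0,
        flow_amp_cm3s=float(rng.uniform(*flow_vpp_range)) / 2.0,
        noise_sigma_frac=noise_sigma_frac,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_recording(
    specs: Sequence[SyntheticSpec],
    gap_s: float = 0.2,
    baseline_noise_sigma: float = 1.0,
    seed: int = 0,
) -> Tuple[RawRecording, List[LabeledCycle], List[Tuple[int, int]]]:
    """Concatenate generated cycles with noisy near-zero gaps.

    Returns the recording, the labeled cycles in order, and the ground-truth
    ``(start, stop_exclusive)`` boundary of each cycle within the recording.
    """
    if len(specs) == 0:
        raise ValueError("specs must be non-empty")
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    rng = np.random.default_rng(seed)
    n_gap = int(round(gap_s * SAMPLING_RATE_HZ))
    pressure_parts: List[np.ndarray] = []
    flow_parts: List[np.ndarray] = []
    labeled: List[LabeledCycle] = []
    boundaries: List[Tuple[int, int]] = []
    pos = 0
    for j, spec in enumerate(specs):
        lc = generate_cycle(spec)
        labeled.append(lc)
        boundaries.append((pos, pos + len(lc.cycle)))
        pressure_parts.append(lc.cycle.pressure)
        flow_parts.append(lc.cycle.flow)
        pos += len(lc.cycle)
        if j < len(specs) - 1 and n_gap > 0:
            gp = rng.normal(0.0, baseline_noise_sigma, size=n_gap) + spec.dc_offset_pa
            gf = rng.normal(0.0, baseline_noise_sigma, size=n_gap) + spec.dc_offset_cm3s
            pressure_parts.append(gp)
            flow_parts.append(gf)
            pos += n_gap
    rec = RawRecording(
        pressure=np.concatenate(pressure_parts),
        flow=np.concatenate(flow_parts),
        sampling_rate_hz=SAMPLING_RATE_HZ,
    )
    return rec, labeled, boundaries
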