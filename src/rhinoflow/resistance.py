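"""The four nasal-resistance indicators, per phase.

mean:      reference-pressure resistance, P_ref / V_pred, with the flow at
           +/-150 Pa linearly interpolated between the first bracketing pair
vertex:    |P| / |V| at the sample of maximal |flow|
effective: RMS(pressure) / RMS(flow) over the phase (trapezoidal integrals)
Broms:     tangent of the polar angle of the scaled pressure-flow curve at
           reference radius 2, with the angle-vs-radius law fit by least
           squares over points near the reference radius

Mean and Broms resistance are computed per cycle on raw effective cycles;
vertex and effective resistance are computed on the average of the
spline-resampled cycles.  All reported resistances are positive; the
expiratory phase is negated internally so magnitudes can be used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import RespiratoryCycle, ResampledCycle
from .resampling import average_cycles, resample_cycle

__all__ = [
    "PhaseSegment",
    "BromsFit",
    "Measure",
    "ResistanceResult",
    "ResistanceConfig",
    "GroupResistance",
    "split_phases",
    "mean_resistance",
    "vertex_resistance",
    "effective_resistance",
    "broms_resistance",
    "resistance_result",
    "compute_all",
    "interpret_severity",
]

INDICATORS = ("vertex", "effective", "mean", "broms")
PHASES = ("ins", "exp")

P_REF_PA = 150.0
BROMS_R_REF = 2.0
BROMS_BAND = 0.25
BROMS_UNIT_PA = 100.0
BROMS_UNIT_CM3S = 100.0
SEVERITY_CUTOFF = 0.75


class NotComputable(ValueError):
    """A resistance indicator cannot be evaluated on this segment."""


@dataclass
class PhaseSegment:
    """One phase of a cycle with magnitudes positive (expiration pre-negated)."""

    phase: str  # "inspiratory" | "expiratory"
    pressure: np.ndarray
    flow: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if len(self.pressure) != len(self.flow):
            raise ValueError("pressure and flow must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate_hz


@dataclass
class BromsFit:
    v0: float  # intercept, radians
    c: float  # slope, radians per radius unit
    r_ref: float
    band_halfwidth: float
    n_points: int


@dataclass
class Measure:
    """A resistance value or the reason it could not be computed."""

    value: Optional[float] = None
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class ResistanceResult:
    vertex_ins: Measure = field(default_factory=Measure)
    vertex_exp: Measure = field(default_factory=Measure)
    effective_ins: Measure = field(default_factory=Measure)
    effective_exp: Measure = field(default_factory=Measure)
    mean_ins: Measure = field(default_factory=Measure)
    mean_exp: Measure = field(default_factory=Measure)
    broms_ins: Measure = field(default_factory=Measure)
    broms_exp: Measure = field(default_factory=Measure)

    def get(self, indicator: str, phase: str) -> Measure:
        return getattr(self, f"{indicator}_{phase}")

    def set(self, indicator: str, phase: str, measure: Measure) -> None:
        setattr(self, f"{indicator}_{phase}", measure)

    def as_dict(self) -> dict:
        return {
            f"{ind}_{ph}": {"value": m.value, "status": m.status}
            for ind in INDICATORS
            for ph in PHASES
            for m in [self.get(ind, ph)]
        }


@dataclass
class ResistanceConfig:
    p_ref_pa: float = P_REF_PA
    broms_r_ref: float = BROMS_R_REF
    broms_band: float = BROMS_BAND
    broms_unit_pa: float = BROMS_UNIT_PA
    broms_unit_cm3s: float = BROMS_UNIT_CM3S
    resample_n: int = 2000


def split_phases(
    cycle: Union[RespiratoryCycle, ResampledCycle],
) -> Tuple[PhaseSegment, Optional[PhaseSegment]]:
    """Split at the first index where flow turns negative and stays negative.

    The expiratory segment is negated so both segments carry positive
    magnitudes.  With no sign change the expiratory segment is ``None``.
    """
    flow = np.asarray(cycle.flow, dtype=float)
    pressure = np.asarray(cycle.pressure, dtype=float)
    if isinstance(cycle, ResampledCycle):
        fs = (len(cycle) - 1) / cycle.duration_s
    else:
        fs = cycle.sampling_rate_hz
    n = len(flow)
    split = None
    for i in range(1, n):
        if flow[i] < 0.0 and (i + 1 >= n or flow[i + 1] < 0.0):
            split = i
            break
    if split is None:
        return (
            PhaseSegment("inspiratory", pressure, flow, fs),
            None,
        )
    insp = PhaseSegment("inspiratory", pressure[:split], flow[:split], fs)
    exp = PhaseSegment("expiratory", -pressure[split:], -flow[split:], fs)
    return insp, exp


def mean_resistance(seg: PhaseSegment, p_ref_pa: float = P_REF_PA) -> float:
    """Reference-pressure resistance P_ref / V_pred.

    The first adjacent sample pair whose pressures bracket ``p_ref_pa``
    defines a connecting line along which the flow at the reference pressure
    is predicted.
    """
    p = seg.pressure
    v = seg.flow
    if len(p) == 0 or np.max(np.abs(p)) < p_ref_pa:
        raise NotComputable("reference pressure not reached")
    for i in range(len(p) - 1):
        p0, p1 = p[i], p[i + 1]
        if (p0 - p_ref_pa) * (p1 - p_ref_pa) <= 0.0:
            if p1 == p0:
                v_pred = v[i]
            else:
                v_pred = v[i] + (p_ref_pa - p0) * (v[i + 1] - v[i]) / (p1 - p0)
            if v_pred == 0.0:
                raise NotComputable("zero predicted flow at reference pressure")
            return abs(p_ref_pa / v_pred)
    # a single sample sitting exactly at p_ref with no neighbor pair
    exact = np.flatnonzero(p == p_ref_pa)
    if len(exact) and v[exact[0]] != 0.0:
        return abs(p_ref_pa / v[exact[0]])
    raise NotComputable("reference pressure not crossed")


def vertex_resistance(seg: PhaseSegment) -> float:
    """|P| / |V| at the (earliest) sample of maximal |flow|."""
    if len(seg.flow) == 0:
        raise NotComputable("empty segment")
    idx = int(np.argmax(np.abs(seg.flow)))
    v = abs(seg.flow[idx])
    if v == 0.0:
        raise NotComputable("zero maximal flow")
    return abs(seg.pressure[idx]) / v


def effective_resistance(seg: PhaseSegment) -> float:
    """RMS pressure over RMS flow with trapezoidal time integrals."""
    n = len(seg.flow)
    if n == 0:
        raise NotComputable("empty segment")
    if n == 1:
        p_eff = abs(seg.pressure[0])
        v_eff = abs(seg.flow[0])
    else:
        duration = (n - 1) * seg.dt
        p_eff = math.sqrt(np.trapezoid(seg.pressure**2, dx=seg.dt) / duration)
        v_eff = math.sqrt(np.trapezoid(seg.flow**2, dx=seg.dt) / duration)
    if v_eff == 0.0:
        raise NotComputable("zero effective flow")
    return p_eff / v_eff


def broms_resistance(
    seg: PhaseSegment,
    r_ref: float = BROMS_R_REF,
    band: float = BROMS_BAND,
    unit_pa: float = BROMS_UNIT_PA,
    unit_cm3s: float = BROMS_UNIT_CM3S,
) -> Tuple[float, BromsFit]:
    """Polar-coordinate resistance at the reference radius.

    Pressure and flow are scaled to Broms coordinates (one radial unit =
    ``unit_pa`` Pa / ``unit_cm3s`` cm^3/s), points within ``band`` of the
    reference radius feed an ordinary least-squares fit of angle on radius,
    and the resistance is the tangent of the predicted angle at ``r_ref``.
    """
    x = np.abs(seg.flow) / unit_cm3s
    y = np.abs(seg.pressure) / unit_pa
    r = np.hypot(x, y)
    mask = np.abs(r - r_ref) <= band
    if int(np.sum(mask)) < 2:
        raise NotComputable(f"curve does not cross radius {r_ref}")
    r_sel = r[mask]
    v_sel = np.arctan2(y[mask], x[mask])
    if np.ptp(r_sel) == 0.0:
        v0, c = float(np.mean(v_sel)), 0.0
    else:
        c, v0 = (float(z) for z in np.polyfit(r_sel, v_sel, 1))
    angle = v0 + c * r_ref
    fit = BromsFit(
        v0=v0, c=c, r_ref=r_ref, band_halfwidth=band, n_points=int(np.sum(mask))
    )
    return math.tan(angle), fit


def _measure(fn, *args, **kwargs) -> Measure:
    try:
        value = fn(*args, **kwargs)
        if isinstance(value, tuple):
            value = value[0]
        return Measure(value=float(value), status="ok")
    except NotComputable as exc:
        return Measure(value=None, status=f"not_computable: {exc}")


def resistance_result(
    cycle: Union[RespiratoryCycle, ResampledCycle],
    config: Optional[ResistanceConfig] = None,
) -> ResistanceResult:
    """All four indicators for both phases of a single cycle."""
    config = config or ResistanceConfig()
    insp, exp = split_phases(cycle)
    result = ResistanceResult()
    for phase_name, seg in (("ins", insp), ("exp", exp)):
        if seg is None:
            for ind in INDICATORS:
                result.set(ind, phase_name, Measure(None, "not_computable: no expiratory phase"))
            continue
        result.set("mean", phase_name, _measure(mean_resistance, seg, config.p_ref_pa))
        result.set("vertex", phase_name, _measure(vertex_resistance, seg))
        result.set("effective", phase_name, _measure(effective_resistance, seg))
        result.set(
            "broms",
            phase_name,
            _measure(
                broms_resistance,
                seg,
                config.broms_r_ref,
                config.broms_band,
                config.broms_unit_pa,
                config.broms_unit_cm3s,
            ),
        )
    return result


@dataclass
class GroupResistance:
    per_cycle: List[ResistanceResult]
    group: ResistanceResult
    averaged_cycle: Optional[ResampledCycle] = None


def compute_all(
    effective_cycles: Sequence[RespiratoryCycle],
    config: Optional[ResistanceConfig] = None,
) -> GroupResistance:
    """Group-level resistances plus per-cycle values for stability analysis.

    Group mean/Broms are the average of the per-cycle values over raw cycles;
    group vertex/effective come from the average of the resampled cycles.
    """
    if len(effective_cycles) == 0:
        raise ValueError("need at least one effective cycle")
    config = config or ResistanceConfig()
    per_cycle = [resistance_result(c, config) for c in effective_cycles]

    group = ResistanceResult()
    for ind in ("mean", "broms"):
        for ph in PHASES:
            values = [r.get(ind, ph).value for r in per_cycle if r.get(ind, ph).ok]
            if values:
                group.set(ind, ph, Measure(float(np.mean(values)), "ok"))
            else:
                group.set(ind, ph, Measure(None, "not_computable: no usable cycle"))

    averaged = average_cycles([resample_cycle(c, config.resample_n) for c in effective_cycles])
    avg_result = resistance_result(averaged, config)
    for ind in ("vertex", "effective"):
        for ph in PHASES:
            group.set(ind, ph, avg_result.get(ind, ph))
    return GroupResistance(per_cycle=per_cycle, group=group, averaged_cycle=averaged)


def interpret_severity(resistance: float, cutoff: float = SEVERITY_CUTOFF) -> str:
    """"normal" below the cutoff, "obstructed" at or above it."""
    if resistance < 0:
        raise ValueError("resistance must be non-negative")
    return "normal" if resistance < cutoff else "obstructed"
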