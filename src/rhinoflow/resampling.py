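"""Natural cubic-spline interpolation and fixed-length resampling of cycles.

Knots sit at sample indices 1..Ln (unit spacing).  Each interval [k, k+1]
carries a cubic in the global index variable, S_k(I) = a*I^3 + b*I^2 + c*I + d,
constrained to interpolate the knots with C2 continuity and zero second
derivative at both ends.  Resampling evaluates the spline at the recurrence
I_1 = 1, I_{j+1} = I_j + Ln/N for N = 2000 output points; for cycles shorter
than N the final points run slightly past the last knot (by less than one
sample interval) and are evaluated by extending the edge polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.linalg import solve_banded

from .core import ResampledCycle, RespiratoryCycle

__all__ = [
    "RESAMPLE_POINTS",
    "SplineModel",
    "fit_natural_cubic_spline",
    "resample_cycle",
    "average_cycles",
]

RESAMPLE_POINTS = 2000


@dataclass
class SplineModel:
    """Piecewise cubic over unit-spaced knots at indices 1..Ln.

    ``coefficients`` has shape (Ln-1, 4): row k-1 holds (a, b, c, d) of the
    cubic on [k, k+1] expressed in powers of the global index I.  Evaluation
    uses the numerically equivalent local form in t = I - k (the global-power
    form cancels catastrophically for large knot counts).
    """

    knots: np.ndarray  # knot values x_1..x_Ln
    coefficients: np.ndarray
    local_coefficients: np.ndarray  # per-interval cubic in t = I - k

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def __call__(self, points: Sequence[float]) -> np.ndarray:
        """Evaluate at global indices; edge intervals extend beyond [1, Ln]."""
        pts = np.asarray(points, dtype=float)
        interval = np.clip(np.floor(pts).astype(int), 1, self.n_knots - 1) - 1
        a3, a2, a1, a0 = self.local_coefficients[interval].T
        t = pts - (interval + 1)
        return ((a3 * t + a2) * t + a1) * t + a0


def fit_natural_cubic_spline(values: Sequence[float]) -> SplineModel:
    """Solve the tridiagonal natural-spline system over unit-spaced knots."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 values, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values contain non-finite entries")
    n = len(x)
    # second derivatives M at the knots: natural ends M_1 = M_n = 0; interior
    # rows M_{k-1} + 4 M_k + M_{k+1} = 6 (x_{k-1} - 2 x_k + x_{k+1})
    m = np.zeros(n)
    if n > 2:
        ab = np.zeros((3, n - 2))
        ab[0, 1:] = 1.0
        ab[1, :] = 4.0
        ab[2, :-1] = 1.0
        rhs = 6.0 * (x[:-2] - 2.0 * x[1:-1] + x[2:])
        m[1:-1] = solve_banded((1, 1), ab, rhs)

    # local form on [k, k+1] with t = I - k:
    #   S(I) = x_k + C t + (M_k / 2) t^2 + ((M_{k+1} - M_k) / 6) t^3
    k = np.arange(1, n)  # left knot index of each interval
    mk, mk1 = m[:-1], m[1:]
    A = (mk1 - mk) / 6.0
    B = mk / 2.0
    C = (x[1:] - x[:-1]) - (2.0 * mk + mk1) / 6.0
    D = x[:-1]
    # expand t = I - k into global powers of I
    a = A
    b = B - 3.0 * A * k
    c = C - 2.0 * B * k + 3.0 * A * k**2
    d = D - C * k + B * k**2 - A * k**3
    return SplineModel(
        knots=x,
        coefficients=np.column_stack([a, b, c, d]),
        local_coefficients=np.column_stack([A, B, C, D]),
    )


def resample_cycle(cycle: RespiratoryCycle, n_points: int = RESAMPLE_POINTS) -> ResampledCycle:
    """Spline-resample both channels onto the fixed ``n_points`` grid."""
    ln = len(cycle)
    if ln < 3:
        raise ValueError(f"cycle too short to resample ({ln} samples)")
    delta_t = ln / n_points
    points = 1.0 + delta_t * np.arange(n_points)
    pressure = fit_natural_cubic_spline(cycle.pressure)(points)
    flow = fit_natural_cubic_spline(cycle.flow)(points)
    return ResampledCycle(
        pressure=pressure,
        flow=flow,
        source_length=ln,
        delta_t=delta_t,
        duration_s=cycle.duration_s,
    )


def average_cycles(cycles: Sequence[ResampledCycle]) -> ResampledCycle:
    """Pointwise arithmetic mean of resampled cycles."""
    if len(cycles) == 0:
        raise ValueError("no cycles to average")
    n = len(cycles[0])
    if any(len(c) != n for c in cycles):
        raise ValueError("resampled cycles must share the same length")
    return ResampledCycle(
        pressure=np.mean([c.pressure for c in cycles], axis=0),
        flow=np.mean([c.flow for c in cycles], axis=0),
        source_length=cycles[0].source_length,
        delta_t=float(np.mean([c.delta_t for c in cycles])),
        duration_s=float(np.mean([c.duration_s for c in cycles])),
    )
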