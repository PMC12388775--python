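"""Exhaustive six-threshold grid search over labeled cycle sets.

Per-cycle features (dominant frequency of each channel and both peak-to-peak
amplitudes) are computed once; every threshold combination is then evaluated
against the cached features, which is equivalent to re-classifying each cycle
per combination.  Ranking is by accuracy, with ties broken by the widest
frequency interval, then the widest pressure interval, then the widest flow
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import LabeledCycle, NoDominantFrequencyError, ThresholdSet, INTERFERENCE_SCENARIOS
from .cycle_validation import classify_cycle, dominant_frequency, peak_to_peak

__all__ = [
    "GridSpec",
    "SearchResult",
    "ClassificationMetrics",
    "classification_metrics",
    "scenario_accuracy",
    "cycle_features",
    "grid_search",
]


@dataclass(frozen=True)
class GridSpec:
    """Axis ranges (lo, hi, step) for the FFT, pressure-VPP and flow-VPP grids."""

    fft_range_hz: Tuple[float, float, float] = (0.08, 0.68, 0.04)
    pvt_range_pa: Tuple[float, float, float] = (100.0, 1500.0, 100.0)
    fvt_range_cm3s: Tuple[float, float, float] = (50.0, 2050.0, 100.0)

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in (
            ("fft_range_hz", self.fft_range_hz),
            ("pvt_range_pa", self.pvt_range_pa),
            ("fvt_range_cm3s", self.fvt_range_cm3s),
        ):
            if not lo < hi:
                raise ValueError(f"{name}: lo must be < hi")
            if not step > 0:
                raise ValueError(f"{name}: step must be positive")

    def axis_values(self, which: str) -> np.ndarray:
        lo, hi, step = getattr(self, which)
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)


@dataclass
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    recall: Optional[float]
    precision: Optional[float]
    accuracy: float

    def as_dict(self) -> dict:
        n = self.tp + self.fp + self.tn + self.fn
        pct = lambda k: 100.0 * k / n if n else None
        return {
            "counts": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "percentages": {
                "tp": pct(self.tp),
                "fp": pct(self.fp),
                "tn": pct(self.tn),
                "fn": pct(self.fn),
            },
            "recall": self.recall,
            "precision": self.precision,
            "accuracy": self.accuracy,
        }


def classification_metrics(
    truth: Sequence[str], predicted: Sequence[str]
) -> ClassificationMetrics:
    """Confusion counts and metrics with "effective" as the positive class.

    Metrics with a zero denominator come back as ``None`` (undefined), never 0.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    if len(truth) == 0:
        raise ValueError("empty label lists")
    t = np.asarray([lbl == "effective" for lbl in truth])
    p = np.asarray([lbl == "effective" for lbl in predicted])
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    accuracy = (tp + tn) / len(t)
    return ClassificationMetrics(tp, fp, tn, fn, recall, precision, accuracy)


def scenario_accuracy(
    labeled: Sequence[LabeledCycle], ts: ThresholdSet
) -> Dict[str, float]:
    """Per-interference-scenario fraction of cycles classified ineffective."""
    totals: Dict[str, int] = {}
    rejected: Dict[str, int] = {}
    for lc in labeled:
        if lc.scenario not in INTERFERENCE_SCENARIOS:
            continue
        totals[lc.scenario] = totals.get(lc.scenario, 0) + 1
        if not classify_cycle(lc.cycle, ts).is_effective:
            rejected[lc.scenario] = rejected.get(lc.scenario, 0) + 1
    return {s: rejected.get(s, 0) / n for s, n in totals.items()}


def cycle_features(labeled: Sequence[LabeledCycle]) -> np.ndarray:
    """Cached features (f_pressure, f_flow, vpp_pressure, vpp_flow) per cycle.

    A channel with no dominant frequency is stored as NaN, which fails every
    frequency window.
    """
    feats = np.empty((len(labeled), 4))
    for i, lc in enumerate(labeled):
        cyc = lc.cycle
        for j, channel in enumerate((cyc.pressure, cyc.flow)):
            try:
                feats[i, j] = dominant_frequency(channel, cyc.sampling_rate_hz)
            except (ValueError, NoDominantFrequencyError):
                feats[i, j] = np.nan
        feats[i, 2] = peak_to_peak(cyc.pressure)
        feats[i, 3] = peak_to_peak(cyc.flow)
    return feats


@dataclass
class SearchResult:
    ranked: List[Tuple[ThresholdSet, float]]
    top_accuracy: float
    n_combinations: int


def _interval_pairs(values: np.ndarray) -> np.ndarray:
    """All (lo, hi) pairs with lo < hi from an axis, shape (n_pairs, 2)."""
    lo, hi = np.meshgrid(values, values, indexing="ij")
    mask = lo < hi
    return np.column_stack([lo[mask], hi[mask]])


def grid_search(
    labeled: Sequence[LabeledCycle],
    grid: Optional[GridSpec] = None,
    top_k: int = 1000,
) -> SearchResult:
    """Rank every threshold combination on the grid by labeling accuracy."""
    grid = grid or GridSpec()
    labels = {lc.truth_label for lc in labeled}
    if labels != {"effective", "ineffective"}:
        raise ValueError("degenerate labels: need both effective and ineffective cycles")

    feats = cycle_features(labeled)
    truth = np.asarray([lc.truth_label == "effective" for lc in labeled])
    n = len(labeled)

    f_pairs = _interval_pairs(grid.axis_values("fft_range_hz"))
    p_pairs = _interval_pairs(grid.axis_values("pvt_range_pa"))
    v_pairs = _interval_pairs(grid.axis_values("fvt_range_cm3s"))

    def _pair_masks(pairs: np.ndarray, cols: List[int]) -> np.ndarray:
        ok = np.ones((len(pairs), n), dtype=bool)
        for col in cols:
            x = feats[:, col]
            ok &= (pairs[:, :1] <= x) & (x <= pairs[:, 1:2])
        return ok

    mf = _pair_masks(f_pairs, [0, 1])  # both channels in the frequency window
    mp = _pair_masks(p_pairs, [2])
    mv = _pair_masks(v_pairs, [3])

    nf, npp, nv = len(f_pairs), len(p_pairs), len(v_pairs)
    acc = np.empty((nf, npp, nv))
    mpv = mp[:, None, :] & mv[None, :, :]  # (npp, nv, n)
    for i in range(nf):
        pred = mpv & mf[i]  # (npp, nv, n)
        acc[i] = (pred == truth).mean(axis=-1)

    flat = acc.ravel()
    f_width = (f_pairs[:, 1] - f_pairs[:, 0])[:, None, None]
    p_width = (p_pairs[:, 1] - p_pairs[:, 0])[None, :, None]
    v_width = (v_pairs[:, 1] - v_pairs[:, 0])[None, None, :]
    fw = np.broadcast_to(f_width, acc.shape).ravel()
    pw = np.broadcast_to(p_width, acc.shape).ravel()
    vw = np.broadcast_to(v_width, acc.shape).ravel()
    # lexsort: last key is primary; negate for descending order
    order = np.lexsort((-vw, -pw, -fw, -flat))

    ranked: List[Tuple[ThresholdSet, float]] = []
    for idx in order[: max(top_k, 1)]:
        i, rem = divmod(int(idx), npp * nv)
        j, k = divmod(rem, nv)
        ts = ThresholdSet(
            minft_hz=float(f_pairs[i, 0]),
            maxft_hz=float(f_pairs[i, 1]),
            minpvt_pa=float(p_pairs[j, 0]),
            maxpvt_pa=float(p_pairs[j, 1]),
            minfvt_cm3s=float(v_pairs[k, 0]),
            maxfvt_cm3s=float(v_pairs[k, 1]),
        )
        ranked.append((ts, float(flat[idx])))
    return SearchResult(
        ranked=ranked,
        top_accuracy=float(flat[order[0]]),
        n_combinations=int(flat.size),
    )
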