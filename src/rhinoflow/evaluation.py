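"""Within-group stability analysis of the four resistance indicators.

For each group of cycles the four indicators are computed per cycle, and the
sample standard deviation (n-1 denominator) per indicator and phase is the
group's dispersion.  The SD distribution across groups is summarized by its
median and interquartile range, separately for unfiltered cycles and cycles
gated by the effectiveness classifier; the report gives the unfiltered/filtered
median ratio per indicator and phase.  Quartiles use numpy's default linear
interpolation rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import RespiratoryCycle, ThresholdSet, default_thresholds
from .cycle_validation import classify_cycle
from .resistance import INDICATORS, PHASES, ResistanceConfig, resistance_result

__all__ = [
    "IndicatorStability",
    "StabilitySummary",
    "within_group_sd",
    "stability_report",
]

logger = logging.getLogger(__name__)

MODES = ("unfiltered", "filtered")
QUANTILE_METHOD = "linear"


@dataclass
class IndicatorStability:
    group_sds: List[float]
    median_sd: float
    q1: float
    q3: float

    @property
    def iqr_sd(self) -> float:
        return self.q3 - self.q1


@dataclass
class StabilitySummary:
    mode: str
    per_indicator: Dict[Tuple[str, str], IndicatorStability]
    n_groups_used: int

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "quantile_method": QUANTILE_METHOD,
            "n_groups_used": self.n_groups_used,
            "indicators": {
                f"{ind}_{ph}": {
                    "group_sds": stats.group_sds,
                    "median_sd": stats.median_sd,
                    "q1": stats.q1,
                    "q3": stats.q3,
                    "iqr_sd": stats.iqr_sd,
                }
                for (ind, ph), stats in self.per_indicator.items()
            },
        }


def within_group_sd(
    groups: Sequence[Sequence[RespiratoryCycle]],
    ts: Optional[ThresholdSet] = None,
    mode: str = "filtered",
    config: Optional[ResistanceConfig] = None,
) -> StabilitySummary:
    """Within-group SD of each indicator, summarized across groups.

    In "filtered" mode only cycles accepted by the classifier contribute; in
    "unfiltered" mode every segmented cycle does.  Groups with fewer than two
    usable cycles for an indicator are excluded from that indicator's SD
    distribution (with a logged warning when a whole group drops out).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    ts = ts or default_thresholds()
    config = config or ResistanceConfig()

    sds: Dict[Tuple[str, str], List[float]] = {
        (ind, ph): [] for ind in INDICATORS for ph in PHASES
    }
    n_used = 0
    for g, group in enumerate(groups):
        if mode == "filtered":
            cycles = [c for c in group if classify_cycle(c, ts).is_effective]
        else:
            cycles = list(group)
        if len(cycles) < 2:
            logger.warning(
                "group %d has %d usable cycle(s) in %s mode; excluded",
                g, len(cycles), mode,
            )
            continue
        n_used += 1
        results = [resistance_result(c, config) for c in cycles]
        for ind in INDICATORS:
            for ph in PHASES:
                values = [r.get(ind, ph).value for r in results if r.get(ind, ph).ok]
                if len(values) >= 2:
                    sds[(ind, ph)].append(float(np.std(values, ddof=1)))

    per_indicator: Dict[Tuple[str, str], IndicatorStability] = {}
    for key, values in sds.items():
        if values:
            arr = np.asarray(values)
            per_indicator[key] = IndicatorStability(
                group_sds=list(map(float, arr)),
                median_sd=float(np.median(arr)),
                q1=float(np.percentile(arr, 25, method=QUANTILE_METHOD)),
                q3=float(np.percentile(arr, 75, method=QUANTILE_METHOD)),
            )
    return StabilitySummary(mode=mode, per_indicator=per_indicator, n_groups_used=n_used)


def stability_report(
    summary_filtered: StabilitySummary,
    summary_unfiltered: StabilitySummary,
) -> dict:
    """Per indicator and phase: ratio of unfiltered to filtered median SD."""
    report: dict = {"quantile_method": QUANTILE_METHOD, "indicators": {}}
    for ind in INDICATORS:
        for ph in PHASES:
            key = (ind, ph)
            if key not in summary_filtered.per_indicator or key not in summary_unfiltered.per_indicator:
                continue
            filt = summary_filtered.per_indicator[key]
            unfilt = summary_unfiltered.per_indicator[key]
            if filt.median_sd == 0.0:
                ratio = None
                infinite = unfilt.median_sd > 0.0
            else:
                ratio = unfilt.median_sd / filt.median_sd
                infinite = False
            report["indicators"][f"{ind}_{ph}"] = {
                "median_sd_unfiltered": unfilt.median_sd,
                "median_sd_filtered": filt.median_sd,
                "iqr_sd_unfiltered": unfilt.iqr_sd,
                "iqr_sd_filtered": filt.iqr_sd,
                "median_ratio": ratio,
                "ratio_infinite": infinite,
            }
    return report
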