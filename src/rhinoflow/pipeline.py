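"""End-to-end pipeline: segment -> validate -> resistance indicators."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import List, Optional

from .core import RawRecording, ThresholdSet, default_thresholds
from .cycle_validation import filter_effective
from .resistance import ResistanceConfig, compute_all
from .segmentation import (
    DEFAULT_BASELINE_WINDOW_S,
    DEFAULT_MIN_CYCLE_S,
    remove_dc,
    segment_cycles,
)

__all__ = ["PipelineConfig", "NoEffectiveCyclesError", "run_pipeline"]

logger = logging.getLogger(__name__)


class NoEffectiveCyclesError(RuntimeError):
    """Raised when validation leaves no cycle to compute resistances from."""

    def __init__(self, message: str, results):
        super().__init__(message)
        self.results = results


@dataclass
class PipelineConfig:
    sampling_rate_hz: float = 100.0
    thresholds: ThresholdSet = field(default_factory=default_thresholds)
    min_cycle_s: float = DEFAULT_MIN_CYCLE_S
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S
    remove_dc: bool = True
    max_cycles: Optional[int] = None
    p_ref_pa: float = 150.0
    broms_r_ref: float = 2.0
    broms_band: float = 0.25
    broms_unit_pa: float = 100.0
    broms_unit_cm3s: float = 100.0
    resample_n: int = 2000
    seed: int = 0

    def resistance_config(self) -> ResistanceConfig:
        return ResistanceConfig(
            p_ref_pa=self.p_ref_pa,
            broms_r_ref=self.broms_r_ref,
            broms_band=self.broms_band,
            broms_unit_pa=self.broms_unit_pa,
            broms_unit_cm3s=self.broms_unit_cm3s,
            resample_n=self.resample_n,
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.as_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = ThresholdSet(**data["thresholds"])
        return cls(**data)


def run_pipeline(config: PipelineConfig, rec: RawRecording) -> dict:
    """Run segmentation, validation, and resistance computation on a recording.

    Returns a JSON-serializable result bundle.  Raises
    :class:`NoEffectiveCyclesError` (carrying per-cycle failure reasons) when
    no cycle survives validation.
    """
    if config.remove_dc:
        rec = remove_dc(rec, config.baseline_window_s)
    cycles = segment_cycles(rec, min_cycle_s=config.min_cycle_s)
    logger.info("segmented %d candidate cycle(s)", len(cycles))

    effective, results = filter_effective(cycles, config.thresholds, config.max_cycles)
    rejections = [
        {"start_index": c.start_index, "n_samples": len(c), "failed_criteria": r.failed_criteria}
        for c, r in zip(cycles, results)
        if not r.is_effective
    ]
    logger.info(
        "validation accepted %d / %d cycle(s); rejection reasons: %s",
        len(effective), len(cycles),
        [r["failed_criteria"] for r in rejections] or "none",
    )
    if not effective:
        raise NoEffectiveCyclesError(
            f"no effective cycles among {len(cycles)} segmented", results
        )

    group = compute_all(effective, config.resistance_config())
    return {
        "config": config.as_dict(),
        "n_segmented": len(cycles),
        "n_effective": len(effective),
        "accepted_cycles": [
            {"start_index": c.start_index, "n_samples": len(c)} for c in effective
        ],
        "rejections": rejections,
        "per_cycle_resistance": [r.as_dict() for r in group.per_cycle],
        "group_resistance": group.group.as_dict(),
    }
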