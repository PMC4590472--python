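"""Pipeline configuration: every tunable constant in one place.

The defaults are the operational choices of a decade-scale coastal
monitoring analysis: significance at 0.05, the 0.05 kg m^-3 per 5 m
mixed-layer criterion, the 75 m stratification reference depth, an
April-July warming window, and log10 transforms for abundance, size and
biomass variables.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    max_harmonics: int = 4
    ar_max_lag: int = 1
    log10_variables: list[str] = field(
        default_factory=lambda: [
            "total_abundance", "lna_abundance", "hna_abundance",
            "total_size", "lna_size", "hna_size",
            "total_biomass", "lna_biomass", "hna_biomass",
            "nitrate", "chlorophyll",
        ]
    )
    mld_threshold_kg_m3: float = 0.05
    mld_span_m: float = 5.0
    si_reference_depth_m: float = 75.0
    window_months: list[int] = field(default_factory=lambda: [4, 5, 6, 7])
    calibration_log_slope: float = 0.5
    calibration_log_intercept: float = math.log10(0.047)
    red_fl_threshold: float = 20.0
    bottle_summary: str = "growth_phase"  # or "mean" / "final"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mld_threshold_kg_m3 <= 0 or self.mld_span_m <= 0:
            raise ValueError("MLD criterion parameters must be positive")
        if self.si_reference_depth_m <= 0:
            raise ValueError("stratification reference depth must be positive")
        if not set(self.window_months) <= set(range(1, 13)):
            raise ValueError("window months must be in 1..12")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
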