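"""Analysis configuration shared by every pipeline stage.

All thresholds flow from one :class:`AnalysisConfig` so a run is fully
described by (config, seed). Defaults follow standard 2-D videogrammetry
practice for gait: 120 Hz sampling, 4th-order zero-lag Butterworth at 6 Hz,
101-point phase grid with toe-off fixed at 60 % of the cycle, α = 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide parameters.

    Parameters
    ----------
    fs : float
        Sampling rate of the angle series, Hz.
    cutoff : float
        Low-pass cutoff for the zero-lag Butterworth filter, Hz.
    filter_order : int
        Effective filter order (the forward-reverse pass squares the
        magnitude response of an order ``filter_order`` design).
    grid_points : int
        Points on the 0-100 % phase grid, endpoints inclusive. 101 keeps
        toe-off at 60 % on an exact grid point.
    toe_off_pct : float
        Stance/swing boundary in % of the gait cycle.
    alpha : float
        Two-sided significance level for the statistical layer.
    max_lag_pct : float
        Half-width of the cross-correlation lag search window, % of cycle.
    min_cycles : int
        Minimum usable cycles for a subject's metrics to count as reliable.
    min_cycle_ms, max_cycle_ms : float
        Plausible cycle-duration band used when segmenting.
    seed : int
        Base seed for any stochastic step.
    """

    fs: float = 120.0
    cutoff: float = 6.0
    filter_order: int = 4
    grid_points: int = 101
    toe_off_pct: float = 60.0
    alpha: float = 0.05
    max_lag_pct: float = 25.0
    min_cycles: int = 3
    min_cycle_ms: float = 600.0
    max_cycle_ms: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.fs / 2:
            raise ConfigError(
                f"cutoff must lie in (0, fs/2): cutoff={self.cutoff}, fs={self.fs}"
            )
        if self.grid_points < 11:
            raise ConfigError(f"grid_points must be >= 11, got {self.grid_points}")
        if not 0 < self.toe_off_pct < 100:
            raise ConfigError(f"toe_off_pct must lie in (0, 100), got {self.toe_off_pct}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.filter_order < 2 or self.filter_order % 2:
            raise ConfigError(f"filter_order must be even and >= 2, got {self.filter_order}")
        if self.min_cycles < 1:
            raise ConfigError(f"min_cycles must be >= 1, got {self.min_cycles}")

    @property
    def phase_grid(self):
        import numpy as np

        return np.linspace(0.0, 100.0, self.grid_points)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)
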