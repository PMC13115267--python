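"""Gait corridors (mean ± SD, min-max envelopes) and phase-specific metrics.

A "corridor" is the pointwise ensemble of phase-normalized waveforms:
across a subject's cycles at subject level, across subject mean waveforms
at group level (dispersion across participants, not pooled cycles).

Phase metrics follow the per-cycle-then-average convention: ROM is the
max−min within the window computed per cycle and then averaged, because
ROM taken on the mean waveform is biased low whenever cycle timing
jitters. Within-subject variability is the across-cycle SD at each grid
point, averaged over the window's points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .gait_cycles import NormalizedCycle


@dataclass
class Corridor:
    """Pointwise mean/SD/min/max envelope on the phase grid."""

    phase: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n: int
    level: str  # "subject" | "group"


@dataclass
class PhaseMetrics:
    """Stance/swing ROM and variability for one subject and side (deg)."""

    subject_id: str
    side: str
    stance_rom: float
    swing_rom: float
    stance_var: float
    swing_var: float
    cycle_var: float  # whole-cycle within-subject SD
    mean_angle: float
    rom: float
    n_cycles: int
    reliable: bool = True


def _stack(cycles: list[NormalizedCycle]) -> np.ndarray:
    if not cycles:
        raise DataError("no cycles given")
    grid = cycles[0].phase
    for c in cycles[1:]:
        if c.phase.shape != grid.shape or not np.allclose(c.phase, grid):
            raise DataError("cycles are on mixed phase grids")
    return np.vstack([c.angle for c in cycles])


def subject_corridor(cycles: list[NormalizedCycle]) -> Corridor:
    """Pointwise mean/SD/min/max across one subject's cycles (SD uses n−1)."""
    arr = _stack(cycles)
    n = arr.shape[0]
    sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
    return Corridor(
        phase=cycles[0].phase.copy(),
        mean=arr.mean(axis=0),
        sd=sd,
        min=arr.min(axis=0),
        max=arr.max(axis=0),
        n=n,
        level="subject",
    )


def group_corridor(subject_means: list[NormalizedCycle]) -> Corridor:
    """Pointwise stats across subject mean waveforms (≥ 2 subjects)."""
    if len(subject_means) < 2:
        raise DataError("group corridor needs at least 2 subjects")
    corr = subject_corridor(subject_means)
    corr.level = "group"
    return corr


def mean_cycle(cycles: list[NormalizedCycle], subject_id: str = "", side: str = "") -> NormalizedCycle:
    """A subject's mean waveform as a NormalizedCycle (mean duration kept)."""
    arr = _stack(cycles)
    return NormalizedCycle(
        phase=cycles[0].phase.copy(),
        angle=arr.mean(axis=0),
        duration=float(np.mean([c.duration for c in cycles])),
        subject_id=subject_id or cycles[0].subject_id,
        side=side or cycles[0].side,
    )


def phase_metrics(
    cycles: list[NormalizedCycle],
    windows: tuple[np.ndarray, np.ndarray],
    min_cycles: int = 3,
) -> PhaseMetrics:
    """Stance/swing ROM and within-subject variability for one subject-side.

    With fewer than ``min_cycles`` cycles the metrics are still computed
    but flagged ``reliable=False``.
    """
    arr = _stack(cycles)
    stance, swing = windows
    n = arr.shape[0]

    def win_rom(idx: np.ndarray) -> float:
        sub = arr[:, idx]
        return float(np.mean(sub.max(axis=1) - sub.min(axis=1)))

    def win_var(idx: np.ndarray) -> float:
        if n < 2:
            return 0.0
        return float(np.mean(arr[:, idx].std(axis=0, ddof=1)))

    all_idx = np.arange(arr.shape[1])
    return PhaseMetrics(
        subject_id=cycles[0].subject_id,
        side=cycles[0].side,
        stance_rom=win_rom(stance),
        swing_rom=win_rom(swing),
        stance_var=win_var(stance),
        swing_var=win_var(swing),
        cycle_var=win_var(all_idx),
        mean_angle=float(arr.mean()),
        rom=win_rom(all_idx),
        n_cycles=n,
        reliable=n >= min_cycles,
    )
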