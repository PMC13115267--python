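"""Gait-cycle segmentation and 0-100 % phase normalization.

A cycle is delimited on the terminal-swing knee extension maximum, the
most robust initial-contact proxy available from a knee-angle-only
series. Because a knee waveform carries *two* near-extension plateaus
per cycle (midstance and terminal swing), the extension peak cannot be
found by height alone: detection first locates the swing-flexion
troughs — the single most prominent landmark of the cycle, gated by a
prominence threshold scaled to the series' own range and a refractory
distance of one minimum cycle duration — and then takes the extension
maximum in the window shortly after each trough (terminal swing re-
extension), which is the boundary.

Each segment is then linearly resampled onto the uniform phase grid
(0..100 %, endpoints inclusive); its real duration in ms is kept as
metadata so lags can be reported in both % of cycle and ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .errors import DataError, SegmentationError
from .kinematics import AngleSeries

#: fraction of the series range the swing-flexion trough must be prominent by
PROMINENCE_FRAC = 0.4
#: boundary search window after each trough, as a fraction of the local
#: trough-to-trough spacing (terminal re-extension peaks ~20-25 % after
#: peak swing flexion; the midstance plateau sits well beyond this window)
REEXTENSION_WINDOW_FRAC = 0.35


@dataclass
class CycleEvents:
    """Cycle-start boundaries in ms (extension-peak proxies)."""

    boundaries: np.ndarray  # ms, strictly increasing
    source: str = "detected"  # or "provided"
    too_few: bool = False

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise DataError("cycle boundaries must be strictly increasing")

    def __len__(self) -> int:
        return self.boundaries.size


@dataclass
class RawCycle:
    """One unnormalized cycle: samples in [start, next boundary)."""

    t: np.ndarray  # ms
    angle: np.ndarray  # deg
    duration: float  # ms, start to next boundary
    subject_id: str = ""
    side: str = ""
    cycle_index: int = 0


@dataclass
class NormalizedCycle:
    """One gait cycle on the 0-100 % phase grid."""

    phase: np.ndarray  # %, 0..100 inclusive
    angle: np.ndarray  # deg
    duration: float  # ms
    subject_id: str = ""
    side: str = ""
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.phase[0] != 0.0 or self.phase[-1] != 100.0:
            raise DataError("phase grid must span exactly 0..100")
        if np.isnan(self.angle).any():
            raise DataError("normalized cycle contains NaN")


def detect_events(
    series: AngleSeries,
    min_dur: float = 600.0,
    max_dur: float = 4000.0,
    min_cycles: int = 3,
) -> CycleEvents:
    """Detect cycle boundaries at the terminal-swing extension peaks.

    Swing-flexion troughs are located first (prominence ≥
    ``PROMINENCE_FRAC`` × series range, separation ≥ ``min_dur``); each
    boundary is then the angle maximum within the
    ``REEXTENSION_WINDOW_FRAC`` of a cycle following the trough, provided
    it exceeds the series mean. Sets ``too_few`` when fewer than
    ``min_cycles`` complete cycles result.

    Raises
    ------
    SegmentationError
        If fewer than 2 boundaries are found (e.g. a constant series).
    """
    x = series.angle
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise SegmentationError("series has fewer than 3 finite samples")
    rng_ = np.nanmax(x) - np.nanmin(x)
    if rng_ <= 0:
        raise SegmentationError("constant series: no extension peaks")
    dist = max(1, int(round(min_dur / 1000.0 * series.fs)))
    # NaN spans must never produce landmarks: poison them for the trough
    # search (+inf on the negated signal keeps them out of peaks)
    xw = np.where(finite, x, np.inf)
    troughs, _ = find_peaks(-xw, distance=dist, prominence=PROMINENCE_FRAC * rng_)
    if troughs.size < 2:
        raise SegmentationError(
            f"only {troughs.size} swing-flexion trough found; need >= 2"
        )
    spacing = np.diff(troughs)
    mean_level = np.nanmean(x)
    idx_list: list[int] = []
    for i, tr in enumerate(troughs):
        gap = spacing[i] if i < spacing.size else int(np.median(spacing))
        hi = min(tr + max(2, int(round(REEXTENSION_WINDOW_FRAC * gap))), x.size - 1)
        if hi <= tr + 1:
            continue
        window = x[tr + 1 : hi + 1]
        if np.isnan(window).all():
            continue
        j = tr + 1 + int(np.nanargmax(window))
        if x[j] >= mean_level:
            idx_list.append(j)
    idx = np.asarray(sorted(set(idx_list)), dtype=int)
    if idx.size < 2:
        raise SegmentationError(f"only {idx.size} cycle boundary found; need >= 2")
    boundaries = series.t[idx]
    durs = np.diff(boundaries)
    n_ok = int(np.sum((durs >= min_dur) & (durs <= max_dur)))
    return CycleEvents(boundaries, source="detected", too_few=n_ok < min_cycles)


def segment(
    series: AngleSeries,
    events: CycleEvents,
    min_dur: float = 600.0,
    max_dur: float = 4000.0,
) -> tuple[list[RawCycle], list[tuple[int, str]]]:
    """Cut the series into raw cycles at the event boundaries.

    Each segment holds the samples in [boundary_i, boundary_{i+1}) and the
    exact boundary-to-boundary duration. Segments containing NaN (an
    unfilled gap) or with implausible duration are dropped; the second
    return value lists (cycle_index, reason) for every drop, with reasons
    in {"gap", "too_short", "too_long"}.
    """
    b = events.boundaries
    if b.size and (b[0] < series.t[0] - 1e-9 or b[-1] > series.t[-1] + 1e-9):
        raise DataError("events fall outside the series time span")
    cycles: list[RawCycle] = []
    dropped: list[tuple[int, str]] = []
    for i in range(len(b) - 1):
        t0, t1 = b[i], b[i + 1]
        dur = t1 - t0
        if dur < min_dur:
            dropped.append((i, "too_short"))
            continue
        if dur > max_dur:
            dropped.append((i, "too_long"))
            continue
        sel = (series.t >= t0) & (series.t < t1)
        ang = series.angle[sel]
        if np.isnan(ang).any():
            dropped.append((i, "gap"))
            continue
        cycles.append(
            RawCycle(
                t=series.t[sel],
                angle=ang,
                duration=float(dur),
                subject_id=series.subject_id,
                side=series.side,
                cycle_index=i,
            )
        )
    return cycles, dropped


def time_normalize(cycle: RawCycle, grid_points: int = 101) -> NormalizedCycle:
    """Resample one raw cycle onto the uniform 0-100 % phase grid.

    Linear interpolation against the cycle's own duration; the 0 % value
    equals the first sample and the 100 % value equals the last sample
    (phase beyond the last sample clamps to it, since the closing boundary
    sample belongs to the next cycle).
    """
    if cycle.t.size < 4:
        raise DataError(
            f"cycle {cycle.cycle_index} has {cycle.t.size} samples; need >= 4"
        )
    phase_grid = np.linspace(0.0, 100.0, grid_points)
    sample_phase = (cycle.t - cycle.t[0]) / cycle.duration * 100.0
    angle = np.interp(phase_grid, sample_phase, cycle.angle)
    return NormalizedCycle(
        phase=phase_grid,
        angle=angle,
        duration=cycle.duration,
        subject_id=cycle.subject_id,
        side=cycle.side,
        cycle_index=cycle.cycle_index,
    )


def phase_windows(config: AnalysisConfig) -> tuple[np.ndarray, np.ndarray]:
    """Index sets partitioning the phase grid into stance and swing.

    Stance is phase ≤ toe_off_pct (boundary point included on the stance
    side), swing is the rest; together they cover every grid point once.
    """
    grid = config.phase_grid
    stance = np.flatnonzero(grid <= config.toe_off_pct)
    swing = np.flatnonzero(grid > config.toe_off_pct)
    return stance, swing


def normalize_series(
    series: AngleSeries,
    config: AnalysisConfig,
    events: CycleEvents | None = None,
) -> tuple[list[NormalizedCycle], list[tuple[int, str]], CycleEvents]:
    """Detect (unless provided), segment and normalize in one call."""
    if events is None:
        events = detect_events(
            series, config.min_cycle_ms, config.max_cycle_ms, config.min_cycles
        )
    raw, dropped = segment(series, events, config.min_cycle_ms, config.max_cycle_ms)
    out: list[NormalizedCycle] = []
    for c in raw:
        if c.t.size < 4:
            dropped.append((c.cycle_index, "too_short"))
            continue
        out.append(time_normalize(c, config.grid_points))
    return out, dropped, events
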