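"""Knee included-angle computation and zero-lag low-pass filtering.

The knee angle is the included angle at the knee between the thigh segment
(knee→hip, greater trochanter marker) and the shank segment (knee→ankle,
lateral malleolus marker): 180° means a fully extended (collinear) limb,
smaller values mean flexion. Flexion in the clinical sense is 180° minus
this value; every downstream metric (ROM, SD, correlations, lags) is
invariant under that flip, so the convention is fixed once here.

Filtering follows standard gait-lab practice: a 4th-order Butterworth
low-pass at 6 Hz applied forward and backward (zero phase), which squares
the single-pass magnitude response and leaves peak timing untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import signal

from .errors import DataError, GeometryError

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory_io import TrialTrajectory

_UNIFORM_TOL_MS = 1e-6


@dataclass
class AngleSeries:
    """Uniformly sampled knee included-angle series in degrees.

    ``angle`` may contain NaN for frames where a marker was lost;
    :func:`gap_fill` interpolates short interior runs and records the
    frame ranges it could not fill in ``unfilled_gaps``.
    """

    subject_id: str
    side: str
    t: np.ndarray  # ms
    angle: np.ndarray  # deg
    fs: float  # Hz
    filtered: bool = False
    unfilled_gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.t.shape != self.angle.shape:
            raise DataError("time and angle arrays differ in length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1000.0 / self.fs) > _UNIFORM_TOL_MS):
                raise DataError(
                    f"angle series not uniformly sampled at fs={self.fs} Hz"
                )

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag Butterworth low-pass specification (forward-reverse)."""

    order: int = 4
    cutoff: float = 6.0
    fs: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < self.fs / 2:
            raise DataError(f"cutoff {self.cutoff} Hz outside (0, fs/2)")
        if self.order < 2 or self.order % 2:
            raise DataError(f"order must be even and >= 2, got {self.order}")


def knee_angle(hip, knee, ankle) -> float | np.ndarray:
    """Included angle at the knee between knee→hip and knee→ankle, degrees.

    Accepts single points of shape (2,) or stacked frames of shape (n, 2);
    vectorized over frames. 180° = collinear (full extension). Invariant to
    rotation, translation and uniform scaling of all three points.

    Raises
    ------
    GeometryError
        If either segment has zero length (reports the first frame index).
    """
    hip = np.asarray(hip, dtype=float)
    knee = np.asarray(knee, dtype=float)
    ankle = np.asarray(ankle, dtype=float)
    thigh = hip - knee
    shank = ankle - knee
    nt = np.linalg.norm(thigh, axis=-1)
    ns = np.linalg.norm(shank, axis=-1)
    bad = (nt == 0) | (ns == 0)
    if np.any(bad):
        idx = int(np.argmax(np.atleast_1d(bad)))
        raise GeometryError(f"zero-length thigh or shank segment at frame {idx}")
    cosang = np.sum(thigh * shank, axis=-1) / (nt * ns)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


def trajectory_knee_angles(traj: "TrialTrajectory", fs: float) -> AngleSeries:
    """Knee angle per frame from a trial's hip (J4), knee (J5), ankle (J6) markers.

    Frames where any of the three markers is missing become NaN; no
    imputation happens here (that is :func:`gap_fill`'s job).
    """
    side = traj.side
    try:
        hip = traj.pos[(side, "J4")]
        knee = traj.pos[(side, "J5")]
        ankle = traj.pos[(side, "J6")]
    except KeyError as exc:
        raise DataError(f"trajectory lacks marker {exc} for side {side!r}") from exc
    missing = (
        traj.missing_mask[(side, "J4")]
        | traj.missing_mask[(side, "J5")]
        | traj.missing_mask[(side, "J6")]
    )
    angle = np.full(len(traj.t), np.nan)
    ok = ~missing
    if ok.any():
        angle[ok] = knee_angle(hip[ok], knee[ok], ankle[ok])
    return AngleSeries(traj.subject_id, side, np.asarray(traj.t, float), angle, fs=fs)


def gap_fill(series: AngleSeries, max_gap_frames: int = 12) -> AngleSeries:
    """Linearly interpolate interior NaN runs no longer than ``max_gap_frames``.

    Longer interior runs, and leading/trailing NaNs, are left as NaN and
    recorded in ``unfilled_gaps`` as (start_index, length) so segmentation
    can drop the cycles they touch. The default 12 frames is 100 ms at
    120 Hz — roughly the longest marker dropout a linear bridge can cross
    without inventing kinematics.
    """
    angle = series.angle.copy()
    isnan = np.isnan(angle)
    if not isnan.any():
        return replace(series, angle=angle, unfilled_gaps=[])

    unfilled: list[tuple[int, int]] = []
    n = angle.size
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        run = j - i
        interior = i > 0 and j < n
        if interior and run <= max_gap_frames:
            # linear bridge between the flanking valid samples
            x0, x1 = angle[i - 1], angle[j]
            angle[i:j] = x0 + (x1 - x0) * np.arange(1, run + 1) / (run + 1)
        else:
            unfilled.append((i, run))
        i = j
    return replace(series, angle=angle, unfilled_gaps=unfilled)


def butterworth_zero_lag(series: AngleSeries, spec: FilterSpec | None = None) -> AngleSeries:
    """Forward-reverse (zero-phase) Butterworth low-pass of an angle series.

    Edge transients are suppressed with reflective padding of length
    3 × (order + 1) samples. DC gain is exactly 1, so a constant series is
    returned unchanged up to round-off.

    Raises
    ------
    DataError
        If the series still contains NaN (run :func:`gap_fill` first) or is
        too short for the padding.
    """
    if spec is None:
        spec = FilterSpec(fs=series.fs)
    x = series.angle
    if np.isnan(x).any():
        raise DataError("series contains NaN; gap_fill before filtering")
    padlen = 3 * (spec.order + 1)
    if x.size <= padlen:
        raise DataError(
            f"series of {x.size} samples too short for padlen {padlen}"
        )
    b, a = signal.butter(spec.order, spec.cutoff / (spec.fs / 2.0), btype="low")
    y = signal.filtfilt(b, a, x, padtype="even", padlen=padlen)
    return replace(series, angle=y, filtered=True)


def filter_response(spec: FilterSpec, freqs_hz: Sequence[float]) -> np.ndarray:
    """Two-pass (zero-lag) magnitude response at the given frequencies.

    Utility for verifying attenuation; equals |H(f)|² of the single-pass
    digital design.
    """
    b, a = signal.butter(spec.order, spec.cutoff / (spec.fs / 2.0), btype="low")
    w = 2 * np.pi * np.asarray(freqs_hz, float) / spec.fs
    _, h = signal.freqz(b, a, worN=w)
    return np.abs(h) ** 2
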