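"""Interlimb coordination: Pearson r, cross-correlation, lag and similarity.

Conventions (stated once, used everywhere):

* ``cross_correlation`` computes the raw discrete sums
  R_xy[k] = Σ_n x[n] · y[n+k], with zero padding outside the signals
  (linear, not circular).
* Positive lag k means y is *delayed* relative to x by k samples.
* ``similarity`` mean-centers both inputs globally and normalizes each
  lag's sum by the energies of the *overlapping* samples at that lag,
  √(Σ_overlap x̃² · Σ_overlap ỹ²). The lag-0 value then coincides exactly
  with Pearson r, |R| ≤ 1 holds at every lag by Cauchy-Schwarz, and a
  pure shift of a periodic waveform is recovered exactly (a full-energy
  denominator would instead bias the peak toward lag 0 for smooth
  signals, because shrinking overlap loses edge terms faster than a
  one-sample misalignment costs). Ties at the peak resolve to the
  smallest |k|, then to the negative k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import DataError, UndefinedStatisticError
from .gait_cycles import NormalizedCycle


@dataclass
class CoordinationResult:
    """Per-subject left/right coordination summary."""

    subject_id: str
    r: float  # Pearson r at lag 0
    R_peak: float  # normalized cross-correlation peak
    lag_pct: float  # % of cycle; positive = right delayed vs left
    lag_ms: float  # lag_pct × mean cycle duration / 100


def _as_float(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise DataError("waveform contains NaN")
    return a


def pearson_r(x, y) -> float:
    """Pearson correlation coefficient between two equal-length waveforms.

    Raises
    ------
    UndefinedStatisticError
        If either input has zero variance (r is undefined, never 0).
    """
    x, y = _as_float(x), _as_float(y)
    if x.size != y.size:
        raise DataError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise DataError("need at least 3 samples")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.dot(xc, xc), np.dot(yc, yc)
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("zero-variance input: correlation undefined")
    return float(np.dot(xc, yc) / np.sqrt(sx * sy))


def cross_correlation(x, y, max_lag: int) -> np.ndarray:
    """Raw cross-correlation sums R_xy[k] for k = −max_lag..max_lag.

    Zero padding outside [0, N): R_xy[k] = Σ_{n} x[n] y[n+k] over the
    overlapping indices. Returned as an array of length 2·max_lag+1 with
    k = index − max_lag; R_xy[0] (center) is the plain dot product.
    """
    x, y = _as_float(x), _as_float(y)
    n = x.size
    if y.size != n:
        raise DataError(f"length mismatch: {n} vs {y.size}")
    if n < 2:
        raise DataError("need at least 2 samples")
    if not 0 <= max_lag < n:
        raise DataError(f"max_lag must satisfy 0 <= max_lag < N={n}, got {max_lag}")
    out = np.empty(2 * max_lag + 1)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            out[i] = np.dot(x[: n - k], y[k:])
        else:
            out[i] = np.dot(x[-k:], y[: n + k])
    return out


def similarity(x, y, max_lag: int) -> tuple[float, int]:
    """Normalized cross-correlation peak and its lag in samples.

    Both inputs are mean-centered; each lag's sum is normalized by the
    overlap energies so the value at lag 0 equals Pearson r and |R| ≤ 1
    everywhere. Returns (R_peak, lag) with the tie-break smallest |k|
    then negative k.
    """
    x, y = _as_float(x), _as_float(y)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.dot(xc, xc), np.dot(yc, yc)
    if sx == 0 or sy == 0:
        raise UndefinedStatisticError("zero-variance input: similarity undefined")
    raw = cross_correlation(xc, yc, max_lag)
    # per-lag overlap energies via cumulative sums of squares
    cx = np.concatenate([[0.0], np.cumsum(xc * xc)])
    cy = np.concatenate([[0.0], np.cumsum(yc * yc)])
    lags = np.arange(-max_lag, max_lag + 1)
    pos = np.clip(lags, 0, n)
    neg = np.clip(-lags, 0, n)
    ex = np.where(lags >= 0, cx[n - pos], cx[n] - cx[neg])
    ey = np.where(lags >= 0, cy[n] - cy[pos], cy[n - neg])
    denom = np.sqrt(ex * ey)
    r = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
    best = np.flatnonzero(r == r.max())
    # ties: smallest |k|, then the negative one
    order = sorted(best, key=lambda i: (abs(lags[i]), lags[i]))
    k = int(lags[order[0]])
    return float(r.max()), k


def interlimb_coordination(
    left: NormalizedCycle,
    right: NormalizedCycle,
    config: AnalysisConfig,
) -> CoordinationResult:
    """Left/right coordination for one subject from the mean cycles.

    Positive lag = right limb delayed relative to left. Lag is reported
    both in % of cycle (grid samples over a 101-point grid are 1 % each)
    and in ms via the mean of the two cycle durations.
    """
    if left.phase.shape != right.phase.shape or not np.allclose(left.phase, right.phase):
        raise DataError("left and right cycles are on different grids")
    n = left.angle.size
    grid_step_pct = 100.0 / (n - 1)
    max_lag = int(round(config.max_lag_pct / grid_step_pct))
    max_lag = min(max_lag, n - 1)
    r = pearson_r(left.angle, right.angle)
    R_peak, k = similarity(left.angle, right.angle, max_lag)
    lag_pct = k * grid_step_pct
    mean_dur = 0.5 * (left.duration + right.duration)
    return CoordinationResult(
        subject_id=left.subject_id,
        r=r,
        R_peak=R_peak,
        lag_pct=lag_pct,
        lag_ms=lag_pct * mean_dur / 100.0,
    )


def group_reference_correlation(
    subject_waveforms: list[NormalizedCycle],
) -> list[float]:
    """Pearson r of each subject's waveform against the group reference.

    The reference for subject i is the mean of all *other* subjects'
    waveforms (leave-one-out), avoiding the self-correlation inflation a
    full-mean reference carries at small n. Requires ≥ 3 subjects.
    """
    if len(subject_waveforms) < 3:
        raise DataError("need at least 3 subjects for a reference correlation")
    arr = np.vstack([c.angle for c in subject_waveforms])
    n = arr.shape[0]
    total = arr.sum(axis=0)
    out = []
    for i in range(n):
        ref = (total - arr[i]) / (n - 1)
        out.append(pearson_r(arr[i], ref))
    return out
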