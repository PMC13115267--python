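"""End-to-end orchestration: read → gap-fill → filter → segment → normalize
→ corridors/metrics/coordination → group statistics.

Both limbs of a subject are segmented on the *left* limb's detected
events so that any right-limb temporal lag survives into the normalized
cycles (segmenting each limb on its own extension peaks would align the
peaks and erase the lag by construction). Every cycle read is accounted
for in the RunRecord: trials_read = cycles_used + cycles_dropped, with a
reason per drop.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .coordination import CoordinationResult, interlimb_coordination
from .corridor_metrics import (
    Corridor,
    group_corridor,
    mean_cycle,
    phase_metrics,
    subject_corridor,
)
from .errors import GaitError, SegmentationError
from .gait_cycles import NormalizedCycle, normalize_series, phase_windows
from .kinematics import AngleSeries, FilterSpec, butterworth_zero_lag, gap_fill, trajectory_knee_angles
from .trajectory_io import CohortManifest, read_trial_csv


@dataclass
class RunRecord:
    """Reproducibility record for one pipeline run."""

    config: dict
    seed: int | None = None
    version: str = __version__
    trials_read: int = 0
    cycles_detected: int = 0
    cycles_used: int = 0
    cycles_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)
    excluded_subjects: list[str] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)

    def log_drops(self, dropped: list[tuple[int, str]]) -> None:
        self.cycles_dropped += len(dropped)
        for _, reason in dropped:
            self.drop_reasons[reason] = self.drop_reasons.get(reason, 0) + 1

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    cycles: dict[str, list[NormalizedCycle]]  # side -> cycles
    corridors: dict[str, Corridor]
    mean_cycles: dict[str, NormalizedCycle]
    metrics: dict[str, object]  # side -> PhaseMetrics
    coordination: CoordinationResult | None


def _prepare_series(series: AngleSeries, config: AnalysisConfig) -> AngleSeries:
    filled = gap_fill(series)
    spec = FilterSpec(order=config.filter_order, cutoff=config.cutoff, fs=config.fs)
    if filled.unfilled_gaps:
        # filter the valid spans only; unfilled gaps stay NaN and drop cycles
        out = filled.angle.copy()
        isn = np.isnan(out)
        starts = np.flatnonzero(np.diff(np.concatenate([[1], isn.view(np.int8)])) == -1)
        ends = np.flatnonzero(np.diff(np.concatenate([isn.view(np.int8), [1]])) == 1) + 1
        padlen = 3 * (spec.order + 1)
        for s, e in zip(starts, ends):
            if e - s > padlen:
                seg = dataclasses.replace(filled, t=filled.t[s:e], angle=out[s:e],
                                          unfilled_gaps=[])
                out[s:e] = butterworth_zero_lag(seg, spec).angle
        return dataclasses.replace(filled, angle=out, filtered=True)
    return butterworth_zero_lag(filled, spec)


def analyze_subject(
    left: AngleSeries,
    right: AngleSeries | None,
    config: AnalysisConfig,
    group: str = "",
    record: RunRecord | None = None,
) -> SubjectResult:
    """Run the per-subject pipeline on one (or both) limbs.

    Events are detected on the left limb (or the only limb given) and
    applied to both sides.
    """
    windows = phase_windows(config)
    sides: dict[str, AngleSeries] = {}
    sides["left" if right is not None else left.side] = left
    if right is not None:
        sides["right"] = right

    prepared = {s: _prepare_series(x, config) for s, x in sides.items()}
    anchor = prepared.get("left") or next(iter(prepared.values()))
    cycles: dict[str, list[NormalizedCycle]] = {}
    events = None
    for s, series in prepared.items():
        cyc, dropped, ev = normalize_series(series, config, events=events)
        if events is None:
            events = ev
        if record is not None:
            record.cycles_detected += len(ev) - 1
            record.cycles_used += len(cyc)
            record.log_drops(dropped)
        cycles[s] = cyc

    corridors = {s: subject_corridor(c) for s, c in cycles.items() if c}
    means = {s: mean_cycle(c) for s, c in cycles.items() if c}
    mets = {
        s: phase_metrics(c, windows, config.min_cycles) for s, c in cycles.items() if c
    }
    coord = None
    if "left" in means and "right" in means:
        coord = interlimb_coordination(means["left"], means["right"], config)
    return SubjectResult(
        subject_id=left.subject_id, group=group, cycles=cycles,
        corridors=corridors, mean_cycles=means, metrics=mets, coordination=coord,
    )


@dataclass
class CohortResult:
    metrics: pd.DataFrame  # one row per subject × side
    coordination: pd.DataFrame  # one row per subject with both sides
    group_corridors: dict[tuple[str, str], Corridor]  # (group, side) -> corridor
    subject_results: list[SubjectResult]
    record: RunRecord


def analyze_cohort(manifest: CohortManifest, config: AnalysisConfig) -> CohortResult:
    """Analyze every subject in a manifest and assemble cohort tables."""
    record = RunRecord(config=dataclasses.asdict(config))
    by_subject: dict[tuple[str, str], dict[str, AngleSeries]] = {}
    for e in manifest.entries:
        obj = read_trial_csv(e.path, dialect=e.dialect, subject_id=e.subject_id,
                             side=e.side, fs=config.fs)
        record.trials_read += 1
        if not isinstance(obj, AngleSeries):
            obj = trajectory_knee_angles(obj, fs=config.fs)
        by_subject.setdefault((e.group, e.subject_id), {})[e.side] = obj

    results: list[SubjectResult] = []
    met_rows, coord_rows = [], []
    means_by_group_side: dict[tuple[str, str], list[NormalizedCycle]] = {}
    for (group, sid), sides in sorted(by_subject.items()):
        left = sides.get("left")
        right = sides.get("right")
        primary = left if left is not None else right
        try:
            res = analyze_subject(primary, right if left is not None else None,
                                  config, group=group, record=record)
        except (SegmentationError, GaitError) as exc:
            record.excluded_subjects.append(f"{sid}: {exc}")
            continue
        if not res.metrics:
            record.excluded_subjects.append(f"{sid}: no usable cycles")
            continue
        results.append(res)
        for side, pm in res.metrics.items():
            met_rows.append({"subject_id": sid, "group": group, "side": side,
                             **dataclasses.asdict(pm)})
        for side, mc in res.mean_cycles.items():
            means_by_group_side.setdefault((group, side), []).append(mc)
        if res.coordination is not None:
            c = res.coordination
            coord_rows.append({"subject_id": sid, "group": group, "r": c.r,
                               "R_peak": c.R_peak, "lag_pct": c.lag_pct,
                               "lag_ms": c.lag_ms})

    corridors = {
        key: group_corridor(means)
        for key, means in means_by_group_side.items()
        if len(means) >= 2
    }
    return CohortResult(
        metrics=pd.DataFrame(met_rows),
        coordination=pd.DataFrame(coord_rows),
        group_corridors=corridors,
        subject_results=results,
        record=record,
    )


def write_cohort_outputs(result: CohortResult, out_dir: str | Path) -> list[Path]:
    """Write metrics/coordination/corridor TSVs plus the run record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out_dir / "metrics.tsv"
    result.metrics.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = out_dir / "coordination.tsv"
    # positive lag = right limb delayed relative to left (samples convention)
    result.coordination.to_csv(p, sep="\t", index=False)
    paths.append(p)
    for (group, side), corr in sorted(result.group_corridors.items()):
        p = out_dir / f"corridor_{group}_{side}.tsv"
        pd.DataFrame({
            "phase_pct": corr.phase, "mean_deg": corr.mean, "sd_deg": corr.sd,
            "min_deg": corr.min, "max_deg": corr.max,
        }).to_csv(p, sep="\t", index=False)
        paths.append(p)
    result.record.output_paths = [str(x) for x in paths]
    rec = out_dir / "run_record.json"
    result.record.write(rec)
    paths.append(rec)
    return paths
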