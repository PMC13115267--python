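"""Synthetic gait-cohort generator.

The knee included-angle waveform over one cycle is modelled as a baseline
near full extension minus two periodic Gaussian flexion bumps: a small
stance-phase flexion wave (weight acceptance, ~15 % of the cycle) and a
large swing-phase flexion wave (limb clearance, ~72 %). The defaults put
the healthy whole-cycle ROM near 60°, the scale clinical 2-D
videogrammetry reports for the knee.

Cohort structure (all pure functions of the seeds):

* between-subject: a baseline offset (deg), a ROM multiplier jitter and a
  mean cycle duration drawn per subject;
* within-subject: per-cycle duration jitter and band-limited additive
  noise (white noise low-passed at 8 Hz, scaled to the requested SD) —
  smooth enough to survive the pipeline's 6 Hz filter, so the filter is
  exercised but not load-bearing;
* interlimb: the right limb replays the left limb's motor program with a
  phase delay (lag % of cycle, drawn per subject) plus per-cycle phase
  jitter ("decoupling");
* optional freezing episodes: a window of the cycle where the angle is
  held near-constant (amplitude collapse), the minimal model needed to
  stress variability metrics.

Group presets emulate the study conditions: PD-OFF attenuates ROM
(×0.65), inflates cycle noise (3°) and interlimb lag (8 %); PD-ON
partially restores all three (×0.85, 2°, 4 %).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal

from .errors import ConfigError
from .kinematics import AngleSeries
from .trajectory_io import (
    CohortManifest,
    ManifestEntry,
    TrialTrajectory,
    write_angle_csv,
    write_manifest,
    write_trial_csv,
)

_NOISE_CUTOFF_HZ = 8.0


@dataclass(frozen=True)
class GaitTemplate:
    """Two-bump knee included-angle template (deg, % of cycle)."""

    baseline: float = 177.0
    stance_amp: float = 18.0
    stance_center: float = 15.0
    stance_width: float = 6.0
    swing_amp: float = 60.0
    swing_center: float = 72.0
    swing_width: float = 9.0

    def __post_init__(self) -> None:
        if self.baseline - self.swing_amp <= 0:
            raise ConfigError("swing amplitude exceeds baseline: angle would go <= 0")
        if not 0 < self.stance_center < self.swing_center < 100:
            raise ConfigError("bump centers must satisfy 0 < stance < swing < 100")


@dataclass(frozen=True)
class CohortSpec:
    """One group's generation parameters.

    ``rom_scale`` multiplies both flexion bumps; ``between_subject_sd`` is
    the SD (deg) of a per-subject baseline offset; ``rom_scale_cv`` the
    coefficient of variation of the per-subject ROM multiplier;
    ``decoupling_pct`` the SD of per-cycle right-limb phase jitter.
    """

    group: str = "healthy"
    n_subjects: int = 27
    cycles_per_subject: int = 10
    fs: float = 120.0
    mean_cycle_ms: float = 1501.0
    duration_between_sd_ms: float = 100.0
    duration_within_sd_ms: float = 40.0
    rom_scale: float = 1.0
    rom_scale_cv: float = 0.05
    cycle_noise_sd: float = 1.0
    between_subject_sd: float = 5.0
    interlimb_lag_pct: float = 0.0
    interlimb_lag_sd_pct: float = 1.0
    decoupling_pct: float = 0.5
    freeze_prob: float = 0.0
    freeze_duration_ms: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.cycles_per_subject < 1:
            raise ConfigError("n_subjects must be >= 0 and cycles_per_subject >= 1")
        if not 0 < self.rom_scale <= 1.5:
            raise ConfigError(f"rom_scale must lie in (0, 1.5], got {self.rom_scale}")
        for name in ("duration_between_sd_ms", "duration_within_sd_ms", "cycle_noise_sd",
                     "between_subject_sd", "interlimb_lag_sd_pct", "decoupling_pct",
                     "rom_scale_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.freeze_prob <= 1:
            raise ConfigError("freeze_prob must lie in [0, 1]")


#: group presets on the study's scale: PD-OFF attenuated/noisy/lagged,
#: PD-ON partially restored.
GROUP_PRESETS: dict[str, dict] = {
    "healthy": dict(group="healthy", n_subjects=27, rom_scale=1.0,
                    cycle_noise_sd=1.0, interlimb_lag_pct=0.0,
                    interlimb_lag_sd_pct=1.0, decoupling_pct=0.5),
    "pd_off": dict(group="pd_off", n_subjects=8, rom_scale=0.65,
                   cycle_noise_sd=3.0, interlimb_lag_pct=8.0,
                   interlimb_lag_sd_pct=3.0, decoupling_pct=4.0),
    "pd_on": dict(group="pd_on", n_subjects=8, rom_scale=0.85,
                  cycle_noise_sd=2.0, interlimb_lag_pct=4.0,
                  interlimb_lag_sd_pct=2.0, decoupling_pct=2.0),
}


def default_specs(seed: int = 0, **overrides) -> list[CohortSpec]:
    """The three default group specs with per-group derived seeds."""
    specs = []
    for i, name in enumerate(("healthy", "pd_off", "pd_on")):
        kw = dict(GROUP_PRESETS[name])
        kw.update(overrides.get(name, {}) if isinstance(overrides.get(name), dict) else {})
        specs.append(CohortSpec(seed=seed * 1000 + i, **kw))
    return specs


def _periodic_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    d = (phase - center + 50.0) % 100.0 - 50.0
    return np.exp(-0.5 * (d / width) ** 2)


def template_waveform(
    template: GaitTemplate, phase: np.ndarray, rom_scale: float = 1.0
) -> np.ndarray:
    """Evaluate the template at the given phases (% of cycle, any real values)."""
    phase = np.asarray(phase, dtype=float)
    return (
        template.baseline
        - rom_scale * template.stance_amp
        * _periodic_bump(phase, template.stance_center, template.stance_width)
        - rom_scale * template.swing_amp
        * _periodic_bump(phase, template.swing_center, template.swing_width)
    )


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited (≤ ~8 Hz) Gaussian noise rescaled to the target SD."""
    if sd == 0 or n < 32:
        return np.zeros(n)
    w = rng.standard_normal(n)
    b, a = signal.butter(2, _NOISE_CUTOFF_HZ / (fs / 2.0), btype="low")
    s = signal.filtfilt(b, a, w)
    s_sd = s.std()
    return s * (sd / s_sd) if s_sd > 0 else np.zeros(n)


def generate_subject(
    spec: CohortSpec,
    template: GaitTemplate | None = None,
    subject_seed: int = 0,
) -> tuple[AngleSeries, AngleSeries]:
    """Generate one subject's continuous left and right angle series.

    Both limbs share the same cycle clock (boundaries in time); the right
    limb replays the left program delayed by the subject's interlimb lag
    plus per-cycle decoupling jitter. Reproducible from
    (spec.seed, subject_seed).
    """
    template = template or GaitTemplate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))

    rom = spec.rom_scale * max(0.1, 1.0 + rng.normal(0.0, spec.rom_scale_cv))
    offset = rng.normal(0.0, spec.between_subject_sd)
    subj_dur = max(600.0, rng.normal(spec.mean_cycle_ms, spec.duration_between_sd_ms))
    lag = rng.normal(spec.interlimb_lag_pct, spec.interlimb_lag_sd_pct)

    # one extra cycle so cycles_per_subject complete boundary-to-boundary
    # spans survive segmentation (the boundary proxy sits near each
    # cycle's end, so the first span starts inside cycle 0)
    n_cyc = spec.cycles_per_subject + 1
    durs = np.clip(
        rng.normal(subj_dur, spec.duration_within_sd_ms, size=n_cyc),
        0.5 * subj_dur, 1.5 * subj_dur,
    )
    edges = np.concatenate([[0.0], np.cumsum(durs)])
    total = edges[-1]
    dt = 1000.0 / spec.fs
    t = np.arange(0.0, total, dt)
    cyc_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_cyc - 1)
    local = (t - edges[cyc_idx]) / durs[cyc_idx] * 100.0

    jitter = rng.normal(0.0, spec.decoupling_pct, size=n_cyc)
    left = template_waveform(template, local, rom) + offset
    right = template_waveform(template, local - lag - jitter[cyc_idx], rom) + offset

    left = left + _smooth_noise(rng, t.size, spec.fs, spec.cycle_noise_sd)
    right = right + _smooth_noise(rng, t.size, spec.fs, spec.cycle_noise_sd)
    # included angle is anatomically bounded: no hyperextension past 180°
    np.clip(left, 1.0, 180.0, out=left)
    np.clip(right, 1.0, 180.0, out=right)

    if spec.freeze_prob > 0:
        for c in range(n_cyc):
            if rng.random() >= spec.freeze_prob:
                continue
            start = edges[c] + rng.uniform(0.0, max(durs[c] - spec.freeze_duration_ms, 0.0))
            sel = (t >= start) & (t < start + spec.freeze_duration_ms)
            if sel.any():
                i0 = int(np.argmax(sel))
                left[sel] = left[i0]
                right[sel] = right[i0]

    sid = f"{spec.group}_{subject_seed:03d}"
    return (
        AngleSeries(sid, "left", t, left, fs=spec.fs),
        AngleSeries(sid, "right", t, right, fs=spec.fs),
    )


def angle_to_markers(series: AngleSeries, thigh_len: float = 40.0,
                     shank_len: float = 42.0, speed_cm_s: float = 120.0) -> TrialTrajectory:
    """Inverse kinematics: place hip/knee/ankle markers realizing the angle.

    The thigh hangs vertically from a hip that advances at walking speed;
    the shank direction makes the included angle with the thigh at the
    knee. knee_angle() on the output recovers the series to float
    precision (angles are rigid-motion invariant, so the forward drift is
    immaterial).
    """
    th = np.deg2rad(series.angle)
    x0 = series.t / 1000.0 * speed_cm_s  # forward drift, cm
    hip = np.column_stack([x0, np.full_like(x0, 100.0)])
    knee = hip + np.array([0.0, -thigh_len])
    # knee→hip direction is (0, 1); rotate it by the included angle
    shank_dir = np.column_stack([np.sin(th), np.cos(th)])
    ankle = knee + shank_len * shank_dir
    side = series.side
    pos = {(side, "J4"): hip, (side, "J5"): knee, (side, "J6"): ankle}
    nan = np.isnan(series.angle)
    for key in pos:
        pos[key] = pos[key].copy()
        pos[key][nan] = np.nan
    return TrialTrajectory(series.subject_id, side, series.t, pos)


@dataclass
class GeneratedCohort:
    manifest: CohortManifest
    manifest_path: Path
    files: list[Path] = field(default_factory=list)


def generate_cohort(
    specs: list[CohortSpec],
    out_dir: str | Path,
    template: GaitTemplate | None = None,
    file_format: str = "angle",
) -> GeneratedCohort:
    """Generate all groups to disk: trial CSVs plus a manifest.yaml.

    ``file_format`` is "angle" (t_ms,angle_deg per side) or "markers"
    (kinovea-dialect J4/J5/J6 columns via inverse kinematics). Same specs
    and seeds produce byte-identical files.
    """
    groups = [s.group for s in specs]
    if len(set(groups)) != len(groups):
        raise ConfigError("duplicate group labels in cohort specs")
    if file_format not in ("angle", "markers"):
        raise ConfigError(f"unknown file_format {file_format!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    files: list[Path] = []
    for spec in specs:
        for i in range(spec.n_subjects):
            left, right = generate_subject(spec, template, subject_seed=i)
            for series in (left, right):
                stem = f"{series.subject_id}_{series.side}"
                if file_format == "angle":
                    p = out_dir / f"{stem}.csv"
                    write_angle_csv(series, p)
                    dialect = "angle"
                else:
                    p = out_dir / f"{stem}_markers.csv"
                    write_trial_csv(angle_to_markers(series), p)
                    dialect = "kinovea"
                files.append(p)
                entries.append(ManifestEntry(
                    series.subject_id, spec.group, series.side, p, dialect
                ))
    manifest = CohortManifest(entries)
    mpath = write_manifest(manifest, out_dir / "manifest.yaml")
    return GeneratedCohort(manifest, mpath, files)


def load_cohort_specs(path: str | Path) -> list[CohortSpec]:
    """Read cohort specs from YAML (list of mappings, or {groups: [...]})."""
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict):
        raw = raw.get("groups", raw)
    if not isinstance(raw, list):
        raise ConfigError("cohort spec YAML must hold a list of group mappings")
    known = {f.name for f in dataclasses.fields(CohortSpec)}
    specs = []
    for item in raw:
        unknown = set(item) - known
        if unknown:
            raise ConfigError(f"unknown cohort spec fields: {sorted(unknown)}")
        specs.append(CohortSpec(**item))
    return specs
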