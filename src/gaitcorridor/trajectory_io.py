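"""Reading and writing marker-trajectory CSVs, angle CSVs and cohort manifests.

The canonical trial dialect ("kinovea") is one header row with a ``t_ms``
time column followed by paired marker columns ``<side>_<joint>x`` /
``<side>_<joint>y`` (side prefix optional for single-side exports), e.g.::

    t_ms,left_J4x,left_J4y,left_J5x,left_J5y,left_J6x,left_J6y

Joints are the six body landmarks J1 shoulder, J2 elbow, J3 wrist,
J4 hip (greater trochanter), J5 knee (lateral femoral condyle),
J6 ankle (lateral malleolus). Units are whatever the tracking produced
(px or cm): the pipeline only ever computes angles, which are
scale-invariant. Blank cells mean "marker lost this frame" and are kept
missing — imputation is exclusively the kinematics module's gap_fill.

A "long" dialect (t_ms, side, joint, x, y — one marker per row) and an
"angle" dialect (t_ms, angle_deg) are also accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError, ResolutionError
from .kinematics import AngleSeries

JOINTS = ("J1", "J2", "J3", "J4", "J5", "J6")
SIDES = ("left", "right")
GROUPS = ("healthy", "pd_off", "pd_on")

_COL_RE = re.compile(r"^(?:(left|right)_)?(J[1-6])(x|y)$")


@dataclass
class TrialTrajectory:
    """Time-stamped 2-D marker positions for one walking trial of one side.

    ``pos`` maps (side, joint) to an (n, 2) array; ``missing_mask`` flags
    frames where that marker was blank in the file.
    """

    subject_id: str
    side: str
    t: np.ndarray  # ms, strictly increasing
    pos: dict[tuple[str, str], np.ndarray]
    missing_mask: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.size < 2:
            raise DataError("a trial needs at least 2 frames")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise DataError(f"time not strictly increasing at frame {idx + 1}")
        if not self.pos:
            raise DataError("trajectory holds no markers")
        for key, xy in self.pos.items():
            if key not in self.missing_mask:
                self.missing_mask[key] = np.isnan(np.asarray(xy, float)).any(axis=1)

    @property
    def markers(self) -> list[tuple[str, str]]:
        return sorted(self.pos)


@dataclass
class ManifestEntry:
    subject_id: str
    group: str
    side: str
    path: Path
    dialect: str = "angle"


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]

    @property
    def groups(self) -> list[str]:
        return sorted({e.group for e in self.entries})

    def by_group(self, group: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.group == group]


def _parse_marker_columns(columns: list[str], default_side: str):
    """Map header columns onto (side, joint) pairs; fail on the first bad one."""
    if not columns or columns[0] != "t_ms":
        raise FormatError(
            f"first column must be 't_ms', got {columns[0] if columns else 'nothing'!r}"
        )
    pairs: dict[tuple[str, str], dict[str, str]] = {}
    for col in columns[1:]:
        m = _COL_RE.match(col)
        if not m:
            raise FormatError(f"unrecognized trial column {col!r}")
        side = m.group(1) or default_side
        joint, axis = m.group(2), m.group(3)
        pairs.setdefault((side, joint), {})[axis] = col
    for key, axes in pairs.items():
        if set(axes) != {"x", "y"}:
            raise FormatError(f"marker {key} lacks a paired x/y column")
    return pairs


def read_trial_csv(
    path: str | Path,
    dialect: str = "kinovea",
    subject_id: str = "",
    side: str = "right",
    fs: float = 120.0,
) -> TrialTrajectory | AngleSeries:
    """Read one trial file in the named dialect.

    ``dialect='angle'`` returns an :class:`AngleSeries` (columns
    ``t_ms,angle_deg``); the others return a :class:`TrialTrajectory`.
    Blank cells become NaN positions with ``missing_mask`` set; nothing is
    interpolated here.
    """
    path = Path(path)
    if not path.exists():
        raise ResolutionError(f"trial file not found: {path}")
    # round_trip parsing keeps re-read values bit-identical to what was written
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)

    if dialect == "angle":
        if cols[:2] != ["t_ms", "angle_deg"]:
            raise FormatError(f"angle dialect needs columns t_ms,angle_deg, got {cols[:2]}")
        t = df["t_ms"].to_numpy(float)
        _check_monotonic(t)
        return AngleSeries(subject_id, side, t, df["angle_deg"].to_numpy(float), fs=fs)

    if dialect == "long":
        need = ["t_ms", "side", "joint", "x", "y"]
        if cols[: len(need)] != need:
            raise FormatError(f"long dialect needs columns {need}, got {cols}")
        t = np.sort(df["t_ms"].unique().astype(float))
        _check_monotonic(t)
        pos: dict[tuple[str, str], np.ndarray] = {}
        for (s, j), sub in df.groupby(["side", "joint"]):
            if s not in SIDES or j not in JOINTS:
                raise FormatError(f"unknown side/joint pair ({s!r}, {j!r})")
            sub = sub.set_index("t_ms").reindex(t)
            pos[(s, j)] = sub[["x", "y"]].to_numpy(float)
        return TrialTrajectory(subject_id, side, t, pos)

    if dialect == "kinovea":
        pairs = _parse_marker_columns(cols, default_side=side)
        t = df["t_ms"].to_numpy(float)
        _check_monotonic(t)
        pos = {
            key: np.column_stack(
                [df[axes["x"]].to_numpy(float), df[axes["y"]].to_numpy(float)]
            )
            for key, axes in pairs.items()
        }
        return TrialTrajectory(subject_id, side, t, pos)

    raise ConfigError(f"unknown dialect {dialect!r}")


def _check_monotonic(t: np.ndarray) -> None:
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise DataError(f"time not strictly increasing at frame {idx + 1}")


def write_trial_csv(traj: TrialTrajectory, path: str | Path) -> Path:
    """Write a trajectory in the kinovea dialect; round trips to 1e-9."""
    if not traj.pos:
        raise DataError("refusing to write a trajectory with no markers")
    path = Path(path)
    data: dict[str, np.ndarray] = {"t_ms": traj.t}
    for (s, j) in traj.markers:
        xy = traj.pos[(s, j)]
        data[f"{s}_{j}x"] = xy[:, 0]
        data[f"{s}_{j}y"] = xy[:, 1]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def write_angle_csv(series: AngleSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t_ms": series.t, "angle_deg": series.angle}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def load_manifest(path: str | Path) -> CohortManifest:
    """Load a cohort manifest (YAML list under ``entries:`` or CSV).

    Columns/keys: subject_id, group ∈ {healthy, pd_off, pd_on}, side,
    path (relative paths resolve against the manifest's directory) and an
    optional dialect (default "angle"). Duplicate (subject_id, side)
    within a group and unresolvable paths are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ResolutionError(f"manifest not found: {path}")
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        if isinstance(raw, dict):
            raw = raw.get("entries", raw)
        if not isinstance(raw, list):
            raise ConfigError("manifest YAML must hold a list of entries")
        records = raw
    else:
        records = pd.read_csv(path).to_dict("records")

    entries: list[ManifestEntry] = []
    seen: set[tuple[str, str, str]] = set()
    missing: list[str] = []
    for rec in records:
        group = str(rec.get("group", ""))
        if group not in GROUPS:
            raise ConfigError(f"unknown group label {group!r} (expected one of {GROUPS})")
        side = str(rec.get("side", ""))
        if side not in SIDES:
            raise ConfigError(f"unknown side {side!r} for subject {rec.get('subject_id')}")
        sid = str(rec["subject_id"])
        key = (group, sid, side)
        if key in seen:
            raise ConfigError(f"duplicate entry for subject {sid!r} side {side!r} in {group}")
        seen.add(key)
        p = Path(str(rec["path"]))
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            missing.append(str(p))
        entries.append(ManifestEntry(sid, group, side, p, str(rec.get("dialect", "angle"))))
    if missing:
        raise ResolutionError("manifest references missing files: " + ", ".join(missing))
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "entries": [
            {
                "subject_id": e.subject_id,
                "group": e.group,
                "side": e.side,
                "path": str(e.path.name),
                "dialect": e.dialect,
            }
            for e in manifest.entries
        ]
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
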