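"""From 2-D marker positions to a subject gait corridor.

Builds marker trajectories (hip J4, knee J5, ankle J6) via inverse
kinematics from a simulated knee-angle series, recomputes the included
knee angle from the markers, and assembles the phase-normalized
corridor (pointwise mean / SD / min / max across cycles).
"""

import numpy as np

from gaitcorridor import (
    AnalysisConfig,
    CohortSpec,
    angle_to_markers,
    generate_subject,
    trajectory_knee_angles,
)
from gaitcorridor.pipeline import analyze_subject

config = AnalysisConfig()
spec = CohortSpec(seed=7, cycles_per_subject=8)

left, _ = generate_subject(spec, subject_seed=0)
markers = angle_to_markers(left)          # what a tracking export contains
series = trajectory_knee_angles(markers, fs=config.fs)

res = analyze_subject(series, None, config)
corr = res.corridors["left"]
pm = res.metrics["left"]

print(f"cycles found            : {pm.n_cycles}")
print(f"mean knee angle         : {pm.mean_angle:6.1f} deg")
print(f"whole-cycle ROM         : {pm.rom:6.1f} deg")
print(f"stance ROM / swing ROM  : {pm.stance_rom:5.1f} / {pm.swing_rom:5.1f} deg")
print(f"within-subject SD       : {pm.cycle_var:6.2f} deg")
i = int(np.argmin(corr.mean))
print(f"deepest flexion         : {corr.mean[i]:6.1f} deg at {corr.phase[i]:.0f} %"
      f" of the cycle (swing)")
print()
print("The corridor envelope (mean +/- SD, min-max per phase point) is in")
print("`corr.mean`, `corr.sd`, `corr.min`, `corr.max` over `corr.phase`.")
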