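"""Interlimb coordination: recovering an imposed left/right timing lag.

Simulates one subject whose right knee replays the left knee's motor
program delayed by 10 % of the gait cycle, runs the pipeline, and reads
the lag back from the normalized cross-correlation peak.
"""

from gaitcorridor import AnalysisConfig, CohortSpec, generate_subject
from gaitcorridor.pipeline import analyze_subject

config = AnalysisConfig()
spec = CohortSpec(seed=42, interlimb_lag_pct=10.0, interlimb_lag_sd_pct=0.0,
                  decoupling_pct=0.0)

left, right = generate_subject(spec, subject_seed=0)
res = analyze_subject(left, right, config)
c = res.coordination

print(f"Pearson r (lag 0)        : {c.r:6.3f}")
print(f"similarity peak R        : {c.R_peak:6.3f}")
print(f"cross-correlation lag    : {c.lag_pct:+5.1f} % of cycle"
      f"  ({c.lag_ms:+7.1f} ms)")
print()
print("The lag-0 Pearson r is low because the limbs are out of phase, but")
print("the cross-correlation peak shows the waveforms are nearly identical")
print("once the 10 % timing offset (positive = right limb delayed) is removed.")
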