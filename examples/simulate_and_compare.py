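"""Full pipeline demo: simulate a healthy + PD-OFF cohort, analyze it,
and run the normality-gated group comparison.

Generates synthetic knee-angle trials to a temporary directory, runs
read -> gap-fill -> filter -> segment -> normalize -> metrics, then the
statistical layer (Shapiro-gated Welch t / Mann-Whitney with Cohen's d
and achieved power).
"""

import tempfile
from pathlib import Path

from gaitcorridor import (
    AnalysisConfig,
    CohortSpec,
    analyze_cohort,
    generate_cohort,
    load_manifest,
    summarize_tables,
)

config = AnalysisConfig()
specs = [
    CohortSpec(group="healthy", seed=100, n_subjects=12, cycles_per_subject=8),
    CohortSpec(group="pd_off", seed=101, n_subjects=8, cycles_per_subject=8,
               rom_scale=0.65, cycle_noise_sd=3.0, interlimb_lag_pct=8.0,
               interlimb_lag_sd_pct=3.0, decoupling_pct=4.0),
]

with tempfile.TemporaryDirectory() as tmp:
    cohort = generate_cohort(specs, Path(tmp))
    result = analyze_cohort(load_manifest(cohort.manifest_path), config)

print(f"subjects analyzed : {result.metrics.subject_id.nunique()}")
print(f"cycles used       : {result.record.cycles_used}"
      f" (dropped {result.record.cycles_dropped})")

rom = result.metrics.groupby("group")["rom"].mean()
print("\nmean whole-cycle ROM (deg) per group:")
print(rom.round(1).to_string())
print("-> the PD-OFF group moves through a visibly smaller knee excursion.")

tables = summarize_tables(result.metrics, result.coordination, config)
comp = tables["group_comparison"]
cols = ["feature", "test", "p_value", "d", "power"]
print("\nhealthy vs pd_off, phase-specific comparison:")
print(comp[cols].round(3).to_string(index=False))
print("-> each row names the test the Shapiro-Wilk gate selected, the")
print("   effect size (pooled-SD Cohen's d) and the achieved power at the")
print("   actual group sizes.")
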