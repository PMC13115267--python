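# Methods

This note documents the models, conventions and numerical choices behind
`gaitcorridor`, and what the synthetic-cohort experiments do and do not
demonstrate about real recordings.

## Angle convention and kinematics

The knee angle is the included angle at the knee marker between the
thigh segment (knee→hip) and shank segment (knee→ankle), computed as
`arccos` of the normalized dot product and therefore invariant to
rotation, translation and uniform scaling of the marker coordinates —
which is why pixel-space trajectories need no metric calibration
anywhere in the pipeline. 180° is full extension; clinical flexion is
180° − angle. Every downstream metric (ROM, SD, Pearson r,
cross-correlation lags) is invariant under that flip, so the convention
is cosmetic but fixed. On the healthy template the scale matches
clinical 2-D videogrammetry reports: mean angle ≈ 147–165°, whole-cycle
ROM ≈ 60°.

Missing marker frames become NaN and are never imputed at read time.
`gap_fill` linearly bridges interior NaN runs up to `max_gap_frames`
(default 12 ≈ 100 ms at 120 Hz — about the longest dropout a linear
bridge can cross without inventing kinematics); longer runs stay NaN and
any cycle touching one is dropped with reason `gap`, mirroring the usual
exclusion of trials with tracking loss.

## Filtering

A Butterworth low-pass of order 4 with 6 Hz cutoff (fs 120 Hz) is
applied forward and backward (`scipy.signal.filtfilt`) with reflective
(`even`) padding of 3 × (order + 1) samples. The effective magnitude
response is the single-pass response squared and the phase response is
identically zero, so extension-peak timing — which the segmentation
relies on — is untouched. DC gain is exactly 1 (a constant series passes
through at 1e-6), a 1 Hz component passes within 0.1 %, and a 30 Hz
component is attenuated below 1e-4. Time-reversal symmetry holds to
1e-6 deg away from the edges; the filtfilt edge transients decay within
roughly 1.5 s at these settings, and tests compare the interior. Series
containing unfilled gaps are filtered piecewise on the valid spans
(spans shorter than the padding are left as-is and their cycles drop).

## Cycle segmentation and phase normalization

No foot-contact signal exists in a knee-angle-only pipeline, so cycle
boundaries use the terminal-swing extension maximum as the
initial-contact proxy. A knee waveform has *two* near-extension plateaus
per cycle (midstance and terminal swing), so a plain peak search
double-counts; instead the detector first finds the swing-flexion
troughs — the most prominent landmark of the cycle, gated by prominence
≥ 0.4 × the series range and a refractory distance of one minimum cycle
duration (600 ms) — and takes the angle maximum within the 35 % of a
cycle following each trough, provided it exceeds the series mean. That
window contains the terminal re-extension but not the midstance plateau.
Boundaries may also be supplied from a file, bypassing detection.

Cycles with duration outside 600–4000 ms are dropped (`too_short` /
`too_long`); every drop carries a reason into the run record so that
detected = used + dropped always balances. Each surviving cycle is
linearly resampled onto the inclusive 0–100 % grid (101 points, so
toe-off at 60 % is an exact grid point; the boundary point belongs to
stance). Normalization maps each cycle's *own* duration to 100 % and
keeps the duration as metadata — the only reading under which subjects
with different cadences are comparable — with the cohort mean duration
near 1.5 s used for ms-scale reporting of lags.

For interlimb analyses both limbs are segmented on the **left** limb's
events. Segmenting each limb on its own extension peaks would align the
peaks by construction and erase precisely the right-limb delay the
coordination metrics measure.

## Corridors and phase metrics

Subject corridors are pointwise mean/SD/min/max across a subject's
cycles (SD with n−1; zero when a single cycle). Group corridors take the
same statistics across subject *mean* waveforms, so the shaded band is
between-participant dispersion, not pooled-cycle dispersion. ROM is
computed per cycle and then averaged — ROM of the mean waveform is
biased low whenever cycle timing jitters — and within-subject
variability is the across-cycle SD at each phase point averaged over the
stance or swing window.

## Coordination conventions

`cross_correlation` implements the raw discrete sums R_xy[k] = Σ x[n]
y[n+k] with zero padding (linear, not circular); positive k means y (the
right limb) is delayed by k samples. `similarity` mean-centers both
inputs globally and normalizes each lag's sum by the energies of the
*overlapping* samples at that lag. This choice keeps three properties
simultaneously: the lag-0 value equals Pearson r exactly, |R| ≤ 1 at
every lag (Cauchy–Schwarz on the overlap), and a pure shift of a
periodic waveform is recovered exactly. A full-energy denominator loses
the third property on smooth waveforms — shrinking overlap loses edge
terms faster than a one-sample misalignment costs, biasing the peak one
sample toward zero. Peak ties resolve to the smallest |k|, then the
negative k. The search window defaults to ±25 % of the cycle:
physiological interlimb offsets are below half a cycle, and a wider
window only admits spurious matches of the periodic waveform. The
group-reference correlation uses a leave-one-out reference (each subject
against the mean of the others) to avoid self-correlation inflation at
small n.

## Statistical layer

Test selection is a pure function of design and Shapiro–Wilk p-values at
α = 0.05: paired designs gate on the paired differences (normal → paired
t, else Wilcoxon signed-rank, two-sided, zeros dropped, exact null for
n ≤ 25 without ties, else normal approximation with continuity
correction); independent designs gate each group (both normal → Welch t,
else Mann–Whitney U, exact for n₁+n₂ ≤ 20 without ties, else
tie-corrected asymptotic with continuity). Effect sizes are reported on
every row regardless of which branch fired: d_z = d̄/s_d for pairs,
Cohen's d with the df-weighted pooled SD for groups, with magnitude
bands |d| < 0.2 negligible, 0.2–0.5 small, 0.5–0.8 medium, ≥ 0.8 large.
Constant inputs never crash the gate (normality is reported as
untestable and the degenerate comparison returns p = 1 with a flag).
p-values are raw; the report records the number of tests performed
rather than applying a multiplicity correction.

Achieved power for a two-sided two-sample t at effect size d uses the
noncentral t distribution with df = n₁+n₂−2 and noncentrality
δ = d·√(n₁n₂/(n₁+n₂)), counting both rejection tails, so d = 0 returns
exactly α. At 27 vs 8 subjects this reproduces, to two decimals, the
canonical power values for d between 0.66 and 1.98 (0.36 → 1.00). One
caveat the package reports explicitly: this formula models the
pooled-variance t test (as G*Power does). The gated pipeline fires
*Welch's* t when both groups pass normality, and at a 27 : 8 imbalance
Welch's effective df (~11 under equal variances) puts its Monte-Carlo
power roughly 0.03–0.04 below the pooled-t value at d ≈ 1.3. The
achieved-power column therefore slightly overstates the power of the
Welch branch at strongly unbalanced n; the acceptance script reports
both the pooled-t and gated-branch empirical powers.

## Synthetic cohort generator

One cycle of the knee included angle is modelled as a baseline near full
extension (177°) minus two periodic Gaussian flexion bumps: a stance
wave (18° at 15 % of the cycle, σ 6 %) for weight acceptance and a swing
wave (60° at 72 %, σ 9 %) for limb clearance, giving a healthy
whole-cycle ROM ≈ 60°. Angles are clamped to the anatomical (0°, 180°]
range. Cohort structure, all pure functions of (spec seed, subject
seed):

- between subject: baseline offset ~ N(0, 5°), ROM multiplier jitter
  (CV 0.05), mean cycle duration ~ N(1501, 100) ms;
- within subject: per-cycle duration jitter (SD 40 ms) and additive
  band-limited noise (white noise low-passed at 8 Hz, rescaled to the
  requested SD) — smooth enough that the 6 Hz pipeline filter is
  exercised without being load-bearing;
- interlimb: the right limb replays the left program delayed by a
  per-subject lag plus per-cycle phase jitter ("decoupling");
- optional freezing episodes: a held-angle window per cycle, the minimal
  amplitude-collapse model needed to stress variability metrics.

Group presets encode the study conditions on the published scale:
healthy (n 27, ROM ×1.0, noise 1°, lag 0 ± 1 %, decoupling 0.5 %),
PD-OFF (n 8, ×0.65, 3°, 8 ± 3 %, 4 %), PD-ON (n 8, ×0.85, 2°, 4 ± 2 %,
2 %). The SDs, duration jitters and the 8 Hz noise band are repository
calibrations chosen once as physiologically plausible.

What the generator does *not* emulate: tremor, stride-to-stride
autocorrelation beyond smooth noise, asymmetric unilateral onset,
marker soft-tissue artefact, perspective error, or any frontal/
transverse-plane motion. Passing parameter-recovery tests therefore
demonstrates that the pipeline measures what it claims on data with this
covariance structure — not that a camera-and-marker system achieves the
same accuracy.

## Validation experiments and problem sizes

Parameter-recovery experiments vary one generator parameter at a time
with the others at healthy defaults, since recovery is only attributable
when nuisance parameters are matched: an imposed 10 % interlimb lag is
recovered to ±1 % (6 subjects); a ×0.65 ROM attenuation to within 10 %
and a 5° between-subject dispersion to within 40 % (20 subjects × 10
cycles each). Statistical calibration uses 1000 null replicates (type-I
error within 0.05 ± 0.015 at n = 27/8) and 500 alternative replicates at
d = 1.3 against the noncentral-t prediction. The interlimb-coordination
ordering healthy > PD-ON > PD-OFF is checked on 50 seeded cohorts at the
default group sizes in the test suite (20 in the acceptance script).
These sizes make the whole suite run in well under a minute while
keeping Monte-Carlo error comfortably inside each tolerance.

## Known limitations

- The terminal-swing boundary proxy assumes one dominant swing-flexion
  trough per cycle; severely degraded waveforms (e.g. continuous
  freezing) can defeat it, which is why boundaries can be provided
  externally.
- Cross-correlation lags are quantized to the phase grid (1 % of a
  cycle ≈ 15 ms at a 1.5 s cycle).
- Within-subject variability conflates amplitude and timing variability;
  no time-warping decomposition is attempted.
- The statistical layer reports raw p-values by design and leaves
  age/covariate adjustment out of scope.
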