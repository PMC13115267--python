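"""Normality-gated hypothesis tests, Cohen's effect sizes and achieved power.

Test selection is a pure function of the design and the Shapiro-Wilk
p-value(s) at level α:

* paired design — the gate runs on the paired differences; normal →
  paired t, otherwise Wilcoxon signed-rank (two-sided, zeros dropped,
  exact null for n ≤ 25 without ties, else normal approximation with
  continuity correction). The effect size is Cohen's d_z = d̄ / s_d
  regardless of which branch fired.
* independent design — the gate runs on each group; both normal →
  Welch's t, otherwise Mann-Whitney U (two-sided, exact for
  n1+n2 ≤ 20 without ties, else tie-corrected normal approximation with
  continuity). The effect size is Cohen's d with the df-weighted pooled
  SD s_p = √(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)).

Achieved (post hoc) power for a two-sided two-sample t at effect size d
uses the noncentral t distribution with df = n1+n2−2 and noncentrality
δ = d·√(n1·n2/(n1+n2)), counting both rejection tails.

Effect magnitudes are read on |d|: < 0.2 negligible, 0.2-0.5 small,
0.5-0.8 medium, ≥ 0.8 large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DataError, UndefinedStatisticError


@dataclass
class PairedEffect:
    d_bar: float  # mean paired difference
    s_d: float  # SD of paired differences (n−1)
    dz: float  # d_bar / s_d; NaN when s_d == 0


@dataclass
class GroupEffect:
    mean1: float
    mean2: float
    s_p: float  # df-weighted pooled SD
    d: float  # (mean1 − mean2) / s_p
    n1: int
    n2: int


@dataclass
class TestResult:
    feature: str
    test: str  # paired_t | wilcoxon | welch_t | mann_whitney | degenerate
    shapiro_p: float | tuple[float, float]
    p_value: float
    effect: PairedEffect | GroupEffect
    power: float | None
    interpretation: str
    flags: list[str]


def interpret_effect(d: float) -> str:
    a = abs(d)
    if math.isnan(a):
        return "undefined"
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def shapiro_gate(values: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk p-value and the normality verdict (p ≥ α → normal).

    Constant input never crashes: it returns (nan, False) since normality
    is untestable and the parametric branch would be degenerate anyway.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise DataError(f"Shapiro-Wilk needs n >= 3, got {v.size}")
    if v.size > 5000:
        raise DataError("Shapiro-Wilk unreliable beyond n = 5000")
    if np.ptp(v) == 0:
        return float("nan"), False
    p = float(stats.shapiro(v).pvalue)
    return p, p >= alpha


def cohen_dz(differences: Sequence[float]) -> PairedEffect:
    d = np.asarray(differences, float)
    d_bar = float(d.mean())
    s_d = float(d.std(ddof=1)) if d.size > 1 else 0.0
    dz = d_bar / s_d if s_d > 0 else float("nan")
    return PairedEffect(d_bar, s_d, dz)


def cohen_d(group1: Sequence[float], group2: Sequence[float]) -> GroupEffect:
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise DataError("Cohen's d needs n >= 2 per group")
    s_p = math.sqrt(
        ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    )
    d = (g1.mean() - g2.mean()) / s_p if s_p > 0 else float("nan")
    return GroupEffect(float(g1.mean()), float(g2.mean()), s_p, d, n1, n2)


def _wilcoxon_p(diffs: np.ndarray) -> float:
    nz = diffs[diffs != 0]
    if nz.size == 0:
        return 1.0
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        diffs, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue)


def _mannwhitney_p(g1: np.ndarray, g2: np.ndarray) -> float:
    pooled = np.concatenate([g1, g2])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (g1.size + g2.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        g1, g2, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def paired_compare(
    left: Sequence[float],
    right: Sequence[float],
    config: AnalysisConfig | None = None,
    feature: str = "",
) -> TestResult:
    """Paired right-vs-left comparison with the normality gate on differences.

    Differences are right − left. All-zero differences short-circuit to a
    degenerate result with p = 1 and an undefined d_z.
    """
    config = config or AnalysisConfig()
    l_ = np.asarray(left, float)
    r_ = np.asarray(right, float)
    if l_.size != r_.size:
        raise DataError("paired samples must be equal length")
    if l_.size < 3:
        raise DataError("paired comparison needs n >= 3")
    diffs = r_ - l_
    effect = cohen_dz(diffs)
    flags: list[str] = []
    if np.all(diffs == 0):
        return TestResult(
            feature, "degenerate", float("nan"), 1.0, effect, None,
            "undefined", ["all_differences_zero"],
        )
    shapiro_p, normal = shapiro_gate(diffs, config.alpha)
    if normal:
        p = float(stats.ttest_rel(r_, l_).pvalue)
        test = "paired_t"
    else:
        p = _wilcoxon_p(diffs)
        test = "wilcoxon"
        if np.any(diffs == 0):
            flags.append("zero_differences_dropped")
    return TestResult(
        feature, test, shapiro_p, p, effect, None, interpret_effect(effect.dz), flags
    )


def independent_compare(
    group1: Sequence[float],
    group2: Sequence[float],
    config: AnalysisConfig | None = None,
    feature: str = "",
) -> TestResult:
    """Between-group comparison with per-group normality gates.

    Welch's t when both groups pass the gate, Mann-Whitney U otherwise.
    Cohen's d uses the df-weighted pooled SD; achieved power is attached
    at the actual group sizes.
    """
    config = config or AnalysisConfig()
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size < 3 or g2.size < 3:
        raise DataError("independent comparison needs n >= 3 per group")
    flags: list[str] = []
    if np.ptp(g1) == 0 and np.ptp(g2) == 0:
        if g1.mean() == g2.mean():
            eff = GroupEffect(float(g1.mean()), float(g2.mean()), 0.0, float("nan"),
                              g1.size, g2.size)
            return TestResult(feature, "degenerate", (float("nan"), float("nan")),
                              1.0, eff, None, "undefined", ["zero_variance"])
        flags.append("zero_variance")
    p1, n1_ok = shapiro_gate(g1, config.alpha)
    p2, n2_ok = shapiro_gate(g2, config.alpha)
    effect = cohen_d(g1, g2)
    if n1_ok and n2_ok:
        p = float(stats.ttest_ind(g1, g2, equal_var=False).pvalue)
        test = "welch_t"
    else:
        p = _mannwhitney_p(g1, g2)
        test = "mann_whitney"
    power = (
        achieved_power_t(abs(effect.d), effect.n1, effect.n2, config.alpha)
        if not math.isnan(effect.d)
        else None
    )
    return TestResult(
        feature, test, (p1, p2), p, effect, power, interpret_effect(effect.d), flags
    )


def achieved_power_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power at effect size d (noncentral t).

    df = n1+n2−2, noncentrality δ = d·√(n1·n2/(n1+n2)); both rejection
    tails count, so d = 0 returns exactly α.
    """
    if d < 0:
        raise DataError("d must be >= 0 (power is symmetric in the sign)")
    if n1 < 2 or n2 < 2:
        raise DataError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    df = n1 + n2 - 2
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, delta)
    lower = stats.nct.cdf(-tcrit, df, delta)
    # far in the noncentral tail scipy can lose the negligible term
    if math.isnan(upper):
        upper = 1.0 if delta > tcrit else 0.0
    if math.isnan(lower):
        lower = 0.0
    return float(upper + lower)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_PHASE_FEATURES = [
    ("stance_rom", "Stance", "ROM"),
    ("swing_rom", "Swing", "ROM"),
    ("stance_var", "Stance", "Variability"),
    ("swing_var", "Swing", "Variability"),
]

_PAIRED_FEATURES = [
    ("mean_angle", "Mean knee angle (deg)"),
    ("rom", "ROM (deg)"),
    ("cycle_var", "Within-subject SD (deg)"),
]


def _result_row(res: TestResult) -> dict:
    eff = res.effect
    row = {
        "feature": res.feature,
        "test": res.test,
        "p_value": res.p_value,
        "interpretation": res.interpretation,
        "flags": ";".join(res.flags),
    }
    if isinstance(eff, PairedEffect):
        row.update(shapiro_p=res.shapiro_p, d_bar=eff.d_bar, s_d=eff.s_d, dz=eff.dz)
    else:
        sp = res.shapiro_p
        row.update(
            shapiro_p1=sp[0], shapiro_p2=sp[1],
            mean1=eff.mean1, mean2=eff.mean2, pooled_sd=eff.s_p,
            d=eff.d, n1=eff.n1, n2=eff.n2, power=res.power,
        )
    return row


def summarize_tables(
    metrics: pd.DataFrame,
    coordination: pd.DataFrame | None,
    config: AnalysisConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the report tables from per-subject metrics and coordination rows.

    ``metrics`` needs one row per subject × side with columns subject_id,
    group, side and the PhaseMetrics fields; ``coordination`` one row per
    subject with columns subject_id, group, r (may be None).

    Returns up to four tables:

    * ``paired_right_left`` — right-vs-left paired comparison per feature,
      for each group with both sides present;
    * ``group_comparison`` — healthy vs each PD group per side × phase ×
      metric, with the gated test, d and achieved power;
    * ``power`` — the effect-size / achieved-power columns of the above;
    * ``interlimb_r`` — pairwise between-group comparison of per-subject
      interlimb r.
    """
    config = config or AnalysisConfig()
    out: dict[str, pd.DataFrame] = {}
    n_tests = 0

    # (a) paired right vs left, per group
    paired_rows = []
    for group, gdf in metrics.groupby("group"):
        value_cols = [c for c, _ in _PAIRED_FEATURES if c in gdf.columns]
        wide = gdf.pivot_table(index="subject_id", columns="side", values=value_cols)
        for col, label in _PAIRED_FEATURES:
            try:
                left = wide[(col, "left")].dropna()
                right = wide[(col, "right")].dropna()
            except KeyError:
                continue
            common = left.index.intersection(right.index)
            if len(common) < 3:
                continue
            res = paired_compare(left[common], right[common], config, feature=label)
            row = {"group": group, **_result_row(res), "n": len(common)}
            paired_rows.append(row)
            n_tests += 1
    if paired_rows:
        out["paired_right_left"] = pd.DataFrame(paired_rows)

    # (b) between-group phase metrics: healthy vs each PD group
    groups = sorted(metrics["group"].unique())
    comp_rows = []
    if "healthy" in groups:
        for other in [g for g in groups if g != "healthy"]:
            for side in sorted(metrics["side"].unique()):
                for col, phase, metric in _PHASE_FEATURES:
                    g1 = metrics.query("group == 'healthy' and side == @side")[col].dropna()
                    g2 = metrics.query("group == @other and side == @side")[col].dropna()
                    if len(g1) < 3 or len(g2) < 3:
                        continue
                    res = independent_compare(
                        g1, g2, config, feature=f"{side} {phase} {metric}"
                    )
                    comp_rows.append({
                        "comparison": f"healthy vs {other}",
                        "side": side, "phase": phase, "metric": metric,
                        **_result_row(res),
                    })
                    n_tests += 1
    if comp_rows:
        df = pd.DataFrame(comp_rows)
        out["group_comparison"] = df
        out["power"] = df[["comparison", "feature", "d", "power"]].copy()

    # (c) interlimb r between groups (pairwise)
    if coordination is not None and not coordination.empty:
        co_rows = []
        cgroups = sorted(coordination["group"].unique())
        for i, ga in enumerate(cgroups):
            for gb in cgroups[i + 1:]:
                ra = coordination.query("group == @ga")["r"].dropna()
                rb = coordination.query("group == @gb")["r"].dropna()
                if len(ra) < 3 or len(rb) < 3:
                    continue
                res = independent_compare(ra, rb, config, feature="interlimb r")
                co_rows.append({"comparison": f"{ga} vs {gb}", **_result_row(res)})
                n_tests += 1
        if co_rows:
            out["interlimb_r"] = pd.DataFrame(co_rows)

    for df in out.values():
        df.attrs["n_tests_total"] = n_tests  # raw p-values; no correction applied
    return out
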