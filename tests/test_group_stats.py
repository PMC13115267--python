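import numpy as np
import pandas as pd
import pytest

from gaitcorridor import (
    AnalysisConfig,
    achieved_power_t,
    cohen_d,
    cohen_dz,
    independent_compare,
    paired_compare,
    shapiro_gate,
    summarize_tables,
)
from gaitcorridor.errors import DataError


class TestShapiroGate:
    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(10)
        passed = sum(
            shapiro_gate(rng.normal(size=50))[1] for _ in range(100)
        )
        assert passed >= 90

    def test_lognormal_samples_usually_fail(self):
        rng = np.random.default_rng(11)
        failed = sum(
            not shapiro_gate(rng.lognormal(0, 1, size=50))[1] for _ in range(100)
        )
        assert failed >= 90

    def test_constant_input_never_crashes(self):
        p, normal = shapiro_gate([5.0] * 10)
        assert np.isnan(p) and normal is False

    def test_tiny_sample_rejected(self):
        with pytest.raises(DataError):
            shapiro_gate([1.0, 2.0])


class TestEffectSizes:
    def test_dz_hand_computation(self):
        eff = cohen_dz([1, 1, 1, 1, -1])
        assert eff.d_bar == pytest.approx(0.6)
        assert eff.s_d == pytest.approx(0.8944, abs=5e-5)
        assert eff.dz == pytest.approx(0.6708, abs=5e-5)

    def test_d_with_equal_group_sds(self):
        # means 10 vs 8, both SD exactly 2, n=16 each -> d = 1.0
        rng = np.random.default_rng(12)
        z = rng.normal(size=16)
        z = (z - z.mean()) / z.std(ddof=1)
        g1, g2 = 10 + 2 * z, 8 + 2 * z
        eff = cohen_d(g1, g2)
        assert eff.s_p == pytest.approx(2.0)
        assert eff.d == pytest.approx(1.0)

    def test_d_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(13)
        g1, g2 = rng.normal(2, 1, 20), rng.normal(0, 1.5, 12)
        assert cohen_d(g1, g2).d == pytest.approx(-cohen_d(g2, g1).d)

    def test_dz_antisymmetric_under_pair_swap(self):
        d = np.array([0.3, -0.1, 0.8, 0.5, 0.2])
        assert cohen_dz(d).dz == pytest.approx(-cohen_dz(-d).dz)


class TestPairedCompare:
    def test_identical_pairs_degenerate(self, config):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_compare(x, x, config)
        assert res.p_value == 1.0
        assert res.test == "degenerate"
        assert np.isnan(res.effect.dz)
        assert "all_differences_zero" in res.flags

    def test_effect_reported_regardless_of_branch(self, config):
        left = np.zeros(5)
        right = np.array([1.0, 1.0, 1.0, 1.0, -1.0])
        res = paired_compare(left, right, config)
        assert res.effect.d_bar == pytest.approx(0.6)
        assert res.effect.dz == pytest.approx(0.6708, abs=5e-5)
        assert res.test in ("paired_t", "wilcoxon")

    def test_gaussian_shift_selects_t_branch(self, config):
        rng = np.random.default_rng(14)
        left = rng.normal(150, 5, 27)
        right = left + rng.normal(1, 1, 27)
        res = paired_compare(left, right, config)
        assert res.test == "paired_t"
        assert res.shapiro_p >= config.alpha

    def test_skewed_differences_select_wilcoxon(self, config):
        rng = np.random.default_rng(15)
        left = rng.normal(150, 5, 40)
        right = left + rng.lognormal(0, 1, 40)
        res = paired_compare(left, right, config)
        assert res.test == "wilcoxon"
        assert res.shapiro_p < config.alpha

    def test_rejection_rate_matches_noncentral_t_prediction(self, config):
        """Paired-t power at dz=1, n=27 calibrates against the analytic value."""
        from scipy import stats

        n, dz = 27, 1.0
        tcrit = stats.t.ppf(0.975, n - 1)
        delta = dz * np.sqrt(n)
        predicted = float(
            1 - stats.nct.cdf(tcrit, n - 1, delta) + stats.nct.cdf(-tcrit, n - 1, delta)
        )
        rng = np.random.default_rng(16)
        rej = 0
        reps = 500
        for _ in range(reps):
            left = rng.normal(0, 5, n)
            right = left + rng.normal(1, 1, n)
            rej += paired_compare(left, right, config).p_value < config.alpha
        assert rej / reps == pytest.approx(predicted, abs=0.04)


class TestIndependentCompare:
    def test_identical_groups_null(self, config):
        rng = np.random.default_rng(17)
        g = rng.normal(150, 5, 16)
        res = independent_compare(g, g.copy(), config)
        assert res.effect.d == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_nonnormal_group_routes_to_mann_whitney(self, config):
        rng = np.random.default_rng(18)
        g1 = rng.normal(10, 1, 27)
        g2 = rng.lognormal(1, 1.2, 30)
        res = independent_compare(g1, g2, config)
        assert res.test == "mann_whitney"

    def test_power_column_consistent_with_achieved_power(self, config):
        rng = np.random.default_rng(19)
        g1, g2 = rng.normal(10, 2, 27), rng.normal(8, 2, 8)
        res = independent_compare(g1, g2, config)
        assert res.power == pytest.approx(
            achieved_power_t(abs(res.effect.d), 27, 8, config.alpha)
        )

    def test_swapping_groups_flips_d_keeps_p(self, config):
        rng = np.random.default_rng(20)
        g1, g2 = rng.normal(10, 2, 20), rng.normal(8, 2, 10)
        a = independent_compare(g1, g2, config)
        b = independent_compare(g2, g1, config)
        assert a.effect.d == pytest.approx(-b.effect.d)
        assert a.p_value == pytest.approx(b.p_value)


class TestAchievedPower:
    def test_null_effect_gives_alpha(self):
        assert achieved_power_t(0.0, 27, 8, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_and_samples_and_alpha(self):
        ds = [achieved_power_t(d, 27, 8) for d in (0.2, 0.5, 1.0, 1.5)]
        assert ds == sorted(ds)
        ns = [achieved_power_t(0.8, n, 8) for n in (5, 10, 27, 60)]
        assert ns == sorted(ns)
        n2s = [achieved_power_t(0.8, 27, n) for n in (3, 8, 20)]
        assert n2s == sorted(n2s)
        als = [achieved_power_t(0.8, 27, 8, a) for a in (0.01, 0.05, 0.1)]
        assert als == sorted(als)

    def test_saturates_at_one_for_huge_effects(self):
        assert achieved_power_t(10.0, 27, 8) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DataError):
            achieved_power_t(-0.5, 27, 8)
        with pytest.raises(DataError):
            achieved_power_t(0.5, 1, 8)
        with pytest.raises(DataError):
            achieved_power_t(0.5, 27, 8, alpha=1.5)


def _metrics_frame(rng, groups):
    rows = []
    for group, n, shift in groups:
        for i in range(n):
            for side in ("left", "right"):
                rows.append({
                    "subject_id": f"{group}{i}", "group": group, "side": side,
                    "stance_rom": rng.normal(50 - shift, 8),
                    "swing_rom": rng.normal(49 - shift, 9),
                    "stance_var": rng.normal(15, 4),
                    "swing_var": rng.normal(17, 4),
                    "cycle_var": rng.normal(17, 3),
                    "mean_angle": rng.normal(147, 6),
                    "rom": rng.normal(63 - shift, 9),
                    "n_cycles": 10,
                })
    return pd.DataFrame(rows)


class TestSummarizeTables:
    def test_single_group_yields_only_paired_table(self, config):
        rng = np.random.default_rng(21)
        tables = summarize_tables(_metrics_frame(rng, [("healthy", 10, 0)]), None, config)
        assert set(tables) == {"paired_right_left"}

    def test_two_groups_yield_comparison_and_power_tables(self, config):
        rng = np.random.default_rng(22)
        metrics = _metrics_frame(rng, [("healthy", 27, 0), ("pd_off", 8, 12)])
        coord = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(35)],
            "group": ["healthy"] * 27 + ["pd_off"] * 8,
            "r": np.concatenate([rng.uniform(0.88, 0.96, 27), rng.uniform(0.4, 0.8, 8)]),
        })
        tables = summarize_tables(metrics, coord, config)
        assert {"paired_right_left", "group_comparison", "power", "interlimb_r"} <= set(tables)
        comp = tables["group_comparison"]
        # 2 sides x 4 phase-metrics for one comparison
        assert len(comp) == 8
        # every row records the branch that fired and its gate
        assert comp["test"].isin(["welch_t", "mann_whitney"]).all()
        assert comp[["shapiro_p1", "shapiro_p2"]].notna().all().all()
        # power column is internally consistent with the noncentral-t formula
        for _, row in tables["power"].iterrows():
            assert row["power"] == pytest.approx(
                achieved_power_t(abs(row["d"]), 27, 8, config.alpha), abs=1e-9
            )
        assert (tables["interlimb_r"]["p_value"] < 0.05).all()

    def test_null_cohorts_show_small_effects(self, config):
        """With no true group difference the |d| column stays near zero."""
        all_d, sig = [], 0
        n_rows = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            metrics = _metrics_frame(rng, [("healthy", 27, 0), ("pd_off", 8, 0)])
            tables = summarize_tables(metrics, None, config)
            comp = tables["group_comparison"]
            all_d.extend(comp["d"].abs())
            sig += int((comp["p_value"] < 0.05).sum())
            n_rows += len(comp)
        # E|d_hat| under the null at n=27/8 is ~0.32; sig fraction ~alpha
        assert np.mean(all_d) < 0.45
        assert sig / n_rows < 0.12
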