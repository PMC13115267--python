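import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitcorridor import (
    AnalysisConfig,
    GaitTemplate,
    NormalizedCycle,
    cross_correlation,
    group_reference_correlation,
    interlimb_coordination,
    pearson_r,
    similarity,
    template_waveform,
)
from gaitcorridor.errors import DataError, UndefinedStatisticError

GRID = np.linspace(0.0, 100.0, 101)


def brute_force_xcorr(x, y, max_lag):
    """Direct double-loop evaluation of R_xy[k] = sum_n x[n] y[n+k]."""
    n = len(x)
    out = []
    for k in range(-max_lag, max_lag + 1):
        s = 0.0
        for i in range(n):
            j = i + k
            if 0 <= j < n:
                s += x[i] * y[j]
        out.append(s)
    return np.array(out)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negated_shifted_is_minus_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        assert pearson_r(x, -x + 7.0) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct evaluation of the definitional sums gives 0.92338 (5 dp)
        assert pearson_r([1, 2, 3, 4], [1, 2, 2, 4]) == pytest.approx(0.92338, abs=5e-6)

    def test_symmetry(self):
        x, y = np.array([1.0, 2, 3, 5]), np.array([2.0, 1, 4, 4])
        assert pearson_r(x, y) == pearson_r(y, x)

    def test_zero_variance_is_an_error_not_zero(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.floats(0.01, 50), b=st.floats(-100, 100), seed=st.integers(0, 999))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


class TestCrossCorrelation:
    def test_hand_sums_length_two(self):
        r = cross_correlation([1.0, 1.0], [1.0, 1.0], max_lag=1)
        np.testing.assert_allclose(r, [1.0, 2.0, 1.0])

    def test_unit_impulse_lag(self):
        # y is x delayed by one sample -> peak at k = +1
        r = cross_correlation([1.0, 0.0, 0.0], [0.0, 1.0, 0.0], max_lag=2)
        lags = np.arange(-2, 3)
        assert lags[np.argmax(r)] == 1
        np.testing.assert_allclose(r, brute_force_xcorr([1, 0, 0], [0, 1, 0], 2))

    def test_center_is_dot_product(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=16), rng.normal(size=16)
        r = cross_correlation(x, y, max_lag=4)
        assert r[4] == pytest.approx(float(np.dot(x, y)))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 32),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_exactly_on_integers(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(-9, 10, size=n).astype(float)
        y = rng.integers(-9, 10, size=n).astype(float)
        max_lag = n - 1
        np.testing.assert_array_equal(
            cross_correlation(x, y, max_lag), brute_force_xcorr(x, y, max_lag)
        )

    def test_max_lag_bounds(self):
        with pytest.raises(DataError):
            cross_correlation([1.0, 2, 3], [1.0, 2, 3], max_lag=3)


class TestSimilarity:
    def test_identical_signals(self):
        x = template_waveform(GaitTemplate(), GRID)
        R, lag = similarity(x, x, max_lag=25)
        assert R == pytest.approx(1.0) and lag == 0

    def test_lag_zero_value_equals_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=101), rng.normal(size=101)
        R, _ = similarity(x, y, max_lag=25)
        assert R >= pearson_r(x, y) - 1e-12

    @pytest.mark.parametrize("shift", [-20, -5, 0, 5, 20])
    def test_circular_shift_recovered_exactly(self, shift):
        phase = np.linspace(0.0, 100.0, 101)[:-1]  # periodic, no duplicate point
        x = template_waveform(GaitTemplate(), phase)
        y = np.roll(x, shift)
        R, lag = similarity(x, y, max_lag=25)
        assert lag == shift
        assert R > 0.9

    def test_white_noise_null_peak_is_small(self):
        """|R_peak| < 0.5 in at least 95 % of independent null pairs."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.normal(size=101), rng.normal(size=101)
            R, _ = similarity(x, y, max_lag=25)
            hits += abs(R) < 0.5
        assert hits / n_rep > 0.95

    def test_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x, y = rng.normal(size=31), rng.normal(size=31)
            R, _ = similarity(x, y, max_lag=30)
            assert abs(R) <= 1.0 + 1e-12


class TestInterlimbCoordination:
    def _cycle(self, angle, side, dur=1501.0):
        return NormalizedCycle(GRID.copy(), np.asarray(angle, float), dur, "s", side)

    def test_identical_limbs(self, config):
        x = template_waveform(GaitTemplate(), GRID)
        res = interlimb_coordination(
            self._cycle(x, "left"), self._cycle(x, "right"), config
        )
        assert res.r == pytest.approx(1.0)
        assert res.lag_pct == 0.0 and res.lag_ms == 0.0

    def test_delayed_right_limb_positive_lag(self, config):
        phase = GRID
        x = template_waveform(GaitTemplate(), phase)
        y = template_waveform(GaitTemplate(), phase - 10.0)  # right delayed 10 %
        res = interlimb_coordination(
            self._cycle(x, "left"), self._cycle(y, "right", dur=1501.0), config
        )
        assert res.lag_pct == pytest.approx(10.0, abs=1.0)
        assert res.lag_ms == pytest.approx(res.lag_pct * 1501.0 / 100.0)
        assert res.R_peak >= res.r

    def test_lag_bounded_by_search_window(self, config):
        rng = np.random.default_rng(4)
        res = interlimb_coordination(
            self._cycle(rng.normal(size=101), "left"),
            self._cycle(rng.normal(size=101), "right"),
            config,
        )
        assert abs(res.lag_pct) <= config.max_lag_pct


class TestGroupReferenceCorrelation:
    def _cycles(self, arrs):
        return [
            NormalizedCycle(GRID.copy(), np.asarray(a, float), 1000.0, f"s{i}")
            for i, a in enumerate(arrs)
        ]

    def test_identical_subjects_all_one(self):
        x = template_waveform(GaitTemplate(), GRID)
        rs = group_reference_correlation(self._cycles([x, x.copy(), x.copy()]))
        assert rs == pytest.approx([1.0, 1.0, 1.0])

    def test_negated_deviation_subject_scores_lowest(self):
        tpl = template_waveform(GaitTemplate(), GRID)
        dev = 5 * np.sin(2 * np.pi * GRID / 100 * 3)
        arrs = [tpl + dev, tpl + dev, tpl + dev, tpl - 3 * dev]
        rs = group_reference_correlation(self._cycles(arrs))
        assert np.argmin(rs) == 3

    def test_leave_one_out_differs_from_full_mean_at_n3(self):
        rng = np.random.default_rng(5)
        arrs = [rng.normal(size=101) for _ in range(3)]
        rs = group_reference_correlation(self._cycles(arrs))
        full_mean = np.mean(arrs, axis=0)
        rs_full = [pearson_r(a, full_mean) for a in arrs]
        assert not np.allclose(rs, rs_full)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DataError):
            group_reference_correlation(self._cycles([GRID, GRID]))
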