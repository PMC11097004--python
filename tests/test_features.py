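"""Feature engineering: windowed primitives against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import accelbehave as ab
from accelbehave.features import FeatureFrame, running_mean, running_se

from conftest import oracle_block_means, oracle_running_mean, oracle_running_se


def constant_trace(n=200, rate=40.0, vec=(0.0, 1.0, 0.0)):
    t = np.arange(n) / rate
    return ab.AccelTrace(rate, t, np.full(n, vec[0]), np.full(n, vec[1]),
                         np.full(n, vec[2]))


class TestStaticDynamicSplit:
    def test_constant_input_is_all_static(self):
        tr = constant_trace()
        (sx, sy, sz), (dx, dy, dz) = ab.split_static_dynamic(tr)
        assert np.allclose(sx, 0) and np.allclose(sy, 1) and np.allclose(sz, 0)
        assert np.allclose(dx, 0) and np.allclose(dy, 0) and np.allclose(dz, 0)

    def test_whole_period_sine_averages_out_of_the_static(self):
        rate, n = 40.0, 800
        t = np.arange(n) / rate
        tr = ab.AccelTrace(rate, t, np.zeros(n),
                           1.0 + 0.5 * np.sin(2 * np.pi * 5.0 * t), np.zeros(n))
        (_, sy, _), _ = ab.split_static_dynamic(tr, window_s=2.0)
        interior = sy[80:-80]
        assert np.all(np.abs(interior - 1.0) <= 0.01)

    def test_raw_minus_static_equals_dynamic(self, rng):
        n = 400
        tr = ab.AccelTrace(40.0, np.arange(n) / 40.0, rng.normal(size=n),
                           rng.normal(size=n), rng.normal(size=n))
        static, dynamic = ab.split_static_dynamic(tr)
        for raw, s, d in zip((tr.ax, tr.ay, tr.az), static, dynamic):
            assert np.allclose(raw - s, d, atol=1e-12)

    def test_empty_trace_rejected(self):
        tr = constant_trace(5)
        tr.t = tr.t[:0]; tr.ax = tr.ax[:0]; tr.ay = tr.ay[:0]; tr.az = tr.az[:0]
        with pytest.raises(ValueError):
            ab.split_static_dynamic(tr)


class TestVedba:
    @pytest.mark.parametrize("vec,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
        ((0.3, 0.4, 1.2), 1.3),  # 3-4-12 Pythagorean quadruple
    ])
    def test_known_norms(self, vec, expected):
        out = ab.vedba(np.array([vec[0]]), np.array([vec[1]]), np.array([vec[2]]))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ab.vedba(np.zeros(3), np.zeros(2), np.zeros(3))


class TestSmooth:
    def test_constant_is_invariant(self):
        out = ab.smooth(np.full(300, 2.5), 2.0, 40.0)
        assert np.allclose(out, 2.5)

    def test_unit_impulse_spreads_to_one_over_window(self):
        x = np.zeros(400)
        x[200] = 1.0
        out = ab.smooth(x, 2.0, 40.0)  # 80-sample window
        hits = np.flatnonzero(out > 0)
        assert len(hits) == 80
        assert np.allclose(out[hits], 1.0 / 80)

    def test_non_positive_window_rejected(self):
        with pytest.raises(ValueError):
            ab.smooth(np.ones(10), 0.0, 40.0)


class TestRunningSE:
    def test_constant_series_has_zero_se(self):
        assert np.allclose(ab.running_se(np.full(100, 3.0), 7), 0.0)

    def test_three_sample_window_closed_form(self):
        # middle of [1, 2, 3]: sd = 1, se = 1/sqrt(3)
        out = running_se(np.array([1.0, 2.0, 3.0]), 3)
        assert out[1] == pytest.approx(0.5774, abs=1e-4)


class TestWindowedOracles:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 1000), st.integers(2, 120), st.integers(0, 2 ** 31 - 1))
    def test_running_mean_matches_brute_force(self, n, window, seed):
        x = np.random.default_rng(seed).normal(size=n)
        assert np.allclose(running_mean(x, window),
                           oracle_running_mean(x, window), atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(3, 1000), st.integers(3, 120), st.integers(0, 2 ** 31 - 1))
    def test_running_se_matches_brute_force(self, n, window, seed):
        x = np.random.default_rng(seed).normal(size=n)
        assert np.allclose(running_se(x, window),
                           oracle_running_se(x, window), atol=1e-9)


class TestPitchRoll:
    @pytest.mark.parametrize("st_vec,pitch,roll", [
        ((0.0, 1.0, 0.0), 0.0, 0.0),    # level: gravity on heave
        ((0.0, 0.0, 1.0), 90.0, 0.0),   # nose up: gravity on surge
        ((1.0, 0.0, 0.0), 0.0, 90.0),   # on its side: gravity on sway
    ])
    def test_reference_postures(self, st_vec, pitch, roll):
        p, r = ab.pitch_roll(*(np.array([v]) for v in st_vec))
        assert p[0] == pytest.approx(pitch, abs=1e-9)
        assert r[0] == pytest.approx(roll, abs=1e-9)

    def test_zero_static_vector_is_flagged(self):
        p, r = ab.pitch_roll(np.zeros(2), np.zeros(2), np.zeros(2))
        assert np.all(np.isnan(p)) and np.all(np.isnan(r))

    def test_angles_invert_the_generator_posture(self):
        regime = ab.DEFAULT_REGIMES["feed"]
        tr = ab.generate_bout(regime, 30, 40, seed=4)
        frame = ab.build_features(tr, "base")
        interior = frame.data.iloc[100:-100]
        assert np.median(interior["Pitch"]) == pytest.approx(-40.0, abs=2.0)


class TestBuildFeatures:
    def test_base_has_13_variables(self, default_features40):
        base = default_features40.restrict("base")
        assert len(base.variables) == 13

    def test_extended_has_21_variables(self, default_features40):
        assert len(default_features40.variables) == 21

    def test_extended_restricted_to_base_matches_base_build(self):
        tr = ab.generate_bout(ab.DEFAULT_REGIMES["walk"], 10, 40, seed=8)
        ext = ab.build_features(tr, "extended")
        base = ab.build_features(tr, "base")
        pd.testing.assert_frame_equal(ext.restrict("base").data, base.data)

    def test_vedba_dominates_each_dynamic_axis(self, default_features40):
        df = default_features40.data
        for axis in ("dyX", "dyY", "dyZ"):
            assert np.all(df["VeDBA"] >= np.abs(df[axis]) - 1e-12)

    def test_se_columns_are_non_negative(self, default_features40):
        df = default_features40.data
        se_cols = [c for c in df.columns if c.startswith("se")]
        assert len(se_cols) == 8
        assert all((df[c] >= 0).all() for c in se_cols)


class TestTo1Hz:
    def _frame(self, values, rate=40):
        n = len(values)
        df = pd.DataFrame({"time_s": np.arange(n) / rate})
        for c in ab.BASE_VARIABLES:
            df[c] = values
        return FeatureFrame(df, float(rate), "base")

    def test_constant_second_collapses_losslessly(self):
        out = ab.to_1hz(self._frame(np.ones(40)))
        assert len(out.data) == 1
        assert out.data.iloc[0]["VeDBA"] == pytest.approx(1.0)

    def test_ramp_mean_is_midpoint(self):
        out = ab.to_1hz(self._frame(np.arange(1.0, 41.0)))
        assert out.data.iloc[0]["VeDBA"] == pytest.approx(20.5)

    def test_row_count_is_floor_of_seconds(self):
        out = ab.to_1hz(self._frame(np.ones(135)))
        assert len(out.data) == 3

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(40, 400), st.integers(0, 2 ** 31 - 1))
    def test_block_means_match_brute_force(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        out = ab.to_1hz(self._frame(x))
        assert np.allclose(out.data["VeDBA"].to_numpy(),
                           oracle_block_means(x, 40), atol=1e-9)

    def test_majority_label_with_earliest_tiebreak(self):
        f = self._frame(np.ones(40))
        f.data["behaviour"] = ["walk"] * 20 + ["trot"] * 20  # tie -> earliest
        out = ab.to_1hz(f)
        assert out.data.iloc[0]["behaviour"] == "walk"
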