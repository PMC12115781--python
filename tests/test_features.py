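import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stresswear as sw
from stresswear.errors import InsufficientDataError
from stresswear.features import FeatureTable, current_window_columns, lag_columns
from stresswear.preprocess import AlignedSignals

import oracle_features as oracle


def signals_from(eda, hr=None, temp=None, subject="S01"):
    eda = np.asarray(eda, dtype=float)
    hr = np.full_like(eda, 70.0) if hr is None else np.asarray(hr, dtype=float)
    temp = np.full_like(eda, 32.0) if temp is None else np.asarray(temp, dtype=float)
    return AlignedSignals(subject, 0.0, 4.0, eda, hr, temp)


class TestWindows:
    @pytest.mark.parametrize(
        "n, expected_starts",
        [(40, [0]), (100, [0, 20, 40, 60]), (59, [0]), (60, [0, 20])],
    )
    def test_window_count_and_starts(self, n, expected_starts):
        windows = sw.make_windows(n, sw.FeatureConfig())
        assert [w[0] for w in windows] == expected_starts
        assert all(stop - start == 40 for start, stop in windows)

    def test_too_short_signal_errors(self):
        with pytest.raises(InsufficientDataError):
            sw.make_windows(39, sw.FeatureConfig())

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 500),
        size=st.integers(1, 60),
        step_frac=st.floats(0.01, 1.0),
    )
    def test_count_matches_brute_force_enumeration(self, n, size, step_frac):
        step = max(1, int(size * step_frac))
        cfg = sw.FeatureConfig(window_size=size, step=step, max_lag=0)
        expected = oracle.oracle_windows(n, size, step)
        if n < size:
            with pytest.raises(InsufficientDataError):
                sw.make_windows(n, cfg)
        else:
            got = sw.make_windows(n, cfg)
            assert got == expected
            assert len(got) == (n - size) // step + 1


class TestRmsFirstDiff:
    @pytest.mark.parametrize(
        "x, expected",
        [([3, 3, 3, 3], 0.0), ([0, 1, 0, 1], 1.0), ([0, 2, 3], np.sqrt(2.5))],
    )
    def test_hand_values(self, x, expected):
        assert sw.rms_first_diff(x) == pytest.approx(expected)

    def test_single_sample_errors(self):
        with pytest.raises(InsufficientDataError):
            sw.rms_first_diff([1.0])


class TestEdaPeaks:
    def test_monotone_window_has_no_peaks(self):
        assert sw.eda_peak_features(np.linspace(0, 1, 40), sw.FeatureConfig()) == (0, 0.0, 0.0)

    def test_triangular_bump_prominence_and_width(self):
        # height-1 triangle over a flat baseline, slope 1/8 per sample:
        # width at half prominence is 8 samples = 2 s at 4 Hz
        idx = np.arange(40)
        x = np.maximum(0.0, 1.0 - np.abs(idx - 20) / 8.0)
        count, amp, dur = sw.eda_peak_features(x, sw.FeatureConfig())
        assert count == 1
        assert amp == pytest.approx(1.0)
        assert dur == pytest.approx(2.0)

    def test_two_disjoint_bumps_double_the_single_bump(self):
        idx = np.arange(40)
        bump = lambda c: np.maximum(0.0, 1.0 - np.abs(idx - c) / 4.0)
        one = sw.eda_peak_features(bump(10), sw.FeatureConfig())
        two = sw.eda_peak_features(bump(10) + bump(30), sw.FeatureConfig())
        assert two[0] == 2 * one[0]
        assert two[1] == pytest.approx(2 * one[1])
        assert two[2] == pytest.approx(2 * one[2])

    def test_subthreshold_prominence_ignored(self):
        idx = np.arange(40)
        x = np.maximum(0.0, 0.005 - np.abs(idx - 20) * 0.001)
        assert sw.eda_peak_features(x, sw.FeatureConfig(peak_prominence=0.01))[0] == 0


class TestWindowFeatures:
    def test_constant_window_conventions(self):
        table = sw.extract_window_features(signals_from(np.full(40, 1.5)))
        row = table.frame.iloc[0]
        assert row["EDA_Min"] == row["EDA_Max"] == row["EDA_Mean"] == 1.5
        for col in ("EDA_Std", "EDA_Skew", "EDA_Kurtosis", "EDA_Peaks",
                    "EDA_Amplitude", "EDA_Duration", "HR_Std", "HR_RMS",
                    "TEMP_Std", "TEMP_RMS"):
            assert row[col] == 0.0

    def test_symmetric_triangle_has_zero_skew(self):
        idx = np.arange(40)
        eda = 1.0 - np.abs(idx - 19.5) / 20.0
        table = sw.extract_window_features(signals_from(eda))
        assert table.frame["EDA_Skew"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_arithmetic_ramp_stats(self):
        eda = np.arange(40) / 39.0
        row = sw.extract_window_features(signals_from(eda)).frame.iloc[0]
        assert row["EDA_Min"] == 0.0 and row["EDA_Max"] == 1.0
        assert row["EDA_Mean"] == pytest.approx(0.5)

    def test_nineteen_canonical_columns(self, rng):
        table = sw.extract_window_features(signals_from(rng.random(100)))
        assert table.feature_columns == current_window_columns()
        assert len(table.feature_columns) == 19

    def test_matches_bruteforce_oracle_on_random_inputs(self, rng):
        cfg = sw.FeatureConfig(window_size=16, step=7, max_lag=0, peak_prominence=0.05)
        for _ in range(25):
            n = rng.integers(16, 200)
            eda, hr, temp = rng.random((3, n))
            table = sw.extract_window_features(signals_from(eda, hr, temp), cfg)
            expected = oracle.oracle_window_features(
                eda, hr, temp, 16, 7, 0.05, cfg.peak_width_fraction
            )
            assert len(table) == len(expected)
            for col in current_window_columns():
                np.testing.assert_allclose(
                    table.frame[col].to_numpy(),
                    [row[col] for row in expected],
                    atol=1e-9,
                    err_msg=col,
                )


class TestLags:
    def two_subject_table(self, rng, n1=15, n2=8):
        frames = []
        for subject, n in (("A", n1), ("B", n2)):
            t = sw.extract_window_features(
                signals_from(rng.random(40 + 20 * (n - 1)), subject=subject)
            )
            frames.append(t.frame)
        return FeatureTable(frame=pd.concat(frames, ignore_index=True))

    def test_eleven_windows_lag10_yields_one_row(self, rng):
        table = sw.extract_window_features(signals_from(rng.random(40 + 20 * 10)))
        out = sw.add_lags(table, sw.FeatureConfig(max_lag=10))
        assert len(out) == 1
        assert len(out.feature_columns) == 49

    def test_lag_zero_is_identity(self, rng):
        table = sw.extract_window_features(signals_from(rng.random(100)))
        out = sw.add_lags(table, sw.FeatureConfig(max_lag=0))
        pd.testing.assert_frame_equal(out.frame, table.frame)

    def test_shift_by_one_hand_example(self, rng):
        table = sw.extract_window_features(signals_from(rng.random(80)))
        means = table.frame["EDA_Mean"].to_numpy()
        out = sw.add_lags(table, sw.FeatureConfig(max_lag=1))
        np.testing.assert_allclose(out.frame["EDA_Mean_lag1"].to_numpy(), means[:-1])

    def test_short_subject_contributes_no_rows_and_warns(self, rng):
        table = self.two_subject_table(rng, n1=15, n2=8)
        with pytest.warns(UserWarning, match="fewer than 11"):
            out = sw.add_lags(table, sw.FeatureConfig(max_lag=10))
        assert set(out.frame["subject_id"]) == {"A"}
        assert len(out) == 5

    def test_lags_never_cross_subjects_and_match_oracle(self, rng):
        table = self.two_subject_table(rng, n1=12, n2=14)
        cfg = sw.FeatureConfig(max_lag=3)
        out = sw.add_lags(table, cfg)
        assert len(out) == (12 - 3) + (14 - 3)
        for subject in ("A", "B"):
            rows = table.frame[table.frame["subject_id"] == subject].to_dict("records")
            expected = oracle.oracle_add_lags(rows, 3)
            got = out.frame[out.frame["subject_id"] == subject]
            for col in lag_columns(3):
                np.testing.assert_allclose(
                    got[col].to_numpy(), [r[col] for r in expected], atol=1e-12
                )


class TestScaling:
    def table_of(self, values, columns=("EDA_Mean", "HR_Mean")):
        frame = pd.DataFrame(np.asarray(values, dtype=float), columns=list(columns))
        frame.insert(0, "window_start", np.arange(len(frame)) * 5.0)
        frame.insert(0, "subject_id", "S01")
        return FeatureTable(frame=frame)

    def test_train_mapped_to_unit_interval(self):
        scaled, _, params = sw.minmax_scale(self.table_of([[2, 0], [4, 10]]))
        np.testing.assert_allclose(scaled.frame["EDA_Mean"], [0, 1])
        assert params["EDA_Mean"] == (2, 4)

    def test_constant_column_maps_to_zero(self):
        scaled, _, _ = sw.minmax_scale(self.table_of([[3, 1], [3, 2]]))
        np.testing.assert_allclose(scaled.frame["EDA_Mean"], [0.0, 0.0])

    def test_other_tables_use_train_parameters(self):
        train = self.table_of([[0, 0], [10, 1]])
        other = self.table_of([[5, 2]])
        _, (scaled_other,), _ = sw.minmax_scale(train, [other])
        assert scaled_other.frame["EDA_Mean"].iloc[0] == pytest.approx(0.5)
        assert scaled_other.frame["HR_Mean"].iloc[0] == pytest.approx(2.0)  # may exceed [0,1]

    # values on a 0.1-spaced grid: a degenerate (near-zero) column range would
    # legitimately change the scaled output, which is not the property under test
    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.integers(-1000, 1000).map(lambda v: v / 10.0),
            min_size=2,
            max_size=20,
            unique=True,
        ),
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, values, a, b):
        base = self.table_of([[v, 0.0] for v in values])
        transformed = self.table_of([[a * v + b, 0.0] for v in values])
        s1, _, _ = sw.minmax_scale(base)
        s2, _, _ = sw.minmax_scale(transformed)
        np.testing.assert_allclose(
            s1.frame["EDA_Mean"].to_numpy(), s2.frame["EDA_Mean"].to_numpy(), atol=1e-9
        )
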