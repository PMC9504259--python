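import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from emgfusion.time_features import (
    FEATURE_ORDER,
    FeatureSequence,
    FramingScheme,
    build_feature_sequence,
    feat_mav,
    feat_mavs,
    feat_ssc,
    feat_wl,
    feat_zc,
    frame_signal,
)

from conftest import make_record


class TestFraming:
    @pytest.mark.parametrize(
        "n,window,overlap,expected_s",
        [(640, 85, 12, 9), (1500, 200, 30, 9), (10, 5, 0, 2)],
    )
    def test_frame_count(self, n, window, overlap, expected_s):
        assert FramingScheme(window, overlap).frame_count(n) == expected_s

    def test_disjoint_tiling_reproduces_signal(self, rng):
        x = rng.standard_normal(10)
        w = frame_signal(x, FramingScheme(5, 0))
        np.testing.assert_array_equal(np.concatenate(w), x)

    def test_windows_match_brute_force_lister(self, rng):
        for n, L, V in [(7, 4, 2), (640, 85, 12), (23, 7, 3), (30, 30, 29)]:
            x = rng.standard_normal(n)
            got = frame_signal(x, FramingScheme(L, V))
            expected = np.array(oracles.bf_windows(list(x), L, V))
            np.testing.assert_allclose(got, expected)

    def test_trailing_window_zero_padded(self):
        w = frame_signal(np.arange(1.0, 8.0), FramingScheme(4, 2))
        assert w.shape == (4, 4)
        np.testing.assert_array_equal(w[3], [7.0, 0.0, 0.0, 0.0])

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(10), FramingScheme(11, 0))

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            FramingScheme(10, 10)
        with pytest.raises(ValueError):
            FramingScheme(10, -1)


class TestFeatureExamples:
    def test_mav(self):
        assert feat_mav([1, -1, 2, -2]) == 1.5
        assert feat_mav(np.zeros(8)) == 0.0
        assert feat_mav([-3.0] * 5) == 3.0

    def test_mavs(self):
        np.testing.assert_allclose(feat_mavs([2.0, 3.5]), [1.5, 0.0])
        np.testing.assert_allclose(feat_mavs([4.0, 4.0, 4.0]), [0.0, 0.0, 0.0])
        np.testing.assert_allclose(feat_mavs([1.0, 4.0, 2.0]), [3.0, -2.0, 0.0])

    def test_zc(self):
        assert feat_zc([0.5, -0.5, 0.5]) == 2
        assert feat_zc([0.004, -0.004]) == 0  # step 0.008 below threshold
        assert feat_zc([0.1, 0.2, 0.3]) == 0
        assert feat_zc([0.0, -0.5, 0.5]) == 1  # exact zero starts no crossing

    def test_ssc(self):
        assert feat_ssc([0, 1, 0, 1, 0]) == 3
        assert feat_ssc([0, 1, 2, 3]) == 0
        assert feat_ssc([0, 0.005, 0]) == 0  # sub-threshold extremum

    def test_wl(self):
        assert feat_wl([0, 1, 0, 1]) == 3.0
        assert feat_wl([2.0] * 6) == 0.0


class TestFeatureOracle:
    """Each feature must match the literal brute-force formula evaluation."""

    def _random_windows(self, count, rng):
        for _ in range(count):
            n = rng.integers(3, 13)
            # integer-grid values scaled near the 0.01 threshold plus plain values
            if rng.random() < 0.5:
                yield list(rng.integers(-3, 4, size=n) * 0.005)
            else:
                yield list(np.round(rng.standard_normal(n), 3))

    def test_against_brute_force(self, rng):
        for w in self._random_windows(1200, rng):
            assert feat_mav(w) == pytest.approx(oracles.bf_mav(w))
            assert feat_wl(w) == pytest.approx(oracles.bf_wl(w))
            assert feat_zc(w) == oracles.bf_zc(w)
            assert feat_ssc(w) == oracles.bf_ssc(w)
        mavs = [oracles.bf_mav(w) for w in self._random_windows(50, rng)]
        np.testing.assert_allclose(feat_mavs(mavs), oracles.bf_mavs(mavs))


float_windows = st.lists(
    st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=3, max_size=12
)


class TestFeatureProperties:
    @settings(derandomize=True, max_examples=200)
    @given(w=float_windows, c=st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_mav_wl_absolutely_homogeneous(self, w, c):
        w = np.asarray(w)
        assert feat_mav(c * w) == pytest.approx(abs(c) * feat_mav(w), abs=1e-9)
        assert feat_wl(c * w) == pytest.approx(abs(c) * feat_wl(w), abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(w=float_windows)
    def test_zc_ssc_sign_flip_invariant(self, w):
        w = np.asarray(w)
        assert feat_zc(-w) == feat_zc(w)
        assert feat_ssc(-w) == feat_ssc(w)

    @settings(derandomize=True, max_examples=100)
    @given(w=float_windows)
    def test_wl_dominates_endpoint_gap(self, w):
        assert feat_wl(w) >= abs(w[-1] - w[0]) - 1e-12


class TestFeatureSequence:
    @pytest.mark.parametrize(
        "channels,n,window,overlap,expected",
        [(8, 640, 85, 12, (5, 72)), (2, 1500, 200, 30, (5, 18))],
    )
    def test_printed_shapes(self, rng, channels, n, window, overlap, expected):
        rec = make_record(rng.standard_normal((channels, n)))
        seq = build_feature_sequence(rec, FramingScheme(window, overlap))
        assert seq.shape == expected

    def test_zero_record_gives_zero_matrix(self):
        rec = make_record(np.zeros((3, 100)))
        seq = build_feature_sequence(rec, FramingScheme(20, 5))
        np.testing.assert_array_equal(seq.values, 0.0)

    def test_channel_major_layout(self, rng):
        sig = rng.standard_normal((2, 100))
        rec = make_record(sig)
        scheme = FramingScheme(25, 5)
        seq = build_feature_sequence(rec, scheme)
        solo = build_feature_sequence(make_record(sig[1:2]), scheme)
        S = scheme.frame_count(100)
        np.testing.assert_array_equal(seq.values[:, S:], solo.values)

    def test_integer_rows_and_nonnegativity(self, rng):
        rec = make_record(rng.standard_normal((2, 200)))
        seq = build_feature_sequence(rec, FramingScheme(50, 10))
        names = dict(zip(FEATURE_ORDER, seq.values))
        assert np.all(names["MAV"] >= 0) and np.all(names["WL"] >= 0)
        for row in (names["ZC"], names["SSC"]):
            assert np.all(row >= 0) and np.all(row == np.round(row))

    @settings(derandomize=True, max_examples=50)
    @given(
        m=st.integers(1, 4),
        n=st.integers(30, 200),
        L=st.integers(5, 30),
        V=st.integers(0, 4),
    )
    def test_column_count_formula(self, m, n, L, V):
        if not (V < L <= n):
            return
        rec = make_record(np.ones((m, n)))
        seq = build_feature_sequence(rec, FramingScheme(L, V))
        assert seq.shape[1] == int(np.ceil(n / (L - V))) * m

    def test_csv_roundtrip(self, tmp_path, rng):
        rec = make_record(rng.standard_normal((2, 100)))
        seq = build_feature_sequence(rec, FramingScheme(25, 5))
        seq.write_csv(tmp_path / "seq.csv")
        back = FeatureSequence.read_csv(tmp_path / "seq.csv")
        np.testing.assert_allclose(back.values, seq.values)
        assert (back.n_segments, back.n_channels) == (seq.n_segments, seq.n_channels)
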