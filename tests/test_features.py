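"""Feature extraction: window geometry, time-domain features, the
preprocessing protocol (split / subsample / standardize)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semgmoe.features import (FeatureDataset, Standardizer, WindowConfig,
                              extract_features, filt_features, mav, n_windows,
                              prepare_datasets, rms, sliding_windows,
                              split_by_repetition, standardize, subsample_rows,
                              window_last_indices, wl)


def brute_force_window_count(T, length, inc):
    """Enumeration oracle: count start offsets whose window fits in T."""
    return sum(1 for s in range(0, T, inc) if s + length <= T and s % inc == 0)


class TestWindows:
    @pytest.mark.parametrize(
        "T,length,inc,expected",
        [(2000, 800, 20, 61), (800, 800, 20, 1), (2400, 800, 800, 3)])
    def test_window_counts(self, T, length, inc, expected):
        assert n_windows(T, length, inc) == expected

    def test_window_content_and_labels(self):
        cfg = WindowConfig(fs=10.0, window_len=4, increment=2)
        x = np.arange(10.0)
        w = sliding_windows(x, cfg)
        assert w.shape == (4, 4)
        np.testing.assert_array_equal(w[1], [2, 3, 4, 5])
        np.testing.assert_array_equal(window_last_indices(10, cfg), [3, 5, 7, 9])

    def test_too_short_series_raises(self):
        cfg = WindowConfig(fs=10.0, window_len=8, increment=2)
        with pytest.raises(ValueError, match="shorter than window"):
            sliding_windows(np.arange(5.0), cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(fs=10.0, window_len=4, increment=5)
        with pytest.raises(ValueError):
            WindowConfig(fs=10.0, window_len=0, increment=1)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(T=st.integers(1, 100), length=st.integers(1, 20),
           data=st.data())
    def test_count_formula_matches_enumeration(self, T, length, data):
        inc = data.draw(st.integers(1, length))
        if T < length:
            with pytest.raises(ValueError):
                n_windows(T, length, inc)
        else:
            assert n_windows(T, length, inc) == brute_force_window_count(T, length, inc)


class TestTimeDomainFeatures:
    def test_hand_computed_values(self):
        np.testing.assert_allclose(mav(np.array([1.0, -1, 2, -2])), 1.5)
        np.testing.assert_allclose(wl(np.array([0.0, 1, 3])), 3.0)
        np.testing.assert_allclose(wl(np.array([0.0, 1, 0, 1])), 3.0)
        np.testing.assert_allclose(rms(np.array([3.0, -4])), np.sqrt(12.5))

    def test_degenerate_windows(self):
        zeros = np.zeros(5)
        assert mav(zeros) == 0 and rms(zeros) == 0 and wl(zeros) == 0
        const = np.full(5, -2.5)
        assert mav(const) == 2.5 and rms(const) == 2.5 and wl(const) == 0

    def test_empty_or_short_windows_raise(self):
        with pytest.raises(ValueError):
            mav(np.array([]))
        with pytest.raises(ValueError):
            wl(np.array([1.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(c=st.floats(-50, 50, allow_nan=False),
           seed=st.integers(0, 2**16))
    def test_scale_equivariance(self, c, seed):
        """features(c x) = |c| features(x) for MAV, WL and RMS."""
        x = np.random.default_rng(seed).normal(size=16)
        for f in (mav, wl, rms):
            np.testing.assert_allclose(f(c * x), abs(c) * f(x), atol=1e-9)


class TestFiltFeature:
    def test_dc_gain_unity(self):
        x = np.full(4000, 1.7)
        out, idx = filt_features(x, fs=1000.0, subsample=200)
        np.testing.assert_allclose(out, 1.7, rtol=1e-6)
        np.testing.assert_array_equal(idx, np.arange(0, 4000, 200))

    def test_zero_in_zero_out(self):
        out, _ = filt_features(np.zeros(2000), fs=1000.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_sinusoid_envelope_mean(self):
        """Rectified 50 Hz sine smooths to its mean level 2A/pi, ripple < 5%."""
        fs, A = 2000.0, 3.0
        t = np.arange(int(4 * fs)) / fs
        x = A * np.sin(2 * np.pi * 50 * t)
        out, _ = filt_features(x, fs=fs, cutoff=2.0, subsample=200)
        # a 2 Hz filter's edge transient spans ~0.5 s; keep 1 s margins
        mid = out[10:-10].ravel()
        expect = 2 * A / np.pi
        assert np.abs(mid.mean() - expect) / expect < 0.01
        assert np.abs(mid - expect).max() / expect < 0.05

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="warm-up"):
            filt_features(np.ones(5), fs=1000.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="twice the cutoff"):
            filt_features(np.ones(100), fs=3.0, cutoff=2.0)


def _toy_dataset(n=60, reps=(1, 2, 3, 4, 5, 6)):
    rng = np.random.default_rng(1)
    rep = np.repeat(reps, n // len(reps))
    return FeatureDataset(X=rng.normal(size=(n, 3)), Y=rng.normal(size=(n, 2)),
                          movement=np.ones(n, dtype=int), repetition=rep)


class TestSplitSubsampleStandardize:
    def test_default_split_holds_out_reps_2_and_5(self):
        ds = _toy_dataset()
        train, test = split_by_repetition(ds)
        assert set(np.unique(train.repetition)) == {1, 3, 4, 6}
        assert set(np.unique(test.repetition)) == {2, 5}
        assert train.n_samples + test.n_samples == ds.n_samples

    def test_empty_test_side_warns(self):
        ds = _toy_dataset()
        with pytest.warns(UserWarning, match="empty side"):
            train, test = split_by_repetition(ds, test_reps=set())
        assert test.n_samples == 0
        assert train.n_samples == ds.n_samples

    def test_subsample_rows(self):
        ds = _toy_dataset(n=3000, reps=(1,))
        assert subsample_rows(ds, 1).n_samples == 3000
        sub = subsample_rows(ds, 10)
        assert sub.n_samples == 300
        np.testing.assert_array_equal(sub.X, ds.X[::10])
        np.testing.assert_array_equal(sub.repetition, ds.repetition[::10])
        with pytest.raises(ValueError):
            subsample_rows(ds, 0)

    def test_standardize_train_statistics_only(self):
        train = np.array([[0.0, 10.0], [2.0, 30.0]])
        test = np.array([[4.0, 50.0]])
        tr, te, sc = standardize(train, test)
        np.testing.assert_allclose(tr[:, 0], [-1.0, 1.0])
        assert tr.mean(axis=0) == pytest.approx(0.0, abs=1e-9)
        assert tr.std(axis=0) == pytest.approx(1.0, abs=1e-9)
        assert not np.allclose(te.mean(axis=0), 0.0)  # train stats applied
        np.testing.assert_allclose(sc.inverse_transform(te), test, atol=1e-12)

    def test_zero_variance_column_named(self):
        bad = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match=r"\[0\]"):
            Standardizer().fit(bad)


class TestExtractFeatures:
    def test_windows_never_straddle_mask_runs(self):
        rng = np.random.default_rng(2)
        emg = rng.normal(size=(300, 2))
        force = rng.normal(size=(300, 1))
        stim = np.zeros(300, int)
        rep = np.ones(300, int)
        mask = np.ones(300, bool)
        mask[100:150] = False  # two runs: 100 and 150 long
        cfg = WindowConfig(fs=100.0, window_len=40, increment=10)
        ds = extract_features(emg, force, stim, rep, fe="rms", cfg=cfg,
                              row_mask=mask)
        assert ds.n_samples == n_windows(100, 40, 10) + n_windows(150, 40, 10)

    def test_full_protocol_shapes_and_standardization(self):
        rng = np.random.default_rng(3)
        T = 4000
        emg = rng.normal(size=(T, 3)) * (1 + (np.arange(T) % 1000 < 500))[:, None]
        force = rng.normal(size=(T, 2))
        stim = (np.arange(T) // 500) % 2
        rep = 1 + (np.arange(T) * 6) // T
        cfg = WindowConfig(fs=1000.0, window_len=100, increment=20)
        train, test, raw_sc, feat_sc = prepare_datasets(
            emg, force, stim, rep, fe="mav", cfg=cfg, test_reps={2, 5},
            train_subsample=2)
        assert train.X.shape[1] == 3 and train.Y.shape[1] == 2
        np.testing.assert_allclose(train.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(train.X.std(axis=0), 1.0, atol=1e-9)
        assert set(np.unique(test.repetition)) <= {2, 5}
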