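import numpy as np
import pandas as pd
import pytest
from scipy.signal import lfilter

from msdeeg import features as ft
from msdeeg.segmentation import SegmentSet, segment_recording

from conftest import make_recording, sinusoid


def make_segment_set(trials, channels=None, fs=500.0):
    trials = np.asarray(trials, dtype=float)
    n = trials.shape[0]
    if channels is None:
        channels = [f"Fp{i + 1}" for i in range(trials.shape[1])][:2] or ["Fp1"]
        from msdeeg.signal_io import CANONICAL_CHANNELS
        channels = list(CANONICAL_CHANNELS[: trials.shape[1]])
    labels = pd.DataFrame({"subject_id": ["S01"] * n, "state": ["rest"] * n,
                           "group": ["low_stress"] * n})
    return SegmentSet(trials=trials, channels=channels, fs=fs, window_s=4.0,
                      stride_s=1.0, labels=labels)


def stable_ar6():
    """AR(6) coefficients from poles well inside the unit circle."""
    poles = [0.7 * np.exp(1j * 0.4), 0.7 * np.exp(-1j * 0.4),
             0.6 * np.exp(1j * 1.5), 0.6 * np.exp(-1j * 1.5), 0.5, -0.4]
    poly = np.real(np.poly(poles))  # 1, -a1, ..., -a6
    return -poly[1:]


class TestSpectrum:
    def test_pure_tone_peaks_at_its_bin(self):
        spec = ft.estimate_spectrum(sinusoid(25.0), fs=500.0)
        assert spec.freqs[np.argmax(spec.amp)] == pytest.approx(25.0)
        assert spec.amp.max() == pytest.approx(1.0, rel=1e-6)

    def test_parseval_on_alternating_signal(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        spec = ft.estimate_spectrum(x, fs=4.0)
        assert spec.pk.sum() == pytest.approx(4.0, rel=1e-12)

    def test_all_zero_trial_gives_zero_spectra(self):
        spec = ft.estimate_spectrum(np.zeros(64), fs=500.0)
        assert spec.psd.sum() == 0 and spec.amp.sum() == 0

    def test_nonfinite_samples_rejected(self):
        x = np.zeros(64)
        x[3] = np.nan
        with pytest.raises(ft.DataError):
            ft.estimate_spectrum(x, fs=500.0)

    def test_parseval_identity_on_random_trials(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=rng.integers(64, 512))
            spec = ft.estimate_spectrum(x, fs=500.0)
            assert spec.pk.sum() == pytest.approx((x**2).sum(), rel=1e-6)


class TestFrequencyFeatures:
    def test_point_mass_spectrum(self):
        x = sinusoid(25.0)
        mdf, mfmd, *_ = ft.frequency_features(ft.estimate_spectrum(x, 500.0))
        assert mdf == pytest.approx(25.0)
        assert mfmd == pytest.approx(25.0)

    def test_flat_psd_median_at_half_bin(self):
        freqs = np.arange(101.0)
        psd = np.zeros(101)
        psd[1:] = 1.0  # flat over bins 1..100
        spec = ft.SpectrumEstimate(freqs=freqs, psd=psd, amp=psd.copy(),
                                   pk=psd.copy(), fs=202.0, n=202)
        mdf, mfmd, *_ = ft.frequency_features(spec)
        assert mdf == 50.0 and mfmd == 50.0

    def test_half_mass_matches_brute_force_on_random_spectra(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            w = rng.uniform(size=rng.integers(10, 200))
            freqs = np.arange(w.size, dtype=float)
            expected = next(f for f in range(w.size)
                            if w[: f + 1].sum() >= 0.5 * w.sum())
            spec = ft.SpectrumEstimate(freqs=freqs, psd=w, amp=w, pk=w,
                                       fs=2.0 * w.size, n=2 * w.size)
            mdf, mfmd, *_ = ft.frequency_features(spec)
            assert mdf == expected == mfmd

    def test_m0_of_alternating_signal(self):
        spec = ft.estimate_spectrum(np.array([1.0, -1.0, 1.0, -1.0]), fs=4.0)
        _, _, m0, _, _ = ft.frequency_features(spec)
        assert m0 == pytest.approx(2.0, rel=1e-12)

    def test_all_zero_spectrum_is_undefined(self):
        spec = ft.estimate_spectrum(np.zeros(64), fs=500.0)
        with pytest.raises(ft.DataError):
            ft.frequency_features(spec)

    def test_root_toggle_squares_moments(self):
        spec = ft.estimate_spectrum(np.random.default_rng(8).normal(size=256),
                                    fs=500.0)
        _, _, m0r, m2r, m4r = ft.frequency_features(spec, root_moments=True)
        _, _, m0, m2, m4 = ft.frequency_features(spec, root_moments=False)
        assert m0 == pytest.approx(m0r**2) and m2 == pytest.approx(m2r**2)
        assert m4 == pytest.approx(m4r**2)


class TestTimeFeatures:
    def test_rms_of_constant(self):
        rms, *_ = ft.time_features(np.full(100, 3.0))
        assert rms == pytest.approx(3.0)

    def test_rms_hand_case(self):
        # mean of squares of 1,2,3,4 is 7.5; tiling preserves it while
        # satisfying the AR fit's minimum length
        x = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        rms, *_ = ft.time_features(x)
        assert rms == pytest.approx(np.sqrt(7.5), rel=1e-12)

    def test_ar6_simulate_and_refit_recovery(self):
        a_true = stable_ar6()
        rng = np.random.default_rng(123)
        e = rng.normal(size=100_000)
        x = lfilter([1.0], np.concatenate([[1.0], -a_true]), e)
        _, *a_hat = ft.time_features(x)
        np.testing.assert_allclose(a_hat, a_true, atol=0.05)

    def test_burg_also_recovers_coefficients(self):
        a_true = stable_ar6()
        rng = np.random.default_rng(12)
        e = rng.normal(size=50_000)
        x = lfilter([1.0], np.concatenate([[1.0], -a_true]), e)
        _, *a_hat = ft.time_features(x, ar_method="burg")
        np.testing.assert_allclose(a_hat, a_true, atol=0.05)

    def test_yule_walker_matches_statsmodels(self):
        from statsmodels.regression.linear_model import yule_walker

        rng = np.random.default_rng(5)
        x = rng.normal(size=4000)
        _, *a_hat = ft.time_features(x)
        rho, _ = yule_walker(x, order=6, method="mle", demean=True)
        np.testing.assert_allclose(a_hat, rho, atol=1e-8)

    def test_constant_signal_degenerates_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            _, *a_hat = ft.time_features(np.full(100, 3.0))
        assert a_hat == [0.0] * 6

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            ft.time_features(np.zeros(6))


class TestFeatureMatrix:
    @pytest.mark.parametrize("n_ch,set_tag,expected", [
        (19, "set3", 228), (19, "set1", 95), (19, "set2", 133),
        (2, "set3", 24),
    ])
    def test_column_counts(self, n_ch, set_tag, expected):
        rng = np.random.default_rng(0)
        segs = make_segment_set(rng.normal(size=(3, n_ch, 256)))
        fm = ft.build_feature_matrix(segs, set_tag)
        assert len(fm.feature_names) == expected
        assert fm.n_trials == 3

    def test_set3_is_concatenation_of_set1_and_set2(self):
        rng = np.random.default_rng(1)
        segs = make_segment_set(rng.normal(size=(4, 3, 256)))
        fm1 = ft.build_feature_matrix(segs, "set1")
        fm2 = ft.build_feature_matrix(segs, "set2")
        fm3 = ft.build_feature_matrix(segs, "set3")
        for col in fm1.feature_names:
            np.testing.assert_array_equal(fm3.data[col], fm1.data[col])
        for col in fm2.feature_names:
            np.testing.assert_array_equal(fm3.data[col], fm2.data[col])
        assert set(fm3.feature_names) == set(fm1.feature_names) | set(fm2.feature_names)

    def test_scaling_behaviour(self):
        rng = np.random.default_rng(2)
        trials = rng.normal(size=(3, 2, 256))
        fm = ft.build_feature_matrix(make_segment_set(trials), "set3")
        fm_scaled = ft.build_feature_matrix(make_segment_set(5.0 * trials), "set3")
        for col in fm.feature_names:
            feat = col.split("__")[1]
            if feat in ("rms", "m0", "m2", "m4"):
                np.testing.assert_allclose(fm_scaled.data[col],
                                           5.0 * fm.data[col], rtol=1e-8)
            else:  # mdf, mfmd, ar coefficients are scale-free
                np.testing.assert_allclose(fm_scaled.data[col], fm.data[col],
                                           rtol=1e-8, atol=1e-10)

    def test_batch_matches_per_trial_ops(self):
        rng = np.random.default_rng(3)
        segs = make_segment_set(rng.normal(size=(2, 2, 300)))
        fm = ft.build_feature_matrix(segs, "set3")
        for ti in range(2):
            for ci, ch in enumerate(segs.channels):
                x = segs.trials[ti, ci]
                mdf, mfmd, m0, m2, m4 = ft.frequency_features(
                    ft.estimate_spectrum(x, segs.fs))
                rms, *ar = ft.time_features(x)
                row = fm.data.iloc[ti]
                np.testing.assert_allclose(
                    [row[f"{ch}__{f}"] for f in ft.SET3_FEATURES],
                    [mdf, mfmd, m0, m2, m4, rms, *ar], rtol=1e-9, atol=1e-12)

    def test_select_channels_equals_rebuild(self):
        rng = np.random.default_rng(4)
        segs = make_segment_set(rng.normal(size=(3, 4, 256)))
        fm = ft.build_feature_matrix(segs, "set3")
        sub_cols = fm.select_channels(["F3", "Fp1"])
        sub_rebuilt = ft.build_feature_matrix(
            segs.select_channels(["F3", "Fp1"]), "set3")
        assert sub_cols.feature_names == sub_rebuilt.feature_names
        np.testing.assert_array_equal(sub_cols.values, sub_rebuilt.values)

    def test_labels_copied_through(self):
        rec = make_recording(np.random.default_rng(5).normal(size=(2, 3000)),
                             state="task", group="high_stress", subject_id="S09")
        fm = ft.build_feature_matrix(segment_recording(rec))
        assert (fm.labels["subject_id"] == "S09").all()
        assert (fm.labels["state"] == "task").all()

    def test_empty_segment_set_rejected(self):
        segs = make_segment_set(np.zeros((1, 2, 256)))
        segs.trials = segs.trials[:0]
        segs.labels = segs.labels.iloc[:0]
        with pytest.raises(ValueError):
            ft.build_feature_matrix(segs)

    def test_extractor_wrapper_matches_function(self):
        rng = np.random.default_rng(6)
        segs = make_segment_set(rng.normal(size=(2, 2, 256)))
        a = ft.FeatureExtractor("set1").fit().transform(segs)
        b = ft.build_feature_matrix(segs, "set1")
        np.testing.assert_array_equal(a.values, b.values)
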