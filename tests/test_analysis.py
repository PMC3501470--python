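"""Filtering, block averaging, spectra, laterality and correlation tools."""
import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats

from hemosplit.analysis import (
    amplitude_spectrum,
    attenuation_ratio_profile,
    block_average,
    component_correlation,
    downsample,
    find_spectral_peak,
    laterality_ttest,
    lowpass_filter,
)
from hemosplit.core import BlockDesign, Epoch, HemoSignal


def tone(freq, fs, duration):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, 10.0, 1.0), x, atol=1e-6)

    def test_stopband_attenuation_matches_analytic_response(self):
        # oracle: |H(f)|^2 of the forward-backward 4th-order Butterworth
        fs, f0 = 10.0, 3.0
        x = tone(f0, fs, 100.0)
        y = lowpass_filter(x, fs, 1.0)
        sos = sps.butter(4, 1.0, btype="low", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[f0], fs=fs)
        expected_gain = np.abs(h[0]) ** 2  # squared: applied twice
        measured = y[300:-300].std() / x[300:-300].std()
        assert measured == pytest.approx(expected_gain, rel=0.05)
        assert measured < 0.1  # attenuated at least 10x

    def test_passband_tone_preserved(self):
        fs = 10.0
        x = tone(0.05, fs, 400.0)
        y = lowpass_filter(x, fs, 1.0)
        assert y.std() == pytest.approx(x.std(), rel=0.05)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(np.zeros(100), 10.0, 5.0)


class TestDownsample:
    def test_forty_to_ten_quarters_length(self):
        x = np.sin(np.arange(4000) * 0.01)
        y = downsample(x, 40.0, 10.0)
        assert abs(y.size - 1000) <= 1

    def test_identity_ratio(self):
        x = np.arange(50.0)
        np.testing.assert_array_equal(downsample(x, 10.0, 10.0), x)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            downsample(np.zeros(100), 10.0, 7.0)

    def test_commutes_with_scaling(self):
        x = np.sin(np.arange(2000) * 0.03)
        np.testing.assert_allclose(downsample(3.0 * x, 40.0, 10.0),
                                   3.0 * downsample(x, 40.0, 10.0), atol=1e-12)


class TestBlockAverage:
    def make_design(self, n_epochs=5):
        epochs = []
        t = 0.0
        for _ in range(n_epochs):
            epochs.append(Epoch("task", t, 20.0)); t += 20.0
            epochs.append(Epoch("rest", t, 20.0)); t += 20.0
        return BlockDesign(tuple(epochs), t)

    def test_identical_epochs_average_to_epoch_with_zero_sd(self):
        design = self.make_design()
        fs = 10.0
        template = np.sin(np.arange(400) * 0.05)
        hbo = np.tile(template, 5)
        sig = HemoSignal(fs, hbo, -0.6 * hbo)
        ba = block_average(sig, design, epoch_window=40.0, baseline="none")
        assert ba.n_trials == 5
        np.testing.assert_allclose(ba.hbo_mean, template, atol=1e-12)
        np.testing.assert_allclose(ba.hbo_sd, 0.0, atol=1e-12)

    def test_single_epoch_mean_is_epoch_sd_zero(self):
        design = BlockDesign((Epoch("task", 0.0, 20.0),), 20.0)
        hbo = np.arange(200.0)
        sig = HemoSignal(10.0, hbo, hbo)
        ba = block_average(sig, design, epoch_window=20.0, baseline="none")
        assert ba.n_trials == 1
        np.testing.assert_array_equal(ba.hbo_mean, hbo)
        assert np.all(ba.hbo_sd == 0)

    def test_onset_baseline_anchors_trials_at_zero(self):
        design = self.make_design()
        rng = np.random.default_rng(1)
        hbo = rng.normal(size=2000) + 5.0
        sig = HemoSignal(10.0, hbo, hbo)
        ba = block_average(sig, design)
        assert ba.hbo_mean[0] == 0.0

    def test_no_matching_epochs_rejected(self):
        design = BlockDesign((Epoch("rest", 0.0, 20.0),), 20.0)
        sig = HemoSignal(10.0, np.zeros(200), np.zeros(200))
        with pytest.raises(ValueError, match="no matching epoch"):
            block_average(sig, design)

    def test_recovers_truth_block_average_on_synthetic_session(self, default_session):
        from hemosplit.separation import ModalityCoefficients, separate_components

        cfg = default_session.config
        pair = separate_components(
            default_session.observed["Left"],
            ModalityCoefficients(cfg.k_f_true, cfg.k_s_true))
        ba_rec = block_average(pair.functional, default_session.design,
                               labels="task_right")
        ba_true = block_average(default_session.truth["Left"].functional,
                                default_session.design, labels="task_right")
        r = np.corrcoef(ba_rec.hbo_mean, ba_true.hbo_mean)[0, 1]
        assert r > 0.95


class TestSpectrum:
    def test_pure_tone_peaks_at_nearest_bin(self):
        fs = 10.0
        spec = amplitude_spectrum(tone(1.5, fs, 200.0), fs)
        peak = find_spectral_peak(spec, (1.0, 2.0))
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - 1.5) <= df / 2

    def test_constant_series_spectrum_is_null(self):
        spec = amplitude_spectrum(np.full(256, 2.0), 10.0)
        assert np.all(spec.magnitude < 1e-9)

    def test_two_tone_sum_produces_two_local_maxima(self):
        fs = 10.0
        x = tone(0.025, fs, 400.0) + 0.5 * tone(1.5, fs, 400.0)
        spec = amplitude_spectrum(x, fs)
        lo = find_spectral_peak(spec, (0.01, 0.1))
        hi = find_spectral_peak(spec, (1.0, 2.0))
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(lo - 0.025) <= df / 2
        assert abs(hi - 1.5) <= df / 2

    def test_band_excluding_tone_warns_low_prominence(self, caplog):
        fs = 10.0
        rng = np.random.default_rng(0)
        x = tone(1.5, fs, 200.0) + 0.01 * rng.normal(size=2000)
        spec = amplitude_spectrum(x, fs)
        with caplog.at_level("WARNING"):
            find_spectral_peak(spec, (3.0, 4.0))
        assert any("prominence" in r.message for r in caplog.records)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            amplitude_spectrum(np.zeros(8), 10.0)

    def test_empty_band_rejected(self):
        spec = amplitude_spectrum(np.random.default_rng(0).normal(size=64), 10.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            find_spectral_peak(spec, (4.9, 4.91))


def lateral_design():
    epochs = [Epoch("rest", 0.0, 20.0)]
    t = 20.0
    for _ in range(5):
        for label in ("task_left", "rest", "task_right", "rest"):
            epochs.append(Epoch(label, t, 20.0)); t += 20.0
    return BlockDesign(tuple(epochs), t, 20.0)


def signal_with_window_means(design, left_vals, right_vals, fs=10.0):
    """Constant-by-epoch HbO such that task-minus-rest window means are given."""
    n = int(design.session_length * fs)
    hbo = np.zeros(n)
    for side, vals in (("task_left", left_vals), ("task_right", right_vals)):
        for ep, v in zip(design.select(side), vals):
            s = int(ep.onset * fs)
            e = int(ep.end * fs)
            hbo[s:e] = v
    return HemoSignal(fs, hbo, -0.6 * hbo)


class TestLateralityTTest:
    def test_symmetric_responses_give_zero_t(self):
        design = lateral_design()
        sig = signal_with_window_means(design, [1, 2, 3, 2, 1], [1, 2, 3, 2, 1])
        res = laterality_ttest(sig, design)
        assert res.t == pytest.approx(0.0, abs=1e-12)

    def test_constant_nonzero_differences_flag_undefined_t(self, caplog):
        design = lateral_design()
        sig = signal_with_window_means(design, [0, 0, 0, 0, 0], [1, 1, 1, 1, 1])
        with caplog.at_level("WARNING"):
            res = laterality_ttest(sig, design)
        assert res.undefined
        assert res.df == 4

    def test_matches_hand_evaluated_paired_t_and_scipy(self):
        design = lateral_design()
        left = [0.0, 0.0, 0.0, 0.0, 0.0]
        right = [2.0, 1.0, 2.0, 1.0, 2.0]
        sig = signal_with_window_means(design, left, right)
        res = laterality_ttest(sig, design)
        d = np.array(left) - np.array(right)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(t_hand, abs=1e-9)
        t_sp, p_sp = stats.ttest_rel(left, right)
        assert res.t == pytest.approx(t_sp, abs=1e-9)
        assert res.p == pytest.approx(p_sp, abs=1e-12)
        np.testing.assert_allclose(res.left_values, left, atol=1e-9)
        np.testing.assert_allclose(res.right_values, right, atol=1e-9)

    def test_unequal_trial_counts_rejected(self):
        design = lateral_design()
        trimmed = BlockDesign(design.epochs[:-2], design.session_length,
                              design.initial_rest)
        sig = signal_with_window_means(design, np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="unequal"):
            laterality_ttest(sig, trimmed)


class TestComponentCorrelation:
    def test_proportional_series(self, rng):
        b = rng.normal(size=100)
        r, scale = component_correlation(2.0 * b, b)
        assert r == pytest.approx(1.0)
        assert scale == pytest.approx(2.0)

    def test_orthogonal_series_scale_zero(self):
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        a, b = np.sin(t), np.cos(t)
        _, scale = component_correlation(a, b)
        assert scale == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_covariance_formula(self, rng):
        a = rng.normal(size=200)
        b = 0.3 * a + rng.normal(size=200)
        r, scale = component_correlation(a, b)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        r_direct = cov / (a.std() * b.std())
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert scale == pytest.approx(np.dot(a, b) / np.dot(b, b), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            component_correlation(np.ones(10), np.arange(10.0))


class TestAttenuationRatioProfile:
    def test_scaled_copies_recover_factors(self, rng):
        ref = rng.normal(size=500)
        factors = {10.0: 0.2, 20.0: 0.6, 30.0: 1.0, 40.0: 1.3}
        series = {d: f * ref for d, f in factors.items()}
        ratios = attenuation_ratio_profile(series, 30.0)
        for d, f in factors.items():
            assert ratios[d] == pytest.approx(f, abs=1e-12)
        assert ratios[30.0] == 1.0

    def test_noisy_scaled_copies_within_five_percent(self, rng):
        ref = rng.normal(size=2000)
        factors = {10.0: 0.2, 20.0: 0.6, 30.0: 1.0, 40.0: 1.3}
        series = {d: f * ref + 0.1 * f * rng.normal(size=2000)  # SNR 10
                  for d, f in factors.items()}
        ratios = attenuation_ratio_profile(series, 30.0)
        for d, f in factors.items():
            assert ratios[d] == pytest.approx(f, rel=0.05)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            attenuation_ratio_profile({10.0: np.ones(5)}, 30.0)
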