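"""Cardiac metric computations: R-peaks, RMSSD, band power, windows."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvfc.cardiac import (RRSeries, bandpass_ecg, detect_r_peaks,
                           instantaneous_hr, interpolate_outliers,
                           normalized_band_power, orthogonalize, rmssd,
                           sliding_metrics)
from hrvfc.simulate import SimConfig, gen_ecg_trace, gen_rr_series

from conftest import constant_rr


def dft_band_fractions(rr: RRSeries):
    """Independent oracle: raw periodogram of the 10-Hz-resampled
    successive-difference series, rectangle-integrated over the bands."""
    diffs = np.diff(rr.rr)
    times = rr.rr_times[1:]
    fs = 10.0
    grid = rr.beat_times[0] + np.arange(int((rr.beat_times[-1] - rr.beat_times[0]) * fs)) / fs
    x = np.interp(grid, times, diffs)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    tot = spec[(freqs >= 0.04) & (freqs < 0.50)].sum()
    lf = 100 * spec[(freqs >= 0.04) & (freqs < 0.15)].sum() / tot
    hf = 100 * spec[(freqs >= 0.15) & (freqs < 0.40)].sum() / tot
    return lf, hf


class TestRRSeries:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RRSeries(np.array([0.0, 1.0, 0.5]), np.array([1000.0, -500.0]))
        with pytest.raises(ValueError):
            RRSeries(np.array([0.0, 1.0]), np.array([1000.0, 1000.0]))

    def test_from_beat_times(self):
        rr = RRSeries.from_beat_times([0.0, 1.0, 2.5])
        assert np.allclose(rr.rr, [1000.0, 1500.0])


class TestRPeakDetection:
    def test_regular_train_gives_1000ms(self):
        rr_true = constant_rr(1000.0, 60.0)
        ecg = gen_ecg_trace(rr_true, fs=250.0)
        det = detect_r_peaks(ecg, fs=250.0, min_distance=0.5)
        assert np.allclose(det.rr, 1000.0, atol=10.0)

    def test_min_distance_insensitive_at_1000ms(self):
        rr_true = constant_rr(1000.0, 60.0)
        ecg = gen_ecg_trace(rr_true, fs=250.0)
        a = detect_r_peaks(ecg, fs=250.0, min_distance=0.5)
        b = detect_r_peaks(ecg, fs=250.0, min_distance=0.9)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_missing_beat_yields_long_interval_then_mad_flag(self):
        beats = list(np.arange(0, 60, 1.0))
        beats.remove(30.0)  # dropped beat -> one 2000-ms interval
        ecg = gen_ecg_trace(RRSeries.from_beat_times(beats), fs=250.0)
        det = detect_r_peaks(ecg, fs=250.0, min_distance=0.5)
        long_rr = det.rr[np.argmax(det.rr)]
        assert long_rr == pytest.approx(2000.0, abs=20.0)
        cleaned, out = interpolate_outliers(det.rr)
        assert out.sum() == 1 and abs(cleaned[np.argmax(det.rr)] - 1000) < 20

    def test_short_or_flat_trace_errors(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(10), fs=250.0, min_distance=0.5)

    def test_bandpass_removes_baseline_drift(self):
        fs = 250.0
        t = np.arange(0, 30, 1 / fs)
        drift = 5.0 * np.sin(2 * np.pi * 0.05 * t)
        filtered = bandpass_ecg(drift, fs)
        assert np.std(filtered) < 0.05 * np.std(drift)


class TestInstantaneousHR:
    @pytest.mark.parametrize("rr_s, expected", [
        (1.0, 60.0), (0.75, 80.0), (0.95, 60.0 / 0.95),
    ])
    def test_inverse_rr_times_60(self, rr_s, expected):
        rr = constant_rr(rr_s * 1000.0, 30 * rr_s)
        assert np.allclose(instantaneous_hr(rr), expected)

    def test_resampled_to_grid(self):
        rr = constant_rr(1000.0, 30.0)
        hr = instantaneous_hr(rr, np.arange(5.0))
        assert hr.shape == (5,) and np.allclose(hr, 60.0)


class TestOutlierInterpolation:
    def test_single_spike_removed(self):
        x = [1000.0, 1000.0, 2000.0, 1000.0, 1000.0]
        cleaned, out = interpolate_outliers(x)
        assert np.allclose(cleaned, 1000.0)
        assert list(out) == [False, False, True, False, False]

    def test_no_outliers_identity(self, rng):
        # bounded jitter: max deviation 20 ms < 3 * MAD (~30 ms)
        x = 1000 + 20 * rng.uniform(-1, 1, 50)
        cleaned, out = interpolate_outliers(x)
        assert not out.any() and np.array_equal(cleaned, x)

    def test_two_adjacent_spikes_bridged(self):
        x = np.array([1000.0, 1010.0, 1900.0, 1950.0, 1020.0, 1000.0, 990.0])
        cleaned, out = interpolate_outliers(x)
        assert out[2] and out[3]
        # linear bridge between neighbours at indices 1 and 4
        expect = np.interp([2, 3], [1, 4], [1010.0, 1020.0])
        assert np.allclose(cleaned[2:4], expect)

    def test_boundary_outlier_takes_nearest_valid(self):
        x = np.array([3000.0, 1000.0, 1010.0, 990.0, 1000.0])
        cleaned, _ = interpolate_outliers(x)
        assert cleaned[0] == 1000.0

    def test_all_outliers_invalid_window(self):
        # with the default 3-MAD rule at least half the window can never be
        # flagged; force the degenerate all-flagged branch with a negative
        # threshold to verify the window is rejected rather than fabricated
        with pytest.raises(ValueError):
            interpolate_outliers([990.0, 1000.0, 1010.0], n_mad=-1.0)


class TestRMSSD:
    def test_constant_rr_zero(self):
        assert rmssd([1000.0] * 10) == 0.0

    def test_constant_difference(self):
        assert rmssd([1000.0, 1020.0, 1040.0, 1060.0]) == pytest.approx(20.0)

    def test_alternating_diffs(self):
        assert rmssd([1000.0, 1030.0, 1000.0, 1030.0]) == pytest.approx(30.0)

    def test_too_few_beats_nan(self):
        assert np.isnan(rmssd([1000.0]))

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(0.1, 10.0), seed=st.integers(0, 1000))
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = 1000 + np.cumsum(rng.standard_normal(20) * 10)
        scaled = x[0] + c * (x - x[0])  # scales all successive differences by c
        assert rmssd(scaled) == pytest.approx(c * rmssd(x), rel=1e-9)


class TestNormalizedBandPower:
    def _pure_tone_rr(self, freq, amp=40.0, duration=100.0):
        cfg = SimConfig(seed=0)
        return gen_rr_series(
            cfg, 0, baseline=1000.0, noise_sd=0.0,
            lf_amp_profile=lambda t: np.full_like(np.asarray(t, float),
                                                  amp if freq < 0.15 else 0.0),
            hf_amp_profile=lambda t: np.full_like(np.asarray(t, float),
                                                  0.0 if freq < 0.15 else amp))

    def test_pure_lf_tone(self):
        rr = self._pure_tone_rr(0.10)
        lf, hf = normalized_band_power(rr)
        lf_o, hf_o = dft_band_fractions(rr)
        assert lf == pytest.approx(100.0, abs=5.0)
        assert hf == pytest.approx(0.0, abs=5.0)
        assert lf == pytest.approx(lf_o, abs=5.0)

    def test_pure_hf_tone(self):
        rr = self._pure_tone_rr(0.30)
        lf, hf = normalized_band_power(rr)
        lf_o, hf_o = dft_band_fractions(rr)
        assert hf == pytest.approx(100.0, abs=5.0)
        assert lf == pytest.approx(0.0, abs=5.0)
        assert hf == pytest.approx(hf_o, abs=5.0)

    def test_equal_power_mixture_near_5050(self):
        # successive differencing scales a tone's amplitude by 2 sin(pi f rr)
        # and linear interpolation from ~1-s beat spacing by sinc(f)^2;
        # pre-compensate both so the two bands carry equal difference power
        def gain(f, d=1.0):
            return 2 * np.sin(np.pi * f * d) * np.sinc(f * d) ** 2

        a_lf = 5.0 / gain(0.10)
        a_hf = 5.0 / gain(0.30)
        cfg = SimConfig(seed=0)
        rr = gen_rr_series(
            cfg, 0, baseline=1000.0, noise_sd=0.0,
            lf_amp_profile=lambda t: np.full_like(np.asarray(t, float), a_lf),
            hf_amp_profile=lambda t: np.full_like(np.asarray(t, float), a_hf))
        lf, hf = normalized_band_power(rr)
        lf_o, hf_o = dft_band_fractions(rr)
        assert lf == pytest.approx(lf_o, abs=5.0)
        assert hf == pytest.approx(hf_o, abs=5.0)
        assert lf == pytest.approx(50.0, abs=10.0)
        assert hf == pytest.approx(50.0, abs=10.0)

    def test_lf_plus_hf_at_most_100(self, rng):
        beats = np.cumsum(np.abs(rng.normal(1.0, 0.05, 200)))
        lf, hf = normalized_band_power(RRSeries.from_beat_times(beats))
        assert lf + hf <= 100.0 + 1e-9
        assert 0.0 <= lf <= 100.0 and 0.0 <= hf <= 100.0

    def test_constant_rr_no_power_nan(self):
        lf, hf = normalized_band_power(constant_rr(1000.0, 120.0))
        assert np.isnan(lf) and np.isnan(hf)


class TestSlidingMetrics:
    def test_grid_spacing_exactly_1s(self):
        cfg = SimConfig(seed=2)
        rr = gen_rr_series(cfg, 0, "control")
        m = sliding_metrics(rr)
        assert np.allclose(np.diff(m.timestamps), 1.0)

    def test_constant_rr_metrics(self):
        m = sliding_metrics(constant_rr(1000.0, 300.0))
        core = np.isfinite(m.mean_rr)
        assert core.any()
        assert np.allclose(m.mean_rr[core], 1000.0)
        assert np.allclose(m.rmssd[core], 0.0)
        assert np.allclose(m.hr[core] * m.mean_rr[core], 60000.0)

    def test_edges_are_missing(self):
        m = sliding_metrics(constant_rr(1000.0, 300.0))
        assert np.isnan(m.mean_rr[m.timestamps < 50.0]).all()

    def test_step_change_tracked_within_half_window(self):
        cfg = SimConfig(seed=4, lf_block_s=300.0, lf_amp_high=50.0,
                        lf_amp_low=5.0, hf_amp=10.0, rr_noise_sd=0.0)
        rr = gen_rr_series(cfg, 0, baseline=1000.0)
        m = sliding_metrics(rr)
        lf = m.lf_hrv
        ok = np.isfinite(lf)
        t, lf = m.timestamps[ok], lf[ok]
        lo, hi = lf[(t > 150) & (t < 250)].mean(), lf[(t > 450) & (t < 550)].mean()
        mid = (lo + hi) / 2  # change point at 300 s (high -> low block)
        crossings = t[:-1][np.diff(np.sign(lf - mid)) != 0]
        assert np.any(np.abs(crossings - 300.0) <= 50.0)

    def test_one_outlier_beat_negligible_after_interpolation(self):
        cfg = SimConfig(seed=5, rr_noise_sd=2.0)
        clean = gen_rr_series(cfg, 0, baseline=1000.0)
        spiked = gen_rr_series(cfg, 0, baseline=1000.0, outlier_times=(400.0,))
        m0 = sliding_metrics(clean)
        m1 = sliding_metrics(spiked)
        ok = np.isfinite(m0.mean_rr) & np.isfinite(m1.mean_rr)
        rel = np.abs(m1.mean_rr[ok] - m0.mean_rr[ok]) / m0.mean_rr[ok]
        assert rel.max() < 0.01

    def test_record_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            sliding_metrics(constant_rr(1000.0, 60.0))


class TestOrthogonalize:
    def test_proportional_metric_vanishes(self, rng):
        ref = rng.standard_normal(200)
        resid = orthogonalize(2.0 * ref, ref)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_metric_only_demeaned(self, rng):
        ref = np.sin(np.arange(200))
        metric = np.cos(np.arange(200)) * 3 + 7
        resid = orthogonalize(metric, ref)
        assert np.allclose(resid, metric - np.polynomial.polynomial.polyfit(
            ref, metric, 1)[0] - np.polynomial.polynomial.polyfit(
            ref, metric, 1)[1] * ref, atol=1e-8)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_residual_uncorrelated_with_reference(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.standard_normal(150)
        metric = rng.standard_normal(150)
        resid = orthogonalize(metric, ref)
        assert abs(np.corrcoef(resid, ref)[0, 1]) < 1e-10

    def test_constant_reference_warns_and_demeans(self):
        with pytest.warns(UserWarning):
            resid = orthogonalize(np.arange(10.0), np.ones(10))
        assert resid.mean() == pytest.approx(0.0, abs=1e-12)

    def test_nan_positions_preserved(self, rng):
        ref = rng.standard_normal(50)
        metric = rng.standard_normal(50)
        metric[3] = np.nan
        resid = orthogonalize(metric, ref)
        assert np.isnan(resid[3]) and np.isfinite(np.delete(resid, 3)).all()
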