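"""Pulse cleaning and heartbeat-probability label construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hbpnet import (PeakSequence, PulseTrace, bandpass_pulse, detect_peaks,
                    filter_peaks_ibi, hbp_from_peaks, psd_hr,
                    resample_normalize, validate_peaks_psd)


def sinusoid(freq_hz, fs, n, amp=1.0, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.cos(2 * np.pi * freq_hz * t + phase)


def band_power(x, fs, f, halfwidth=0.05):
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    spec = np.abs(np.fft.rfft(x)) ** 2
    sel = np.abs(freqs - f) <= halfwidth
    return spec[sel].sum()


class TestBandpass:
    def test_out_of_band_component_attenuated_20db(self):
        fs, n = 50.0, 5000
        x = sinusoid(1.2, fs, n) + sinusoid(0.1, fs, n)
        out = bandpass_pulse(PulseTrace(x, fs), 0.7, 3.0)
        before = band_power(x, fs, 0.1)
        after = band_power(out.samples, fs, 0.1)
        assert after < before / 100          # >= 20 dB suppression
        # passband component survives
        assert band_power(out.samples, fs, 1.2) > 0.5 * band_power(x, fs, 1.2)

    def test_zero_phase_keeps_peak_positions(self):
        fs = 50.0
        x = sinusoid(1.2, fs, 1500)
        out = bandpass_pulse(PulseTrace(x, fs), 0.7, 3.0)
        p_in = detect_peaks(x, fs).indices
        p_out = detect_peaks(out.samples, fs).indices
        interior = (p_in > 50) & (p_in < 1450)
        assert np.all(np.abs(p_in[interior][:, None]
                             - p_out[None, :]).min(axis=1) <= 1)

    @pytest.mark.parametrize("lo,hi", [(2.0, 1.0), (0.0, 3.0), (0.7, 30.0)])
    def test_invalid_band_rejected(self, lo, hi):
        trace = PulseTrace(np.zeros(100) + np.arange(100.0), 50.0)
        with pytest.raises(ValueError):
            bandpass_pulse(trace, lo, hi)


class TestResampleNormalize:
    def test_hand_interpolation(self):
        out = resample_normalize(PulseTrace(np.array([0.0, 1, 2, 3]), 1.0), 7)
        expected = np.array([0, 0.5, 1, 1.5, 2, 2.5, 3]) - 1.5
        np.testing.assert_allclose(out, expected)

    def test_constant_trace_maps_to_zeros(self):
        out = resample_normalize(PulseTrace(np.full(50, 3.3), 10.0), 17)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)
        assert len(out) == 17

    def test_too_short_target_rejected(self):
        with pytest.raises(ValueError):
            resample_normalize(PulseTrace(np.arange(10.0), 10.0), 1)


class TestDetectPeaks:
    def test_cosine_peaks_exactly_periodic(self):
        fs = 30.0
        x = np.cos(2 * np.pi * np.arange(300) / 30)   # period 30 samples
        peaks = detect_peaks(x, fs)
        assert np.all(np.diff(peaks.indices) == 30)

    def test_monotone_ramp_has_no_peaks(self):
        peaks = detect_peaks(np.arange(100.0), 30.0)
        assert len(peaks) == 0

    def test_close_pair_keeps_higher(self):
        x = np.zeros(40)
        x[10], x[15] = 1.0, 2.0         # 5 apart; min distance 10
        fs, max_hr = 1.0, 6.0           # fs*60/max_hr = 10 samples
        peaks = detect_peaks(x, fs, min_hr_bpm=1.0, max_hr_bpm=max_hr)
        assert list(peaks.indices) == [15]

    def test_round_trip_through_label_map(self):
        # peaks of a label map built from equally spaced peaks are recovered
        # keep T short of one full period past the last peak: the outer
        # cosine would otherwise rise back to a genuine maximum there
        idx = np.arange(10, 280, 28)
        hbp = hbp_from_peaks(PeakSequence(idx, 30.0), 280)
        found = detect_peaks(hbp.values, 30.0)
        np.testing.assert_array_equal(found.indices, idx)


class TestPsdHr:
    def test_pure_tone_exact_bin(self):
        fs = 30.0
        x = sinusoid(1.2, fs, 1200)
        assert psd_hr(PulseTrace(x, fs)) == pytest.approx(72.0)

    def test_noisy_tone_within_one_bin(self, rng):
        fs = 30.0
        x = sinusoid(1.0, fs, 1200) + rng.normal(0, 0.1, 1200)
        assert abs(psd_hr(PulseTrace(x, fs)) - 60.0) <= 6.0 + 1e-9  # one 0.1 Hz bin

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            psd_hr(PulseTrace(np.ones(25), 50.0))

    def test_bandpass_then_psd_recovers_rate(self):
        fs = 50.0
        x = sinusoid(1.5, fs, 3000) + sinusoid(0.2, fs, 3000, amp=3.0)
        hr = psd_hr(bandpass_pulse(PulseTrace(x, fs)))
        assert abs(hr - 90.0) <= 0.1 * 60 / 10  # within one Welch bin


class TestFilterPeaksIbi:
    def test_long_interval_peak_removed(self):
        peaks = PeakSequence(np.array([0, 30, 60, 90, 150, 180]), 30.0)
        out = filter_peaks_ibi(peaks, 0.2)
        # the peak terminating the 60-frame interval goes; the following
        # interval (90 frames after the merge) violates too and cascades
        assert list(out.indices) == [0, 30, 60, 90]

    def test_equal_intervals_identity(self):
        peaks = PeakSequence(np.arange(0, 300, 30), 30.0)
        out = filter_peaks_ibi(peaks)
        np.testing.assert_array_equal(out.indices, peaks.indices)

    def test_small_jitter_within_tolerance_identity(self):
        peaks = PeakSequence(np.array([0, 30, 63, 90]), 30.0)  # 30,33,27
        out = filter_peaks_ibi(peaks, 0.2)
        np.testing.assert_array_equal(out.indices, peaks.indices)

    def test_fewer_than_three_peaks_warns(self):
        peaks = PeakSequence(np.array([5, 40]), 30.0)
        with pytest.warns(UserWarning):
            out = filter_peaks_ibi(peaks)
        np.testing.assert_array_equal(out.indices, peaks.indices)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(4, 30), st.integers(0, 2 ** 31 - 1))
    def test_idempotent_on_jittered_beats(self, n, seed):
        r = np.random.default_rng(seed)
        intervals = 30 * (1 + r.uniform(-0.1, 0.1, n))
        if r.random() < 0.5:
            intervals[r.integers(0, n)] *= 2.5   # isolated outlier
        idx = np.concatenate([[0], np.cumsum(intervals)]).astype(int)
        once = filter_peaks_ibi(PeakSequence(idx, 30.0))
        twice = filter_peaks_ibi(once)
        np.testing.assert_array_equal(once.indices, twice.indices)


class TestValidatePeaksPsd:
    def test_clean_pulse_passes(self):
        fs = 30.0
        x = sinusoid(1.2, fs, 1200)
        peaks = detect_peaks(x, fs)
        report = validate_peaks_psd(peaks, PulseTrace(x, fs))
        assert report.passed
        assert report.hr_peaks_bpm == pytest.approx(72.0, abs=1.0)
        assert report.hr_psd_bpm == pytest.approx(72.0, abs=1.0)

    def test_thinned_peaks_fail(self):
        fs = 30.0
        x = sinusoid(1.2, fs, 1200)
        peaks = detect_peaks(x, fs)
        thinned = PeakSequence(peaks.indices[::2], fs)
        report = validate_peaks_psd(thinned, PulseTrace(x, fs))
        assert not report.passed

    def test_unbounded_tolerance_always_passes(self):
        fs = 30.0
        x = sinusoid(1.2, fs, 1200)
        peaks = detect_peaks(x, fs)
        thinned = PeakSequence(peaks.indices[::2], fs)
        assert validate_peaks_psd(thinned, PulseTrace(x, fs), rel_tol=1.0).passed


class TestHbpFromPeaks:
    def test_peak_and_midpoint_calibration(self):
        hbp = hbp_from_peaks(PeakSequence(np.array([10, 30]), 30.0), 40)
        assert hbp.values[10] == 1.0
        assert hbp.values[30] == 1.0
        assert hbp.values[20] == pytest.approx(0.0, abs=1e-12)

    def test_outer_branch_hand_values(self):
        # Dmax = 20; x=5 pre-first: cos(2*pi*15/20) -> 0.5
        # x=35 post-last: cos(2*pi*5/20) -> 0.5
        hbp = hbp_from_peaks(PeakSequence(np.array([10, 30]), 30.0), 40)
        assert hbp.values[5] == pytest.approx(0.5, abs=1e-12)
        assert hbp.values[35] == pytest.approx(0.5, abs=1e-12)

    def test_equally_spaced_peaks_give_periodic_map(self):
        idx = np.arange(15, 300, 30)
        hbp = hbp_from_peaks(PeakSequence(idx, 30.0), 300)
        inner = hbp.values[idx[0]:idx[-1]]
        np.testing.assert_allclose(inner[:-30], inner[30:], atol=1e-9)

    def test_fewer_than_two_peaks_rejected(self):
        with pytest.raises(ValueError):
            hbp_from_peaks(PeakSequence(np.array([7]), 30.0), 40)

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValueError):
            hbp_from_peaks(PeakSequence(np.array([10, 50]), 30.0), 40)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 12), st.integers(0, 2 ** 31 - 1))
    def test_range_calibration_and_branch_continuity(self, n_peaks, seed):
        """[0,1] range, exact 1 at peaks, smooth junction at both branch
        boundaries (jump bounded by the map's largest one-step change)."""
        r = np.random.default_rng(seed)
        T = 240
        idx = np.sort(r.choice(np.arange(5, T - 5), size=n_peaks, replace=False))
        if np.any(np.diff(idx) < 2):
            idx = np.unique(np.concatenate([[idx[0]], idx[np.diff(
                np.concatenate([[idx[0] - 2], idx])) >= 2]]))
        if len(idx) < 2:
            return
        hbp = hbp_from_peaks(PeakSequence(idx, 30.0), T)
        v = hbp.values
        assert v.min() >= 0.0 and v.max() <= 1.0
        assert np.all(v[idx] == 1.0)
        max_step = np.abs(np.diff(v)).max()
        p0, pt = idx[0], idx[-1]
        if p0 > 0:
            assert abs(v[p0] - v[p0 - 1]) <= max_step + 1e-12
        if pt < T - 1:
            assert abs(v[pt + 1] - v[pt]) <= max_step + 1e-12
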