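import numpy as np
import pytest
from scipy import signal as sp_signal

from spindlelat.io_psg import AnalysisConfig
from spindlelat.spindles import (ChannelThresholds, compute_thresholds,
                                 detect_spindles, spindle_band_filter,
                                 spindle_density)

from conftest import clean_mask

FS = 256.0


def tone(freq, seconds, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(seconds * fs)) / fs)


class TestSpindleBandFilter:
    def test_passband_center_preserved(self):
        y = spindle_band_filter(tone(14.5, 120), FS)
        edge = int(15 * FS)
        assert np.abs(y[edge:-edge]).max() == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("freq", [10.0, 20.0])
    def test_out_of_band_attenuated(self, freq):
        y = spindle_band_filter(tone(freq, 120), FS)
        edge = int(15 * FS)
        assert np.abs(y[edge:-edge]).max() < 0.05

    def test_order_scales_with_rate(self):
        # at 256 Hz the design order is 2816 -> kernel 2817 taps; a shorter
        # signal must be rejected
        with pytest.raises(ValueError, match="filter length"):
            spindle_band_filter(np.zeros(3 * 2817 - 1), FS)
        # at 128 Hz the scaled order halves, so the same sample count passes
        spindle_band_filter(np.zeros(3 * 2817 - 1), 128.0)


class TestThresholds:
    def test_constant_amplitude(self, nrem_mask_10):
        # rectified trace identically 1 μV (alternating sign square wave)
        x = np.where(np.arange(int(300 * FS)) % 2 == 0, 1.0, -1.0)
        thr = compute_thresholds(x, nrem_mask_10, FS, "F3")
        assert thr.mean_amplitude_uv == pytest.approx(1.0)
        assert thr.upper == pytest.approx(5.0)
        assert thr.lower == pytest.approx(2.0)

    def test_sine_rectified_mean_two_a_over_pi(self, nrem_mask_10):
        A = 3.0
        thr = compute_thresholds(tone(14.0, 300, amp=A), nrem_mask_10, FS, "F3")
        assert thr.mean_amplitude_uv == pytest.approx(2 * A / np.pi, rel=1e-3)
        assert thr.upper == pytest.approx(10 * A / np.pi, rel=1e-3)

    def test_homogeneity(self, nrem_mask_10, rng):
        x = rng.normal(size=int(300 * FS))
        t1 = compute_thresholds(x, nrem_mask_10, FS, "F3")
        t2 = compute_thresholds(2 * x, nrem_mask_10, FS, "F3")
        assert t2.mean_amplitude_uv == pytest.approx(2 * t1.mean_amplitude_uv)
        assert t2.upper == pytest.approx(2 * t1.upper)
        assert t2.lower == pytest.approx(2 * t1.lower)

    def test_ratio_invariant(self, nrem_mask_10, rng):
        thr = compute_thresholds(rng.normal(size=int(300 * FS)),
                                 nrem_mask_10, FS, "F3")
        assert thr.upper / thr.lower == pytest.approx(2.5)

    def test_empty_mask_rejected(self):
        mask = clean_mask(2)
        mask.included[:] = False
        with pytest.raises(ValueError, match="no included"):
            compute_thresholds(np.zeros(int(60 * FS)), mask, FS, "F3")


def burst(center_s, plateau_s, freq, amp, n_samples, fs=FS, ramp_s=0.1):
    """Tukey-shaped 13–16 Hz burst with a flat plateau, added into zeros."""
    dur = plateau_s + 2 * ramp_s
    n = int(dur * fs)
    t = np.arange(n) / fs
    w = sp_signal.windows.tukey(n, alpha=2 * ramp_s / dur)
    x = np.zeros(n_samples)
    a = int((center_s - dur / 2) * fs)
    x[a:a + n] += amp * w * np.sin(2 * np.pi * freq * t)
    return x


class TestDetectSpindles:
    def thresholds(self, mean=1.0):
        return ChannelThresholds(channel="F3", mean_amplitude_uv=mean)

    def test_zero_signal_no_events(self, nrem_mask_10):
        events = detect_spindles(np.zeros(int(300 * FS)), self.thresholds(),
                                 nrem_mask_10, FS)
        assert events == []

    def test_single_burst_recovered(self, nrem_mask_10):
        # 1.0-s plateau at 6× the mean background amplitude in clean N2
        n = int(300 * FS)
        x = burst(45.0, 1.0, 14.0, amp=6.0, n_samples=n)
        events = detect_spindles(x, self.thresholds(), nrem_mask_10, FS)
        assert len(events) == 1
        ev = events[0]
        assert 0.8 <= ev.duration_s <= 1.2
        assert 44.4 < ev.peak_s < 45.6

    @pytest.mark.parametrize("gap_ms,n_expected", [(50, 1), (150, 2)])
    def test_gap_merge_rule(self, nrem_mask_10, gap_ms, n_expected):
        from scipy.signal import hilbert

        # calibrate the burst's above-lower half-width on its envelope so the
        # constructed sub-lower gap is exactly the requested one
        n = int(300 * FS)
        single = burst(45.0, 0.6, 14.0, 6.0, n)
        env = np.abs(hilbert(single))
        above = np.flatnonzero(env >= 2.0)
        half_width = (above[-1] - above[0] + 1) / FS / 2
        gap = gap_ms / 1000.0
        second = 45.0 + 2 * half_width + gap
        x = single + burst(second, 0.6, 14.0, 6.0, n)
        events = detect_spindles(x, self.thresholds(), nrem_mask_10, FS)
        assert len(events) == n_expected

    def test_too_long_rejected(self, nrem_mask_10):
        n = int(300 * FS)
        x = burst(45.0, 3.5, 14.0, 6.0, n)
        assert detect_spindles(x, self.thresholds(), nrem_mask_10, FS) == []

    def test_amplitude_cap(self, nrem_mask_10):
        n = int(300 * FS)
        x = burst(45.0, 1.0, 14.0, 250.0, n)
        thr = ChannelThresholds(channel="F3", mean_amplitude_uv=250 / 6.0)
        assert detect_spindles(x, thr, nrem_mask_10, FS) == []

    def test_scaling_invariance(self, nrem_mask_10, rng):
        n = int(300 * FS)
        noise = 0.3 * rng.normal(size=n)
        x = burst(45.0, 1.0, 14.0, 6.0, n) + burst(105.0, 0.8, 15.0, 7.0, n) + noise
        xf = x  # already band-limited enough for the threshold logic
        thr1 = compute_thresholds(xf, nrem_mask_10, FS, "F3")
        ev1 = detect_spindles(xf, thr1, nrem_mask_10, FS)
        k = 3.7
        thr2 = compute_thresholds(k * xf, nrem_mask_10, FS, "F3")
        ev2 = detect_spindles(k * xf, thr2, nrem_mask_10, FS)
        assert [(e.start_s, e.end_s) for e in ev1] == [(e.start_s, e.end_s) for e in ev2]

    def test_event_in_artifact_dropped(self):
        mask = clean_mask(10)
        mask.artifact_subintervals[1] = [(44.0, 46.0)]
        n = int(300 * FS)
        x = burst(45.0, 1.0, 14.0, 6.0, n)
        assert detect_spindles(x, self.thresholds(), mask, FS) == []

    def test_event_in_excluded_epoch_dropped(self):
        mask = clean_mask(10)
        mask.included[1] = False  # epoch covering 30-60 s
        n = int(300 * FS)
        x = burst(45.0, 1.0, 14.0, 6.0, n)
        assert detect_spindles(x, self.thresholds(), mask, FS) == []

    def test_events_sorted_and_disjoint(self, nrem_mask_10):
        n = int(300 * FS)
        x = sum(burst(20.0 + 10 * i, 1.0, 14.0, 6.0, n) for i in range(5))
        events = detect_spindles(x, self.thresholds(), nrem_mask_10, FS)
        assert len(events) == 5
        for a, b in zip(events[:-1], events[1:]):
            assert a.end_s <= b.start_s


class TestDensity:
    def test_arithmetic(self):
        assert spindle_density(30, 10.0) == 3.0
        assert spindle_density(0, 10.0) == 0.0

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            spindle_density(5, 0.0)
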