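"""Band power against a Parseval oracle, RPL invariants, sliding windows,
hemodynamic baseline/averaging, and the per-minute behavioral counts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sig

import drowsikit as dk
from drowsikit.core_io import Annotation, DrowsikitError, default_band_set
from drowsikit.features import (
    UndefinedRPLError,
    band_power,
    detect_impulses,
    hemo_baseline_average,
    per_minute_parameters,
    relative_power_level,
    sliding_rpl,
)

from conftest import make_small_recording

FS = 512.0


def _tone(freq, dur=10.0, fs=FS, ampl=1.0):
    t = np.arange(int(dur * fs)) / fs
    return ampl * np.sin(2 * np.pi * freq * t)


def _periodogram_band_power(x, fs, lo, hi):
    """Independent oracle: raw periodogram bins summed over [lo, hi)."""
    f, p = sig.periodogram(x, fs=fs)
    df = f[1] - f[0]
    return p[(f >= lo) & (f < hi)].sum() * df


class TestBandPower:
    def test_single_tone_concentrates_in_alpha(self):
        x = _tone(10.0)
        alpha = band_power(x, FS, (8.0, 13.0))
        total = band_power(x, FS, (1.0, 50.0))
        assert alpha / total > 0.95

    def test_zero_signal(self):
        assert band_power(np.zeros(int(4 * FS)), FS, (8.0, 13.0)) == 0.0

    def test_two_equal_tones_split_evenly(self):
        x = _tone(3.0) + _tone(20.0)
        delta = band_power(x, FS, (1.0, 4.0))
        beta = band_power(x, FS, (13.0, 30.0))
        assert abs(delta - beta) / beta < 0.05

    @pytest.mark.parametrize("freqs,ampls", [
        ((3.0, 10.0, 20.0), (1.0, 0.5, 2.0)),
        ((2.0, 35.0), (1.5, 1.0)),
    ])
    def test_matches_parseval_oracle(self, freqs, ampls):
        """Welch band power agrees with a direct periodogram integration
        within 5 % on multi-tone signals."""
        x = sum(_tone(f, ampl=a) for f, a in zip(freqs, ampls))
        for lo, hi in ((1.0, 4.0), (8.0, 13.0), (13.0, 30.0), (30.0, 50.0)):
            ours = band_power(x, FS, (lo, hi))
            oracle = _periodogram_band_power(x, FS, lo, hi)
            if oracle > 1e-6:
                assert abs(ours - oracle) / oracle < 0.05

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(DrowsikitError):
            band_power(np.zeros(4000), 10.0, (1.0, 8.0))

    def test_too_short_rejected(self):
        with pytest.raises(DrowsikitError):
            band_power(np.zeros(100), FS, (8.0, 13.0))


class TestRPL:
    def test_five_equal_tones_give_uniform_rpl(self):
        x = (_tone(2.5) + _tone(6.0) + _tone(10.0) + _tone(20.0) + _tone(40.0))[None, :]
        rpl = relative_power_level(x, FS)
        np.testing.assert_allclose(rpl, 0.2, atol=0.01)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, int(8 * FS)))
        rpl = relative_power_level(x, FS)
        assert abs(rpl.sum() - 1.0) < 1e-9
        assert np.all(rpl >= 0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((2, int(4 * FS)))
        base = relative_power_level(x, FS)
        scaled = relative_power_level(scale * x, FS)
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(UndefinedRPLError):
            relative_power_level(np.zeros((1, int(4 * FS))), FS)

    def test_drowsy_weighting_lowers_beta(self):
        """A signal whose beta share of power is reduced shows a strictly
        lower beta RPL."""
        rng = np.random.default_rng(3)
        sos_b = sig.butter(4, [13, 30], btype="bandpass", fs=FS, output="sos")
        sos_d = sig.butter(4, [1, 4], btype="bandpass", fs=FS, output="sos")
        n = int(20 * FS)
        beta_part = sig.sosfilt(sos_b, rng.standard_normal(n))
        delta_part = sig.sosfilt(sos_d, rng.standard_normal(n))
        awake = (1.5 * beta_part + delta_part)[None]
        drowsy = (0.6 * beta_part + 1.8 * delta_part)[None]
        assert relative_power_level(drowsy, FS)[3] < relative_power_level(awake, FS)[3]


class TestSlidingRPL:
    def test_window_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, int(10 * FS)))
        series = sliding_rpl(x, FS)
        assert series.rpl.shape[0] == 9
        np.testing.assert_allclose(series.times, np.arange(1, 10, dtype=float))

    def test_stationary_signal_is_stable(self):
        rng = np.random.default_rng(1)
        sos = sig.butter(4, [1, 50], btype="bandpass", fs=FS, output="sos")
        x = sig.sosfilt(sos, rng.standard_normal((1, int(60 * FS))), axis=-1)
        series = sliding_rpl(x, FS)
        assert series.beta.std() < 0.1

    def test_step_change_crossing_located(self):
        """A switch from beta-heavy to delta-heavy power at t = 5 s moves the
        sliding beta RPL across the midpoint within 2 s of the switch."""
        rng = np.random.default_rng(2)
        n = int(10 * FS)
        sos_b = sig.butter(4, [13, 30], btype="bandpass", fs=FS, output="sos")
        sos_d = sig.butter(4, [1, 4], btype="bandpass", fs=FS, output="sos")
        beta_part = sig.sosfilt(sos_b, rng.standard_normal(n))
        delta_part = sig.sosfilt(sos_d, rng.standard_normal(n))
        beta_part /= beta_part.std()
        delta_part /= delta_part.std()
        gate = (np.arange(n) < 5 * FS).astype(float)
        x = (gate * beta_part + (1 - gate) * delta_part)[None]
        series = sliding_rpl(x, FS)
        hi = series.beta[series.times <= 3].mean()
        lo = series.beta[series.times >= 8].mean()
        mid = (hi + lo) / 2
        crossing = series.times[np.flatnonzero(series.beta < mid)[0]]
        assert abs(crossing - 5.0) <= 2.0

    def test_too_short_rejected(self):
        with pytest.raises(DrowsikitError):
            sliding_rpl(np.zeros((1, int(1 * FS))), FS)


class TestHemo:
    def test_constant_removed_by_baseline(self):
        hbo = np.full((3, 200), 0.3)
        hb = np.full((3, 200), -0.1)
        out = hemo_baseline_average(hbo, hb, 10.0)
        np.testing.assert_allclose(out.hbo, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.hb, 0.0, atol=1e-12)

    def test_channel_average_of_common_ramp(self):
        t = np.arange(300) / 10.0
        ramp = 0.2 * t / t[-1]
        hbo = np.vstack([0.1 + ramp, 0.3 + ramp])
        out = hemo_baseline_average(hbo, np.zeros_like(hbo), 10.0, downsample_to_1hz=False)
        expect = ramp - ramp[:100].mean()
        np.testing.assert_allclose(out.hbo, expect, atol=1e-12)

    def test_block_mean_downsampling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 257))  # 25.7 s at 10 Hz
        out = hemo_baseline_average(x, x, 10.0)
        assert out.hbo.size == 25
        base = x[0] - x[0, :100].mean()
        np.testing.assert_allclose(out.hbo[3], base[30:40].mean(), atol=1e-12)
        np.testing.assert_allclose(out.times, np.arange(25, dtype=float))

    def test_baseline_correction_idempotent(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 400))
        once = hemo_baseline_average(x, x, 10.0, downsample_to_1hz=False)
        twice = hemo_baseline_average(once.hbo[None], once.hb[None], 10.0,
                                      downsample_to_1hz=False)
        np.testing.assert_allclose(once.hbo, twice.hbo, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(DrowsikitError):
            hemo_baseline_average(np.zeros((2, 50)), np.zeros((2, 50)), 10.0)

    def test_all_channels_excluded_rejected(self):
        with pytest.raises(DrowsikitError):
            hemo_baseline_average(np.zeros((2, 200)), np.zeros((2, 200)), 10.0,
                                  excluded=(0, 1))


class TestPerMinuteParameters:
    def _recording_with_events(self, cmap, n_blinks=12, n_beats=70):
        rec = make_small_recording(cmap, duration_s=120.0, fs=128.0, seed=8,
                                   annotations=[Annotation(onset_s=30.0, duration_s=3.0)])
        fs = rec.fs_eeg
        blink = 60.0 * 0.5 * (1 - np.cos(2 * np.pi * np.arange(int(0.4 * fs)) / (int(0.4 * fs) - 1)))
        for k in range(n_blinks):
            i = int((1.0 + k * 58.0 / n_blinks) * fs)
            rec.eog[0, i : i + blink.size] += blink
        spike = 500.0 * np.concatenate([np.linspace(0, 1, 3), np.linspace(1, 0, 3)[1:]])
        for k in range(n_beats):
            i = int((0.5 + k * 59.0 / n_beats) * fs)
            rec.ecg[0, i : i + spike.size] += spike
        return rec

    def test_injected_counts_recovered(self, small_channel_map):
        rec = self._recording_with_events(small_channel_map)
        table = per_minute_parameters(rec)
        assert table.loc[0, "blink_rate"] == 12
        assert table.loc[0, "heart_rate"] == 70
        assert table.loc[0, "eye_closure"] == 1
        assert table.loc[1, "eye_closure"] == 0
        assert len(table) == 2

    def test_short_closures_not_counted(self, small_channel_map):
        rec = make_small_recording(
            small_channel_map, duration_s=60.0, fs=128.0,
            annotations=[Annotation(onset_s=10.0, duration_s=1.0)],
        )
        table = per_minute_parameters(rec)
        assert table.loc[0, "eye_closure"] == 0

    def test_impulse_detector_refractory(self):
        fs = 128.0
        x = np.zeros(int(10 * fs))
        rng = np.random.default_rng(0)
        x += 0.1 * rng.standard_normal(x.size)
        for t in (1.0, 1.05, 3.0):  # two impulses closer than the refractory
            x[int(t * fs)] += 5.0
        times = detect_impulses(x, fs, refractory_s=0.2)
        assert len(times) == 2
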