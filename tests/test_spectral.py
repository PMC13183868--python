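"""Spectral analysis: filter response, spectrogram/PSD conventions, band
powers and the peri-event SWA operations."""

import numpy as np
import pytest
from scipy import signal as sps

from microarousal import (
    BANDS,
    Event,
    EventSet,
    Interval,
    SWA,
    SignalTrace,
    band_power,
    bandpass,
    nrem_swa_baseline,
    peri_event_band_timecourse,
    post_ma_swa,
    psd_before_during_after,
    spectrogram,
    welch_psd,
)
from microarousal.hypnogram import Hypnogram
from microarousal.spectral import BandDefinition, bandpass_sos

FS = 256.0


def sine(freq, duration=60.0, amp=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return SignalTrace(amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_passband_center_preserved(self):
        out = bandpass(sine(2.0))
        mid = out.samples[len(out.samples) // 4 : -len(out.samples) // 4]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuated(self):
        out = bandpass(sine(0.2, duration=120.0))
        rms_in = 1.0 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert rms_out < 0.05 * rms_in

    def test_zero_in_zero_out(self):
        out = bandpass(SignalTrace(np.zeros(int(30 * FS)), FS))
        assert np.allclose(out.samples, 0.0)

    def test_hi_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sine(2.0), lo=1.0, hi=200.0)

    def test_magnitude_matches_analog_design(self):
        # digital realization within 1 dB of the analytic Butterworth
        # response at lo/2, the geometric passband center, and 2*hi
        lo, hi, order = 1.0, 30.0, 20
        sos = bandpass_sos(lo, hi, order, FS)
        b, a = sps.butter(order // 2, [2 * np.pi * lo, 2 * np.pi * hi],
                          btype="bandpass", analog=True)
        for f in (lo / 2, np.sqrt(lo * hi), 2 * hi):
            w, h_dig = sps.sosfreqz(sos, worN=[f], fs=FS)
            _, h_an = sps.freqs(b, a, worN=[2 * np.pi * f])
            dig_db = 20 * np.log10(np.abs(h_dig[0]) + 1e-300)
            an_db = 20 * np.log10(np.abs(h_an[0]) + 1e-300)
            if an_db > -30:
                assert dig_db == pytest.approx(an_db, abs=1.0)
            else:
                # deep stopband: bilinear warping only sharpens the rolloff;
                # require at least the analytic attenuation (small slack)
                assert dig_db <= an_db + 3.0


class TestSpectrogram:
    def test_bin_count(self):
        spec = spectrogram(sine(4.0, duration=10.0))
        assert spec.power.shape[0] == 20  # 10 s / 0.5 s

    def test_sine_peaks_at_its_frequency(self):
        spec = spectrogram(sine(4.0, duration=10.0))
        peak_freqs = spec.freqs[spec.power.argmax(axis=1)]
        assert np.all(peak_freqs == pytest.approx(4.0, abs=1.01))

    def test_white_noise_flat(self, rng):
        x = SignalTrace(rng.standard_normal(int(120 * FS)), FS)
        spec = spectrogram(x)
        mean_by_freq = spec.power.mean(axis=0)[1:-1]  # skip DC/Nyquist bins
        assert mean_by_freq.std() / mean_by_freq.mean() < 0.15

    def test_window_longer_than_trace(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram(SignalTrace(np.zeros(10), FS), window_s=0.5)


class TestWelchPSD:
    def test_grid_spacing_is_half_hz(self):
        psd = welch_psd(sine(3.0, duration=30.0))
        assert psd.df == pytest.approx(0.5)
        assert psd.freqs[0] == 0.0
        assert psd.freqs[-1] == pytest.approx(FS / 2)

    def test_sine_peak_and_parseval(self):
        psd = welch_psd(sine(3.0, duration=60.0))
        assert psd.freqs[psd.density.argmax()] == pytest.approx(3.0)
        # integrated power of a unit sinusoid is A^2/2 = 0.5
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(0.5, rel=0.05)

    def test_zero_signal(self):
        psd = welch_psd(SignalTrace(np.zeros(int(10 * FS)), FS))
        assert np.all(psd.density == 0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            welch_psd(SignalTrace(np.zeros(100), FS))

    def test_white_noise_integrates_to_variance(self, rng):
        x = rng.standard_normal(int(200 * FS))  # 400 segments
        psd = welch_psd(SignalTrace(x, FS))
        total = np.trapezoid(psd.density, psd.freqs)
        assert total == pytest.approx(x.var(), rel=0.05)


class TestBandPower:
    def test_delta_sine_dominates_swa(self):
        # on the 0.5-Hz Welch grid the 2-Hz line is fully inside SWA
        psd = welch_psd(sine(2.0, duration=30.0))
        swa = band_power(psd, SWA)
        theta = band_power(psd, BANDS["theta"])
        assert swa >= 20.0 * max(theta, 1e-12)
        # the coarse 2-Hz spectrogram grid leaks into the shared 4-Hz bin,
        # but SWA still dominates
        spec = spectrogram(sine(2.0, duration=30.0))
        assert band_power(spec, SWA).mean() >= 8.0 * band_power(spec, BANDS["theta"]).mean()

    def test_zero_signal(self):
        spec = spectrogram(SignalTrace(np.zeros(int(10 * FS)), FS))
        assert np.all(band_power(spec, SWA) == 0.0)

    def test_full_band_equals_overall_mean(self, rng):
        x = SignalTrace(rng.standard_normal(int(30 * FS)), FS)
        spec = spectrogram(x)
        full = BandDefinition("all", 0.0, FS / 2)
        assert np.allclose(band_power(spec, full), spec.power.mean(axis=1))

    def test_empty_band_rejected(self, rng):
        psd = welch_psd(SignalTrace(rng.standard_normal(1024), FS))
        with pytest.raises(ValueError, match="empty"):
            band_power(psd, BandDefinition("nothing", 10.1, 10.2))

    def test_partition_sums_to_total(self, rng):
        # integral band power over a partition of [0, Nyquist] equals the
        # total integrated power within 1%
        x = SignalTrace(rng.standard_normal(int(60 * FS)), FS)
        psd = welch_psd(x)
        edges = [0.0, 4.0, 10.0, 16.0, 30.0, 80.0, FS / 2]
        total = np.trapezoid(psd.density, psd.freqs)
        # sum of integrals over contiguous bands (trapezoid is additive
        # when bands share edge bins)
        parts = sum(
            band_power(psd, BandDefinition("p", lo, hi), mode="integral")
            for lo, hi in zip(edges[:-1], edges[1:])
        )
        assert parts == pytest.approx(total, rel=0.01)


def delta_modulated_trace(rng, duration=600.0, events=(), drop=0.5,
                          post=None, fs=FS):
    """1-4 Hz noise whose amplitude drops by ``drop`` during events and is
    set to ``post`` (fraction of baseline power) 3-8 s after each onset."""
    n = int(duration * fs)
    carrier = rng.standard_normal(n)
    sos = sps.butter(4, [1.0, 4.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    carrier /= carrier.std()
    amp = np.ones(n)
    for ev in events:
        i0, i1 = int(ev.onset * fs), int(ev.offset * fs)
        amp[i0:i1] = np.sqrt(1.0 - drop)
        if post is not None:
            p0, p1 = int((ev.onset + 3) * fs), int((ev.onset + 8) * fs)
            amp[p0:p1] = np.sqrt(post)
    return SignalTrace(carrier * amp, fs)


class TestPeriEvent:
    def test_stationary_signal_flat_timecourse(self, rng):
        trace = delta_modulated_trace(rng, duration=900.0)
        events = EventSet([Event(t, 3.0) for t in (200.0, 400.0, 600.0)])
        t, mean, sem = peri_event_band_timecourse(
            trace, events, SWA, pre_s=60.0, post_s=60.0,
            baseline=Interval(-50.0, 30.0),
        )
        # no planted modulation: percent change fluctuates around zero
        assert abs(mean.mean()) < 15.0

    def test_planted_drop_recovered(self, rng):
        events = EventSet([Event(t, 4.0) for t in np.arange(150.0, 1500.0, 90.0)])
        trace = delta_modulated_trace(rng, duration=1600.0, events=events, drop=0.5)
        t, mean, sem = peri_event_band_timecourse(
            trace, events, SWA, pre_s=60.0, post_s=60.0,
            baseline=Interval(-50.0, 30.0),
        )
        during = mean[(t >= 0.5) & (t < 3.5)].mean()
        assert during == pytest.approx(-50.0, abs=15.0)

    def test_single_event_zero_sem(self, rng):
        trace = delta_modulated_trace(rng, duration=300.0)
        events = EventSet([Event(150.0, 3.0)])
        _, _, sem = peri_event_band_timecourse(trace, events, SWA, 60.0, 60.0,
                                               Interval(-50.0, 30.0))
        assert np.all(sem == 0.0)


class TestPSDBeforeDuringAfter:
    def test_stationary_no_change(self, rng):
        trace = SignalTrace(rng.standard_normal(int(1200 * FS)), FS)
        events = EventSet([Event(t, 3.0) for t in np.arange(100.0, 1100.0, 100.0)])
        res = psd_before_during_after(trace, events)
        sel = (res["percent_change"].freqs >= 1) & (res["percent_change"].freqs <= 30)
        assert abs(np.nanmean(res["percent_change"].density[sel])) < 15.0

    def test_planted_during_drop_and_post_overshoot(self, rng):
        events = EventSet([Event(t, 2.0) for t in np.arange(120.0, 1400.0, 80.0)])
        trace = delta_modulated_trace(rng, duration=1500.0, events=events,
                                      drop=0.6, post=1.4)
        res = psd_before_during_after(trace, events)
        f = res["before"].freqs
        swa_sel = (f >= 1) & (f <= 4)
        before = res["before"].density[swa_sel].mean()
        during = res["during"].density[swa_sel].mean()
        after = res["after"].density[swa_sel].mean()
        assert during / before == pytest.approx(0.4, abs=0.12)
        assert after > before
        assert res["auc"] > 0.0

    def test_insufficient_context_events_skipped(self, rng):
        trace = SignalTrace(rng.standard_normal(int(400 * FS)), FS)
        events = EventSet([Event(10.0, 2.0), Event(200.0, 2.0)])
        res = psd_before_during_after(trace, events)
        assert res["n_events"] == 1

    def test_all_skipped_errors(self, rng):
        trace = SignalTrace(rng.standard_normal(int(100 * FS)), FS)
        events = EventSet([Event(10.0, 2.0)])
        with pytest.raises(ValueError, match="context"):
            psd_before_during_after(trace, events)


class TestPostMASWA:
    def test_equal_to_baseline_gives_100(self, rng):
        trace = delta_modulated_trace(rng, duration=120.0)
        spec = spectrogram(SignalTrace(trace.segment(53.0, 58.0), FS))
        baseline = float(band_power(spec, SWA).mean())
        pct = post_ma_swa(trace, Event(50.0, 2.0), baseline)
        assert pct == pytest.approx(100.0, abs=1e-6)

    def test_double_baseline_gives_200(self, rng):
        trace = delta_modulated_trace(rng, duration=120.0)
        spec = spectrogram(SignalTrace(trace.segment(53.0, 58.0), FS))
        baseline = float(band_power(spec, SWA).mean())
        pct = post_ma_swa(trace, Event(50.0, 2.0), baseline / 2.0)
        assert pct == pytest.approx(200.0, abs=1e-6)

    def test_nonpositive_baseline_rejected(self, rng):
        trace = delta_modulated_trace(rng, duration=60.0)
        with pytest.raises(ValueError, match="baseline"):
            post_ma_swa(trace, Event(20.0, 2.0), 0.0)


def test_nrem_swa_baseline_tracks_delta_amplitude(rng):
    hyp = Hypnogram(np.array(["N"] * 100))
    trace = delta_modulated_trace(rng, duration=400.0)
    b1 = nrem_swa_baseline(trace, hyp)
    doubled = SignalTrace(trace.samples * 2.0, FS)
    b2 = nrem_swa_baseline(doubled, hyp)
    assert b2 / b1 == pytest.approx(4.0, rel=1e-6)


def test_bandpass_then_welch_stopband_power(rng):
    # after 1-30 Hz filtering, bins below 0.5 Hz and above 40 Hz carry
    # under 1% of the total power
    x = SignalTrace(rng.standard_normal(int(120 * FS)), FS)
    y = bandpass(x)
    psd = welch_psd(y)
    stop = (psd.freqs < 0.5) | (psd.freqs > 40.0)
    assert psd.density[stop].sum() / psd.density.sum() < 0.01
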