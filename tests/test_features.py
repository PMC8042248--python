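"""Event morphology metrics and patient-level summaries."""
import numpy as np
import pytest

from scalphfo import features as feat
from scalphfo.filtering import bandpass_ripple
from scalphfo.types import (
    DataInterval,
    HfoEvent,
    InvalidConfigError,
    UndefinedFrequencyError,
)

FS = 1024.0


def _tone_segment(freq, ms, amp=1.0):
    n = int(ms / 1000 * FS)
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS)


class TestEventFrequency:
    @pytest.mark.parametrize("freq,tol", [(100.0, 1.0), (250.0, 2.0)])
    def test_pure_tone(self, freq, tol):
        seg = _tone_segment(freq, 50.0)
        assert abs(feat.event_frequency(seg, FS) - freq) <= tol

    def test_linear_chirp_gives_mean_instantaneous_frequency(self):
        # oracle: mean instantaneous frequency of a 90->110 Hz chirp is 100 Hz
        n = int(0.1 * FS)
        t = np.arange(n) / FS
        phase = 2 * np.pi * (90.0 * t + 0.5 * (110.0 - 90.0) / t[-1] * t**2)
        seg = np.sin(phase)
        assert abs(feat.event_frequency(seg, FS) - 100.0) <= 3.0

    def test_too_few_crests_raise(self):
        with pytest.raises(UndefinedFrequencyError):
            feat.event_frequency(_tone_segment(100.0, 8.0), FS)

    def test_fft_method_agrees_on_pure_tone(self):
        seg = _tone_segment(160.0, 100.0)
        assert abs(feat.event_frequency(seg, FS, method="fft") - 160.0) <= 10.0


class TestEventDuration:
    def test_41_samples_is_40ms(self):
        assert round(feat.event_duration_ms(100, 141, FS), 1) == 40.0

    def test_rectangular_burst_duration(self):
        n = int(0.024 * FS)
        assert abs(feat.event_duration_ms(0, n, FS) - 24.0) <= 1000.0 / FS


class TestEventAmplitude:
    def test_sinusoid_peak_to_peak(self):
        seg = _tone_segment(100.0, 50.0, amp=10.0)
        assert feat.event_amplitude(seg) == pytest.approx(20.0, rel=0.02)

    def test_decaying_burst_uses_largest_pair(self):
        seg = _tone_segment(100.0, 50.0, amp=8.0) * np.exp(
            -np.arange(int(0.05 * FS)) / (0.02 * FS)
        )
        amp = feat.event_amplitude(seg)
        assert 12.0 <= amp <= 16.0  # first full crest-trough pair dominates

    def test_asymmetric_wave(self):
        # crest +12, trough -5 -> highest adjacent pair 17
        t = np.arange(int(0.05 * FS)) / FS
        seg = np.where(np.sin(2 * np.pi * 100 * t) > 0, 12.0, -5.0) * np.abs(
            np.sin(2 * np.pi * 100 * t)
        )
        assert feat.event_amplitude(seg) == pytest.approx(17.0, rel=0.05)


class TestEventSnr:
    def test_equal_power_gives_unity(self):
        x = _tone_segment(100.0, 2000.0)
        a, b = int(0.75 * FS), int(1.25 * FS)
        assert feat.event_snr(x, a, b, FS) == pytest.approx(1.0, rel=0.05)

    def test_silent_flanks_give_inf_with_warning(self):
        x = np.zeros(int(2 * FS))
        x[1024:1124] = 1.0
        with pytest.warns(UserWarning):
            assert np.isinf(feat.event_snr(x, 1024, 1124, FS))

    def test_tone_on_band_noise_matches_analytic_expectation(self):
        # oracle: SNR ~ (A^2/2 + sigma_b^2) / sigma_b^2 for in-band noise
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(20):
            noise = bandpass_ripple(rng.standard_normal(int(3 * FS)), FS)
            sigma2 = np.mean(noise**2)
            a, b = int(1.4 * FS), int(1.6 * FS)
            x = noise.copy()
            A = 5.0 * np.sqrt(sigma2)
            x[a:b] += A * np.sin(2 * np.pi * 120.0 * np.arange(b - a) / FS)
            expected = (A**2 / 2 + sigma2) / sigma2
            ratios.append(feat.event_snr(x, a, b, FS) / expected)
        assert abs(np.mean(ratios) - 1.0) <= 0.10


class TestRippleBandActivity:
    def test_inband_sinusoid_gives_a_over_sqrt2(self):
        x = 3.0 * np.sin(2 * np.pi * 130.0 * np.arange(int(10 * FS)) / FS)
        ivs = [DataInterval(0.0, 5.0), DataInterval(5.0, 10.0)]
        rba = feat.ripple_band_activity(x, FS, ivs)
        assert rba == pytest.approx(3.0 / np.sqrt(2), rel=0.02)

    def test_zero_signal_gives_zero(self):
        ivs = [DataInterval(0.0, 5.0)]
        assert feat.ripple_band_activity(np.zeros(int(5 * FS)), FS, ivs) == 0.0

    def test_white_noise_matches_filter_gain_oracle(self):
        # oracle: measure the filter's RMS gain on an independent realization
        rng = np.random.default_rng(5)
        sigma = 2.0
        gain = np.sqrt(
            np.mean(bandpass_ripple(rng.standard_normal(int(30 * FS)), FS) ** 2)
        )
        x = sigma * rng.standard_normal(int(10 * FS))
        ivs = [DataInterval(0.0, 5.0), DataInterval(5.0, 10.0)]
        rba = feat.ripple_band_activity(x, FS, ivs)
        assert rba == pytest.approx(gain * sigma, rel=0.05)


def _ev(channel, onset=0.0, status="accepted", freq=100.0):
    return HfoEvent(channel, onset, onset + 0.05, freq, 50.0, 15.0, 8.0, status)


class TestChannelRatesAndSummary:
    def test_published_rate_arithmetic(self):
        # 397 events over six 5-min intervals -> 13.2/min; 137 over four -> 6.85
        ivs6 = [DataInterval(i * 300.0, (i + 1) * 300.0) for i in range(6)]
        evs = [_ev("P3-O1", onset=i * 4.0) for i in range(397)]
        prof = feat.channel_rates(evs, ivs6)["P3-O1"]
        assert round(prof.rate_per_min, 1) == 13.2
        ivs4 = ivs6[:4]
        evs = [_ev("T6-P4", onset=i * 4.0) for i in range(137)]
        prof = feat.channel_rates(evs, ivs4)["T6-P4"]
        assert prof.rate_per_min == pytest.approx(6.85)

    def test_rate_times_minutes_is_integral(self):
        ivs = [DataInterval(i * 300.0, (i + 1) * 300.0) for i in range(7)]
        evs = [_ev("F3-C3", onset=i * 10.0) for i in range(23)]
        prof = feat.channel_rates(evs, ivs)["F3-C3"]
        assert prof.rate_per_min * prof.total_minutes == pytest.approx(23.0)

    def test_zero_events_zero_rate(self):
        ivs = [DataInterval(0.0, 300.0)]
        assert feat.channel_rates([], ivs, channels=["F3-C3"])["F3-C3"].rate_per_min == 0.0

    def test_zero_minutes_is_an_error(self):
        with pytest.raises(InvalidConfigError):
            feat.channel_rates([], [])

    def test_rejected_events_do_not_count(self):
        ivs = [DataInterval(0.0, 300.0)]
        evs = [_ev("F3-C3"), _ev("F3-C3", onset=1.0, status="rejected_snr")]
        assert feat.channel_rates(evs, ivs)["F3-C3"].event_count == 1

    def test_top_channel_tie_breaks_on_name(self):
        ivs = [DataInterval(0.0, 300.0)]
        evs = [_ev("P3-O1"), _ev("F3-C3", onset=2.0)]
        profiles = feat.channel_rates(evs, ivs)
        assert feat.top_channel(profiles) == "F3-C3"

    def test_three_events_morphology_invalid(self):
        ivs = [DataInterval(0.0, 300.0)]
        evs = [_ev("F3-C3", onset=i * 2.0) for i in range(3)]
        s = feat.summarize_patient(evs, ivs)
        assert not s.morphology_valid
        assert s.mean_frequency_hz is None
        assert s.mean_snr is not None  # SNR mean has no >3 requirement

    def test_four_identical_events_mean_frequency(self):
        ivs = [DataInterval(0.0, 300.0)]
        evs = [_ev("F3-C3", onset=i * 2.0, freq=100.0) for i in range(4)]
        s = feat.summarize_patient(evs, ivs)
        assert s.morphology_valid
        assert s.mean_frequency_hz == pytest.approx(100.0)
        assert s.rate_top == pytest.approx(4 / 5.0)
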