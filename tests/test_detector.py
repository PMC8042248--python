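"""Three-stage detector: stage behaviour, invariants, end-to-end recovery."""
import numpy as np
import pytest

from scalphfo.detector import (
    DetectorConfig,
    detect_hfo,
    isolated_peak_decision,
    stage1_detect,
    stage2_isolated_peak,
    stage3_scalp_filter,
)
from scalphfo.simulate import inject_events, match_events
from scalphfo.types import (
    DataInterval,
    EventOfInterest,
    GroundTruthEvent,
    HfoEvent,
    InvalidConfigError,
    Recording,
)

FS = 1024.0


def _noise(seconds, seed, sigma=1.0):
    return sigma * np.random.default_rng(seed).standard_normal(int(seconds * FS))


def _burst(freq, ms, amp):
    from scipy.signal import windows

    n = int(ms / 1000 * FS)
    return amp * windows.tukey(n, 0.5) * np.sin(2 * np.pi * freq * np.arange(n) / FS)


class TestStage1:
    def test_all_zero_signal_yields_no_eoi(self):
        assert stage1_detect(np.zeros(int(20 * FS)), FS) == []

    def test_strong_ripple_detected_at_injected_support(self):
        x = _noise(20.0, 0)
        burst = _burst(120.0, 60.0, 20.0)
        a = int(10.0 * FS)
        x[a : a + burst.size] += burst
        eois = stage1_detect(x, FS)
        assert any(e.onset_sample < a + burst.size and a < e.offset_sample for e in eois)

    def test_nearby_ripples_merge_into_one_eoi(self):
        x = _noise(20.0, 1)
        b1 = _burst(140.0, 40.0, 20.0)
        a1 = int(10.0 * FS)
        a2 = a1 + b1.size + int(0.005 * FS)  # 5 ms gap < merge_gap_ms
        x[a1 : a1 + b1.size] += b1
        x[a2 : a2 + b1.size] += b1
        eois = stage1_detect(x, FS)
        hits = [e for e in eois if e.offset_sample > a1 and e.onset_sample < a2 + b1.size]
        assert len(hits) == 1

    def test_min_duration_filters_short_blips(self):
        x = _noise(20.0, 2)
        b = _burst(200.0, 8.0, 25.0)  # 8 ms, below min_duration_ms
        a = int(10.0 * FS)
        x[a : a + b.size] += b
        cfg = DetectorConfig(min_duration_ms=30.0)
        eois = stage1_detect(x, FS, cfg)
        assert not any(a <= e.onset_sample <= a + b.size for e in eois)


class TestStage2:
    def test_isolated_ripple_burst_kept(self):
        x = 0.2 * _noise(1.0, 3)
        b = _burst(130.0, 60.0, 10.0)
        a = int(0.5 * FS)
        x[a : a + b.size] += b
        eoi = EventOfInterest("F3-C3", a, a + b.size, 10.0)
        assert stage2_isolated_peak(eoi, x, FS)

    def test_filtered_spike_rejected(self):
        # band-limited click: monotonically decaying spectrum, no trough
        x = 0.2 * _noise(1.0, 4)
        t = np.arange(-0.05, 0.05, 1 / FS)
        spike = 40.0 * (-t / 0.005) * np.exp(-(t**2) / (2 * 0.005**2))
        a = int(0.5 * FS)
        x[a : a + spike.size] += spike
        mid = a + spike.size // 2
        eoi = EventOfInterest("F3-C3", mid - 20, mid + 20, 10.0)
        assert not stage2_isolated_peak(eoi, x, FS)

    def test_trough_ratio_boundary_is_inclusive(self):
        cfg = DetectorConfig()
        freqs = np.arange(10.0, 251.0, 2.0)
        profile = np.ones_like(freqs)
        profile[freqs <= 40.0] = 10.0
        peak = 8.0
        profile[np.argmin(np.abs(freqs - 150.0))] = peak
        trough_idx = np.argmin(np.abs(freqs - 60.0))
        profile[trough_idx] = cfg.stage2_trough_ratio * peak  # exactly at ratio
        assert isolated_peak_decision(freqs, profile, cfg)
        profile[trough_idx] = cfg.stage2_trough_ratio * peak * 1.001
        profile[freqs > 40.0] = np.maximum(
            profile[freqs > 40.0], cfg.stage2_trough_ratio * peak * 1.001
        )
        assert not isolated_peak_decision(freqs, profile, cfg)


def _hfo(channel, onset=1.0, offset=1.05, amp=15.0, snr=8.0, status="accepted"):
    return HfoEvent(channel, onset, offset, 120.0, 50.0, amp, snr, status)


class TestStage3:
    def test_amplitude_at_or_above_40_rejected(self):
        out = stage3_scalp_filter([_hfo("F3-C3", amp=45.0)], {})
        assert out[0].status == "rejected_amplitude"
        out = stage3_scalp_filter([_hfo("F3-C3", amp=40.0)], {})
        assert out[0].status == "rejected_amplitude"

    def test_boundary_semantics_as_printed(self):
        # amplitude 39.9 with SNR exactly 4 is accepted
        out = stage3_scalp_filter([_hfo("F3-C3", amp=39.9, snr=4.0)], {})
        assert out[0].status == "accepted"
        out = stage3_scalp_filter([_hfo("F3-C3", snr=3.99)], {})
        assert out[0].status == "rejected_snr"

    def test_bilateral_overlap_rejects_both_partners(self):
        hm = {"F3-T3": "F4-T4", "F4-T4": "F3-T3"}
        left = _hfo("F3-T3", onset=1.0, offset=1.05)
        right = _hfo("F4-T4", onset=1.049, offset=1.10)  # one shared instant
        out = stage3_scalp_filter([left, right], hm)
        assert [e.status for e in out] == ["rejected_bilateral"] * 2

    def test_touching_events_do_not_overlap(self):
        hm = {"F3-T3": "F4-T4", "F4-T4": "F3-T3"}
        left = _hfo("F3-T3", onset=1.0, offset=1.05)
        right = _hfo("F4-T4", onset=1.05, offset=1.10)  # half-open: no overlap
        out = stage3_scalp_filter([left, right], hm)
        assert [e.status for e in out] == ["accepted", "accepted"]

    def test_channel_without_homologue_has_no_partner(self):
        out = stage3_scalp_filter(
            [_hfo("Fz-Cz", onset=1.0), _hfo("Fz-Cz", onset=1.02)], {}
        )
        assert all(e.status == "accepted" for e in out)


def _inject_ripples(background, amps, channel="F3-C3", freq=120.0, dur=60.0):
    events = [
        GroundTruthEvent(channel, 3.0 + i * 5.5, dur, freq, float(a))
        for i, a in enumerate(amps)
    ]
    rec, truth = inject_events(background, events)
    return rec, truth


class TestDetectHfo:
    def test_silent_recording_yields_no_events(self, silent_recording):
        ivs = [DataInterval(0.0, silent_recording.duration_s)]
        assert detect_hfo(silent_recording, ivs) == []

    def test_no_intervals_is_an_error(self, silent_recording):
        with pytest.raises(InvalidConfigError):
            detect_hfo(silent_recording, [])

    def test_recall_and_precision_on_subset(
        self, background_subset_60s, interval_60s
    ):
        rec, truth = _inject_ripples(background_subset_60s, [15.0] * 10)
        dets = detect_hfo(rec, interval_60s)
        recall, precision, _ = match_events(dets, truth)
        assert recall >= 0.8
        assert precision >= 0.8

    def test_determinism(self, background_subset_60s, interval_60s):
        rec, _ = _inject_ripples(background_subset_60s, [15.0] * 3)
        assert detect_hfo(rec, interval_60s) == detect_hfo(rec, interval_60s)

    def test_accepted_events_satisfy_stage3_predicates(
        self, background_subset_60s, interval_60s
    ):
        rec, _ = _inject_ripples(background_subset_60s, [15.0, 25.0, 35.0, 45.0])
        for ev in detect_hfo(rec, interval_60s):
            if ev.accepted:
                assert ev.amplitude_uv < 40.0
                assert ev.snr >= 4.0
                assert 80.0 <= ev.frequency_hz <= 250.0

    def test_amplitude_doubling_flips_40uv_boundary(
        self, background_subset_60s, interval_60s
    ):
        rec, truth = _inject_ripples(background_subset_60s, [25.0] * 5)
        dets = {
            (round(d.onset_s, 1), d.channel): d
            for d in detect_hfo(rec, interval_60s)
            if d.channel == "F3-C3"
        }
        doubled = rec.copy()
        doubled.samples *= 2.0
        dets2 = {
            (round(d.onset_s, 1), d.channel): d
            for d in detect_hfo(doubled, interval_60s)
            if d.channel == "F3-C3"
        }
        common = set(dets) & set(dets2)
        assert common
        for key in common:
            a, b = dets[key], dets2[key]
            assert b.amplitude_uv == pytest.approx(2 * a.amplitude_uv, rel=0.15)
            if a.accepted and 20.0 <= a.amplitude_uv < 40.0 <= b.amplitude_uv:
                assert b.status == "rejected_amplitude"

    def test_recall_monotone_in_amplitude(self, background_subset_60s, interval_60s):
        recalls = []
        for amp in (10.0, 18.0, 30.0):
            rec, truth = _inject_ripples(background_subset_60s, [amp] * 8)
            r, _, _ = match_events(detect_hfo(rec, interval_60s), truth)
            recalls.append(r)
        assert recalls == sorted(recalls)

    def test_decoys_never_accepted(self, background_subset_60s, interval_60s):
        from scalphfo.montage import canonical_pair_name

        events = [
            GroundTruthEvent("F3-C3", 3.0 + i * 7.0, 60.0, 120.0, 15.0)
            for i in range(5)
        ]
        events += [
            GroundTruthEvent(
                "C3-P3", 5.0 + i * 11.0, 60.0, 130.0, 90.0,
                kind="high_amplitude_artifact",
            )
            for i in range(3)
        ]
        events += [
            GroundTruthEvent(
                "Fp1-F3", 8.0 + i * 11.0, 60.0, 110.0, 60.0,
                kind="bilateral_artifact",
            )
            for i in range(3)
        ]
        rec, truth = inject_events(background_subset_60s, events)
        accepted = [d for d in detect_hfo(rec, interval_60s) if d.accepted]
        for d in accepted:
            for t in truth:
                if t.kind == "ripple":
                    continue
                shares = set(canonical_pair_name(d.channel).split("-")) & set(
                    canonical_pair_name(t.channel).split("-")
                )
                overlaps = d.onset_s < t.offset_s and t.onset_s < d.offset_s
                assert not (shares and overlaps), f"decoy accepted: {d} vs {t}"
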