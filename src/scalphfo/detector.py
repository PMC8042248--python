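"""Three-stage automated ripple-band HFO detector for scalp EEG.

Stage I   -- baseline from high-Stockwell-entropy windows (low oscillatory
             activity), amplitude threshold on the smoothed Hilbert envelope
             of the band-passed trace; suprathreshold runs become events of
             interest (EoI).
Stage II  -- keep only EoI whose ripple-band time-frequency peak is isolated
             from low-frequency activity by a spectral trough.
Stage III -- scalp-specific rejection: peak-to-peak amplitude >= 40 uV, SNR
             < 4, or simultaneous occurrence on homologous channels of the
             two hemispheres (partial overlap in time).

Stage-I numeric constants are not pinned by the validation studies for this
montage and are exposed in :class:`DetectorConfig`; the printed constraints
(ripple band, 40 uV, SNR 4, overlap rule) are the defaults of Stage III.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import features as feat
from .filtering import bandpass_ripple, hilbert_envelope, smooth_envelope
from .montage import homologue_map, make_bipolar_montage
from .stockwell import stockwell_entropy, stockwell_power_profile
from .types import (
    ACCEPTED,
    REJECTED_AMPLITUDE,
    REJECTED_BILATERAL,
    REJECTED_EDGE,
    REJECTED_SNR,
    REJECTED_STAGE2,
    BaselineError,
    DataInterval,
    EventOfInterest,
    HfoEvent,
    InvalidConfigError,
    Recording,
)

__all__ = [
    "DetectorConfig",
    "stage1_detect",
    "stage2_isolated_peak",
    "stage3_scalp_filter",
    "detect_hfo",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of the three detection stages.

    The Stage-III constants (``amplitude_reject_uv``, ``snr_reject``, the
    band and the overlap rule) are the validated scalp criteria and should
    not normally be changed; Stage-I/II constants are implementation choices.
    """

    band_hz: tuple[float, float] = (80.0, 250.0)
    # Stage I
    entropy_window_s: float = 1.0
    baseline_entropy_quantile: float = 0.75
    baseline_statistic: str = "mean_sd"  # or "max"
    threshold_multiplier: float = 5.5  # threshold = mean + k*SD over baseline
    edge_multiplier: float = 1.0  # event delimitation threshold
    envelope_smooth_ms: float = 20.0
    min_duration_ms: float = 30.0
    min_oscillations: int = 3
    merge_gap_ms: float = 10.0
    crest_height_fraction: float = 0.25  # noise-crest floor for frequency
    # Stage II
    stage2_trough_ratio: float = 0.5
    stage2_low_band: tuple[float, float] = (10.0, 40.0)
    stage2_df_hz: float = 2.0
    stage2_context_s: float = 0.5
    # Stage III
    amplitude_reject_uv: float = 40.0
    snr_reject: float = 4.0
    snr_flank_s: float = 0.5
    min_flank_s: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.band_hz[0] < self.band_hz[1]:
            raise InvalidConfigError(f"bad band {self.band_hz}")
        if not 0 < self.baseline_entropy_quantile < 1:
            raise InvalidConfigError("baseline quantile must be in (0, 1)")
        if self.baseline_statistic not in ("mean_sd", "max"):
            raise InvalidConfigError("baseline_statistic must be mean_sd or max")


def _thresholds(
    baseline_smooth: np.ndarray, baseline_raw: np.ndarray, cfg: DetectorConfig
) -> tuple[float, float]:
    """Detection (smoothed-envelope) and delimitation (raw-envelope)
    thresholds from baseline envelope samples."""
    if cfg.baseline_statistic == "max":
        hi = cfg.threshold_multiplier * float(baseline_smooth.max())
        lo = 0.5 * hi
    else:
        hi = float(baseline_smooth.mean()) + cfg.threshold_multiplier * float(
            baseline_smooth.std()
        )
        lo = float(baseline_raw.mean()) + cfg.edge_multiplier * float(
            baseline_raw.std()
        )
    return hi, lo


def _suprathreshold_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs where the boolean mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def stage1_detect(
    signal: np.ndarray,
    fs: float,
    cfg: DetectorConfig = DetectorConfig(),
    channel: str = "",
) -> list[EventOfInterest]:
    """Stage I: entropy-baseline amplitude thresholding on one channel.

    Returns candidate events delimited at the lower edge threshold, merged
    across gaps shorter than ``merge_gap_ms`` and filtered for minimum
    duration and oscillation count.
    """
    signal = np.asarray(signal, dtype=float)
    bp = bandpass_ripple(signal, fs, cfg.band_hz)
    env_raw = hilbert_envelope(bp)
    env = smooth_envelope(env_raw, fs, cfg.envelope_smooth_ms)

    starts, ent = stockwell_entropy(signal, fs, cfg.entropy_window_s, cfg.band_hz)
    cut = np.quantile(ent, cfg.baseline_entropy_quantile)
    base_idx = np.flatnonzero(ent >= cut)
    if base_idx.size == 0:
        raise BaselineError("no high-entropy baseline window found")
    wlen = int(round(cfg.entropy_window_s * fs))
    base_slices = [slice(starts[i], starts[i] + wlen) for i in base_idx]
    thr_hi, thr_lo = _thresholds(
        np.concatenate([env[s] for s in base_slices]),
        np.concatenate([env_raw[s] for s in base_slices]),
        cfg,
    )

    # detect on the smoothed envelope at the high threshold, then delimit
    # each event on the raw envelope: walk outward to the edge threshold
    events: list[tuple[int, int]] = []
    for a, b in _suprathreshold_runs(env > thr_hi):
        while a > 0 and env_raw[a - 1] >= thr_lo:
            a -= 1
        while b < env_raw.size and env_raw[b] >= thr_lo:
            b += 1
        events.append((a, b))

    # merge runs separated by less than merge_gap_ms
    gap = int(round(cfg.merge_gap_ms / 1000.0 * fs))
    merged: list[list[int]] = []
    for a, b in events:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    min_len = int(round(cfg.min_duration_ms / 1000.0 * fs))
    out = []
    for a, b in merged:
        if b - a < min_len:
            continue
        seg = bp[a:b]
        crests = np.flatnonzero(
            (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] > 0)
        )
        if crests.size < cfg.min_oscillations:
            continue
        out.append(
            EventOfInterest(
                channel=channel,
                onset_sample=int(a),
                offset_sample=int(b),
                peak_envelope_uv=float(env_raw[a:b].max()),
            )
        )
    return out


def stage2_isolated_peak(
    eoi: EventOfInterest,
    signal: np.ndarray,
    fs: float,
    cfg: DetectorConfig = DetectorConfig(),
) -> bool:
    """Stage II: is the high-frequency peak isolated in time-frequency space?

    The S-transform power spectrum is averaged over the event span (within a
    context window) and the event is kept iff the trough between the
    low-frequency power maximum and the ripple-band peak is at most
    ``stage2_trough_ratio`` times the ripple peak power (boundary inclusive).
    A spectrum that decays monotonically into the ripple band -- a filtered
    sharp transient -- has no such trough and is rejected.
    """
    n = signal.size
    ctx = max(int(round(cfg.stage2_context_s * fs)), eoi.n_samples)
    mid = (eoi.onset_sample + eoi.offset_sample) // 2
    a = max(0, mid - ctx // 2)
    b = min(n, a + ctx)
    a = max(0, b - ctx)
    seg = signal[a:b]
    ev = slice(eoi.onset_sample - a, eoi.offset_sample - a)
    freqs, prof = stockwell_power_profile(
        seg, fs, cfg.stage2_low_band[0], cfg.band_hz[1], df=cfg.stage2_df_hz,
        t_slice=ev,
    )
    return isolated_peak_decision(freqs, prof, cfg)


def isolated_peak_decision(
    freqs: np.ndarray, profile: np.ndarray, cfg: DetectorConfig = DetectorConfig()
) -> bool:
    """The Stage-II predicate on a time-averaged power profile.

    Keep iff the minimum power between the low-frequency maximum and the
    ripple-band peak is at most ``stage2_trough_ratio`` times the ripple peak
    power; the boundary (trough exactly at the ratio) is kept.
    """
    in_ripple = freqs >= cfg.band_hz[0]
    in_low = freqs <= cfg.stage2_low_band[1]
    if not in_ripple.any() or not in_low.any():
        return True  # degenerate spectrum; nothing to compare against
    i_peak = np.flatnonzero(in_ripple)[np.argmax(profile[in_ripple])]
    i_low = np.flatnonzero(in_low)[np.argmax(profile[in_low])]
    between = profile[i_low + 1 : i_peak]
    if between.size == 0:
        return True
    trough = float(between.min())
    return trough <= cfg.stage2_trough_ratio * float(profile[i_peak])


def stage3_scalp_filter(
    events: Sequence[HfoEvent],
    homologues: dict[str, str] | None = None,
    amplitude_reject_uv: float = 40.0,
    snr_reject: float = 4.0,
) -> list[HfoEvent]:
    """Stage III: set the scalp-specific rejection status on each event.

    Precedence follows the criterion order: amplitude >= 40 uV, then SNR < 4,
    then bilateral co-occurrence (partial overlap in time on the homologous
    channel; both partners are rejected).  Channels without a homologue entry
    are treated as having no partner.  Events arriving with a non-accepted
    status (Stage-II or edge rejections) keep it, but still count as partners
    for the bilateral check.
    """
    if homologues is None:
        homologues = homologue_map()
    by_channel: dict[str, list[HfoEvent]] = {}
    for ev in events:
        by_channel.setdefault(ev.channel, []).append(ev)

    out = []
    for ev in events:
        status = ev.status
        if status == ACCEPTED:
            if ev.amplitude_uv >= amplitude_reject_uv:
                status = REJECTED_AMPLITUDE
            elif ev.snr < snr_reject:
                status = REJECTED_SNR
            else:
                partner_ch = homologues.get(ev.channel)
                partners = by_channel.get(partner_ch, []) if partner_ch else []
                if any(ev.overlaps(p) for p in partners):
                    status = REJECTED_BILATERAL
        out.append(replace_status(ev, status))
    return out


def replace_status(ev: HfoEvent, status: str) -> HfoEvent:
    return replace(ev, status=status)


def _characterize(
    eoi: EventOfInterest,
    bp: np.ndarray,
    fs: float,
    interval_start_s: float,
    cfg: DetectorConfig,
) -> HfoEvent:
    """Attach morphology features to a Stage-II-approved candidate."""
    a, b = eoi.onset_sample, eoi.offset_sample
    seg = bp[a:b]
    try:
        freq = feat.event_frequency(
            seg, fs, cfg.band_hz, min_height_fraction=cfg.crest_height_fraction
        )
    except Exception:
        freq = float("nan")
    flank = int(round(cfg.snr_flank_s * fs))
    min_flank = int(round(cfg.min_flank_s * fs))
    pre_avail = min(a, flank)
    post_avail = min(bp.size - b, flank)
    status = ACCEPTED
    if pre_avail < min_flank or post_avail < min_flank:
        status = REJECTED_EDGE
        snr = float("nan")
    else:
        snr = feat.event_snr(bp, a, b, fs, cfg.snr_flank_s)
    return HfoEvent(
        channel=eoi.channel,
        onset_s=interval_start_s + a / fs,
        offset_s=interval_start_s + b / fs,
        frequency_hz=freq,
        duration_ms=feat.event_duration_ms(a, b, fs),
        amplitude_uv=feat.event_amplitude(seg),
        snr=snr,
        status=status,
    )


def detect_hfo(
    rec: Recording,
    intervals: Sequence[DataInterval],
    cfg: DetectorConfig = DetectorConfig(),
) -> list[HfoEvent]:
    """Run the full Stage I -> II -> III pipeline over analysis intervals.

    The recording is re-referenced to the bipolar neighbour montage; each
    interval is processed independently per channel, and Stage III is applied
    across channels within the interval.  Deterministic for fixed input.
    """
    if not intervals:
        raise InvalidConfigError("need at least one analysis interval")
    if len(intervals) < 3:
        warnings.warn(
            f"only {len(intervals)} analysis interval(s); below the "
            "recommended minimum of three 5-min intervals"
        )
    pairs, signals = make_bipolar_montage(rec)
    homologues = homologue_map(pairs)
    all_events: list[HfoEvent] = []
    for iv in intervals:
        a = int(round(iv.start_s * rec.fs_hz))
        b = int(round(iv.end_s * rec.fs_hz))
        iv_events: list[HfoEvent] = []
        for pair, sig in zip(pairs, signals):
            seg = sig[a:b]
            if seg.size == 0:
                continue
            eois = stage1_detect(seg, rec.fs_hz, cfg, channel=pair.name)
            bp = bandpass_ripple(seg, rec.fs_hz, cfg.band_hz)
            for eoi in eois:
                ev = _characterize(eoi, bp, rec.fs_hz, iv.start_s, cfg)
                if ev.status == ACCEPTED and not stage2_isolated_peak(
                    eoi, seg, rec.fs_hz, cfg
                ):
                    ev = replace_status(ev, REJECTED_STAGE2)
                iv_events.append(ev)
        all_events.extend(
            stage3_scalp_filter(
                iv_events, homologues, cfg.amplitude_reject_uv, cfg.snr_reject
            )
        )
    for ev in all_events:  # postcondition: no accepted event violates Stage III
        if ev.accepted and not (
            ev.amplitude_uv < cfg.amplitude_reject_uv and ev.snr >= cfg.snr_reject
        ):
            raise RuntimeError(f"Stage III postcondition violated: {ev}")
    return all_events
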