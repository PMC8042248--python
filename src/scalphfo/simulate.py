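"""Synthetic multichannel scalp-EEG with known injected ripples.

The simulator emulates the N3-sleep substrate the detector runs on: a
1/f-weighted noise floor plus slow-wave (0.5-2 Hz) and spindle (11-15 Hz)
components, with the ripple-band RMS per channel pinned to a target value.
Injected events are Tukey-windowed sinusoids specified directly at a bipolar
derivation (half added to the anode, half subtracted at the cathode, so the
derivation sees exactly the stated peak-to-peak amplitude); decoy kinds
reproduce the two scalp artifact classes the detector must reject:

* ``high_amplitude_artifact`` -- in-band burst with band-passed peak-to-peak
  >= 40 uV (generator default 80-120 uV, so even half-amplitude leakage onto
  derivations sharing one electrode stays above the rejection limit);
* ``bilateral_artifact`` -- time-overlapping copies on homologous left/right
  derivations.

A cohort generator draws patient ages and imposes a decreasing HFO-rate-vs-
age law and a decreasing background-RMS-vs-age law, so the cohort statistics
layer can recover the negative rate-age and RBA-age correlations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .filtering import bandpass_ripple
from .montage import MONTAGE_ELECTRODES, canonical_pair_name, homologue_map, montage_pairs
from .types import (
    Annotation,
    GroundTruthEvent,
    InvalidConfigError,
    MontageError,
    PatientMeta,
    Recording,
)

__all__ = [
    "SimConfig",
    "CohortConfig",
    "generate_background",
    "inject_events",
    "draw_events",
    "generate_cohort",
    "match_events",
]


@dataclass(frozen=True)
class SimConfig:
    """Background-generation parameters.

    ``background_rms_uv`` is the target ripple-band (80-250 Hz) RMS per
    bipolar-difference-free electrode channel; slow-wave and spindle
    amplitudes are broadband additions with negligible ripple-band content.
    """

    labels: tuple[str, ...] = tuple(MONTAGE_ELECTRODES)
    fs_hz: float = 1024.0
    duration_s: float = 300.0
    background_rms_uv: float = 1.5
    one_over_f_exponent: float = 1.0
    slow_wave_uv: float = 40.0
    spindle_uv: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.fs_hz <= 2 * 250.0:
            raise InvalidConfigError("sampling rate below ripple-band Nyquist")
        if self.background_rms_uv <= 0:
            raise InvalidConfigError("background RMS must be positive")


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    return np.fft.irfft(spec, n=n)


def generate_background(config: SimConfig) -> Recording:
    """N3-like background: 1/f noise pinned to the target ripple-band RMS,
    plus slow waves and spindle bursts.  Fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    fs = config.fs_hz
    t = np.arange(n) / fs
    samples = np.empty((len(config.labels), n))
    for i in range(len(config.labels)):
        x = _one_over_f_noise(rng, n, fs, config.one_over_f_exponent)
        band = bandpass_ripple(x, fs)
        rms = np.sqrt(np.mean(band**2))
        x *= config.background_rms_uv / rms
        # slow waves: a few random-phase low-frequency components
        for _ in range(3):
            f0 = rng.uniform(0.5, 2.0)
            x += (config.slow_wave_uv / 3.0) * np.sin(
                2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi)
            )
        # spindles: 1-s bursts every ~10 s
        n_spindles = max(0, int(config.duration_s // 10))
        for _ in range(n_spindles):
            f0 = rng.uniform(11.0, 15.0)
            start = rng.uniform(0, max(config.duration_s - 1.0, 0.0))
            idx = slice(int(start * fs), int((start + 1.0) * fs))
            m = x[idx].size
            w = sps.windows.tukey(m, 0.5)
            x[idx] += config.spindle_uv * w * np.sin(2 * np.pi * f0 * t[:m])
        samples[i] = x
    rec = Recording(
        samples=samples,
        fs_hz=fs,
        labels=list(config.labels),
        annotations=[Annotation(0.0, config.duration_s, "N3")],
    )
    return rec


def _event_waveform(
    fs: float, duration_ms: float, frequency_hz: float, amplitude_uv: float
) -> np.ndarray:
    """Tukey(0.5)-windowed sinusoid with in-band peak-to-peak amplitude_uv."""
    n = max(4, int(round(duration_ms / 1000.0 * fs)))
    t = np.arange(n) / fs
    w = sps.windows.tukey(n, 0.5)
    return (amplitude_uv / 2.0) * w * np.sin(2 * np.pi * frequency_hz * t)


def _with_partners(events: list[GroundTruthEvent]) -> list[GroundTruthEvent]:
    """Ensure bilateral artifacts come in homologous, time-overlapping pairs."""
    hm = homologue_map()
    out = list(events)
    for e in events:
        if e.kind != "bilateral_artifact":
            continue
        partner_ch = hm.get(canonical_pair_name(e.channel))
        if partner_ch is None:
            continue
        if not any(
            o.kind == "bilateral_artifact"
            and canonical_pair_name(o.channel) == partner_ch
            and o.onset_s < e.offset_s
            and e.onset_s < o.offset_s
            for o in out
        ):
            out.append(replace(e, channel=partner_ch))
    return out


def inject_events(
    rec: Recording, events: list[GroundTruthEvent]
) -> tuple[Recording, list[GroundTruthEvent]]:
    """Add ground-truth events to a recording (returns a modified copy).

    Each event's waveform is split +/- between the anode and cathode of its
    bipolar derivation, so the derived signal carries the full stated
    amplitude.  Bilateral artifacts missing their homologous partner get one
    added (same parameters, mirrored channel).
    """
    fs = rec.fs_hz
    out = rec.copy()
    label_idx = {lab: i for i, lab in enumerate(out.labels)}
    events = _with_partners(events)
    for ev in events:
        name = canonical_pair_name(ev.channel)
        anode, cathode = name.split("-")
        if anode not in label_idx or cathode not in label_idx:
            raise MontageError(f"channel {ev.channel!r} not in recording")
        if ev.onset_s < 0 or ev.offset_s > rec.duration_s + 1e-9:
            raise InvalidConfigError(f"event at {ev.onset_s}s exceeds record bounds")
        if ev.kind == "ripple" and not 80.0 <= ev.frequency_hz <= 250.0:
            raise InvalidConfigError("ripple frequency outside 80-250 Hz")
        w = _event_waveform(fs, ev.duration_ms, ev.frequency_hz, ev.amplitude_uv)
        a = int(round(ev.onset_s * fs))
        b = min(a + w.size, out.n_times)
        out.samples[label_idx[anode], a:b] += w[: b - a] / 2.0
        out.samples[label_idx[cathode], a:b] -= w[: b - a] / 2.0
    return out, events


def draw_events(
    rng: np.random.Generator,
    duration_s: float,
    rate_per_min: float,
    channels: list[str] | None = None,
    focus_channel: str | None = None,
    focus_fraction: float = 0.7,
    frequency_hz: tuple[float, float] = (90.0, 200.0),
    duration_ms: tuple[float, float] = (24.0, 85.0),
    amplitude_uv: tuple[float, float] = (10.0, 34.0),
    kind: str = "ripple",
) -> list[GroundTruthEvent]:
    """Draw a Poisson event population, concentrated on a focus channel.

    Parameter ranges default to the event population reported for scalp
    ripples (durations ~24-85 ms, amplitudes below the 40 uV artifact limit).
    """
    if channels is None:
        channels = [p.name for p in montage_pairs()]
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    events = []
    for _ in range(n):
        if focus_channel is not None and rng.random() < focus_fraction:
            ch = focus_channel
        else:
            ch = channels[rng.integers(len(channels))]
        dur = rng.uniform(*duration_ms)
        onset = rng.uniform(0.5, duration_s - 0.5 - dur / 1000.0)
        events.append(
            GroundTruthEvent(
                channel=ch,
                onset_s=float(onset),
                duration_ms=float(dur),
                frequency_hz=float(rng.uniform(*frequency_hz)),
                amplitude_uv=float(rng.uniform(*amplitude_uv)),
                kind=kind,
            )
        )
    return events


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating laws.

    Rates follow ``rate0 * exp(-age/age_tau)`` HFO/min with lognormal noise;
    the background ripple-band RMS declines linearly with age.  Defaults give
    younger-vs-older medians and RBA values in the range reported for
    paediatric scalp EEG cohorts (rates ~0.1-13 HFO/min, RBA ~1-2 uV).
    """

    n_patients: int = 30
    age_range: tuple[float, float] = (0.7, 17.4)
    duration_s: float = 300.0
    labels: tuple[str, ...] = tuple(MONTAGE_ELECTRODES)
    rate0_per_min: float = 4.5
    age_tau_years: float = 5.5
    rate_noise_sigma: float = 0.4  # lognormal sigma; 0 = deterministic law
    rms0_uv: float = 1.9
    rms_slope_uv_per_year: float = -0.05
    rms_noise_sigma: float = 0.08
    freq0_hz: float = 130.0
    freq_slope_hz_per_year: float = -1.5
    include_decoys: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise InvalidConfigError("cohort needs at least 2 patients")


def generate_cohort(
    n_patients: int = 30,
    seed: int = 0,
    age_range: tuple[float, float] = (0.7, 17.4),
    config: CohortConfig | None = None,
) -> list[tuple[Recording, list[GroundTruthEvent], PatientMeta]]:
    """Generate a cohort of synthetic patients with age-dependent HFO rates.

    Returns one (recording, ground-truth events, metadata) triple per
    patient.  The metadata's ``extras``-free fields are drawn to resemble a
    mixed focal/generalized paediatric cohort.
    """
    cfg = config or CohortConfig(n_patients=n_patients, age_range=age_range)
    if cfg.n_patients < 2:
        raise InvalidConfigError("cohort needs at least 2 patients")
    rng = np.random.default_rng(seed)
    pairs = [p.name for p in montage_pairs() if set(p.name.split("-")) <= set(cfg.labels)]
    out = []
    ages = np.sort(rng.uniform(*cfg.age_range, size=cfg.n_patients))
    for i, age in enumerate(ages):
        true_rate = cfg.rate0_per_min * math.exp(-age / cfg.age_tau_years)
        if cfg.rate_noise_sigma > 0:
            true_rate *= math.exp(rng.normal(0.0, cfg.rate_noise_sigma))
        rms = cfg.rms0_uv + cfg.rms_slope_uv_per_year * age
        if cfg.rms_noise_sigma > 0:
            rms += rng.normal(0.0, cfg.rms_noise_sigma)
        rms = max(rms, 0.8)
        bg = generate_background(
            SimConfig(
                labels=cfg.labels,
                duration_s=cfg.duration_s,
                background_rms_uv=rms,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        fmid = float(np.clip(cfg.freq0_hz + cfg.freq_slope_hz_per_year * age, 95.0, 230.0))
        focus = pairs[rng.integers(len(pairs))]
        events = draw_events(
            rng,
            cfg.duration_s,
            true_rate,
            channels=pairs,
            focus_channel=focus,
            frequency_hz=(fmid - 15.0, fmid + 15.0),
        )
        if cfg.include_decoys:
            events += draw_events(
                rng, cfg.duration_s, 0.4, channels=pairs,
                amplitude_uv=(80.0, 120.0), kind="high_amplitude_artifact",
            )
            bilateral_pairs = sorted(homologue_map().keys())
            usable = [c for c in bilateral_pairs if c in pairs]
            if usable:
                events += draw_events(
                    rng, cfg.duration_s, 0.4, channels=usable,
                    amplitude_uv=(40.0, 80.0), kind="bilateral_artifact",
                )
        rec, truth = inject_events(bg, events)
        meta = PatientMeta(
            patient_id=f"sim{i + 1:03d}",
            age_years=float(age),
            sex=rng.choice(["F", "M"]),
            classification=rng.choice(["focal", "generalized"], p=[0.7, 0.3]),
            aetiology=rng.choice(["structural", "genetic", "unknown"], p=[0.6, 0.2, 0.2]),
            csws=bool(rng.random() < 0.13),
            seizures_per_month=float(10 ** rng.normal(1.0, 1.2)),
        )
        rec.meta = meta
        out.append((rec, truth, meta))
    return out


def match_events(
    detections,
    truth: list[GroundTruthEvent],
    kinds: tuple[str, ...] = ("ripple",),
) -> tuple[float, float, int]:
    """Overlap-based matching of accepted detections against ground truth.

    A detection matches a truth event when their time spans overlap and the
    detection's derivation shares an electrode with the truth derivation
    (injection leaks, at half amplitude, onto neighbouring derivations that
    share an electrode, so such detections reflect the same physical event).

    Returns ``(recall, precision, n_matched_truth)`` over truth events of the
    given kinds and accepted detections.
    """
    truth = [t for t in truth if t.kind in kinds]
    accepted = [d for d in detections if d.accepted]

    def electrodes(name: str) -> set[str]:
        return set(canonical_pair_name(name).split("-"))

    def matches(d, t) -> bool:
        return (
            d.onset_s < t.offset_s
            and t.onset_s < d.offset_s
            and bool(electrodes(d.channel) & electrodes(t.channel))
        )

    matched_truth = sum(1 for t in truth if any(matches(d, t) for d in accepted))
    matched_det = sum(1 for d in accepted if any(matches(d, t) for t in truth))
    recall = matched_truth / len(truth) if truth else float("nan")
    precision = matched_det / len(accepted) if accepted else float("nan")
    return recall, precision, matched_truth
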