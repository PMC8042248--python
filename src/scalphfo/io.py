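"""Reading and writing recordings, intervals and event tables.

EDF reading goes through :func:`mne.io.read_raw_edf`; writing uses a minimal
16-bit EDF writer (1-s data records) sufficient for round-tripping synthetic
recordings.  Sleep stages and artifact spans travel as a BIDS-style
tab-separated sidecar (``onset``/``duration``/``trial_type``) next to the
EDF, and patient metadata as a JSON sidecar.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .montage import normalize_label
from .types import (
    Annotation,
    AnnotationError,
    DataInterval,
    HfoEvent,
    InvalidConfigError,
    PatientMeta,
    Recording,
)

__all__ = [
    "write_edf",
    "load_recording",
    "select_intervals",
    "exclude_channels",
    "write_annotations",
    "write_meta",
    "events_to_frame",
    "write_events",
    "intervals_to_frame",
    "write_intervals",
]

_WAKE_LABELS = {"w", "wake"}
_SLEEP_LABELS = {"n1", "n2", "n3", "n4", "r", "rem"}
_ARTIFACT_TOKENS = ("artifact", "artefact", "bad")


def _fixed(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The duration is truncated to whole seconds (records must be complete).
    Physical units are microvolts; per-channel physical range is the data
    range, so quantization error is (max-min)/2^16 per channel.
    """
    path = Path(path)
    fs = rec.fs_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise InvalidConfigError("EDF writer requires an integer sampling rate")
    n_records = rec.n_times // spr
    if n_records == 0:
        raise InvalidConfigError("recording shorter than one 1-s EDF record")
    ns = len(rec.labels)
    data = rec.samples[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.maximum(phys_max - phys_min, 1e-6)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / span
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(rec.meta.patient_id or "X", 80),
            _fixed("synthetic", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(256 * (1 + ns), 8),
            _fixed("", 44),
            _fixed(n_records, 8),
            _fixed(1, 8),
            _fixed(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in rec.labels),
            b"".join(_fixed("AgAgCl electrode", 80) for _ in rec.labels),
            b"".join(_fixed("uV", 8) for _ in rec.labels),
            b"".join(_fixed(f"{phys_min[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_fixed(f"{phys_max[i]:.6g}"[:8], 8) for i in range(ns)),
            b"".join(_fixed(dig_min, 8) for _ in rec.labels),
            b"".join(_fixed(dig_max, 8) for _ in rec.labels),
            b"".join(_fixed("", 80) for _ in rec.labels),
            b"".join(_fixed(spr, 8) for _ in rec.labels),
            b"".join(_fixed("", 32) for _ in rec.labels),
        ]
    )
    with open(path, "wb") as f:
        f.write(header + sig)
        for r in range(n_records):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def write_annotations(path: str | Path, annotations: Sequence[Annotation]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "onset": [a.onset_s for a in annotations],
            "duration": [a.duration_s for a in annotations],
            "trial_type": [a.label for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def write_meta(path: str | Path, meta: PatientMeta) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(meta), indent=1))
    return path


def _sidecars_for(edf_path: Path) -> tuple[Path, Path]:
    stem = edf_path.with_suffix("")
    return Path(f"{stem}_events.tsv"), Path(f"{stem}_meta.json")


def load_recording(path: str | Path, dialect: str = "edf") -> Recording:
    """Load a recording from an EDF file or a BIDS-EEG style directory.

    Channel labels are normalized onto 10-20 electrode names (vendor
    prefixes/suffixes and case variants handled); unmappable channels are
    dropped.  Annotations are read from the EDF itself plus a
    ``*_events.tsv`` sidecar when present; patient metadata from a
    ``*_meta.json`` sidecar.
    """
    import mne

    path = Path(path)
    if dialect == "bids":
        if path.is_dir():
            candidates = sorted(path.rglob("*_eeg.edf")) or sorted(path.rglob("*.edf"))
            if not candidates:
                raise FileNotFoundError(f"no EDF file under {path}")
            path = candidates[0]
    elif dialect != "edf":
        raise InvalidConfigError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels, rows = [], []
    for i, ch in enumerate(raw.ch_names):
        norm = normalize_label(ch)
        if norm is not None and norm not in labels:
            labels.append(norm)
            rows.append(i)
    if not labels:
        raise AnnotationError("no channel label maps onto the 10-20 montage")
    samples = raw.get_data(picks=rows) * 1e6  # volts -> microvolts
    annotations = [
        Annotation(float(on), float(du), str(de))
        for on, du, de in zip(
            raw.annotations.onset, raw.annotations.duration, raw.annotations.description
        )
    ]
    ev_path, meta_path = _sidecars_for(path)
    if ev_path.exists():
        df = pd.read_csv(ev_path, sep="\t")
        col = "trial_type" if "trial_type" in df.columns else df.columns[-1]
        annotations += [
            Annotation(float(r["onset"]), float(r["duration"]), str(r[col]))
            for _, r in df.iterrows()
        ]
    meta = PatientMeta()
    if meta_path.exists():
        meta = PatientMeta(**json.loads(meta_path.read_text()))
    return Recording(
        samples=samples, fs_hz=float(raw.info["sfreq"]), labels=labels,
        annotations=annotations, meta=meta,
    )


def exclude_channels(rec: Recording, bad_labels: Sequence[str]) -> Recording:
    """Drop channels with continuous interference before montage building.

    An empty list is the identity; unknown labels are ignored.
    """
    if not bad_labels:
        return rec
    bad = {normalize_label(b) or b for b in bad_labels}
    keep = [i for i, lab in enumerate(rec.labels) if lab not in bad]
    return Recording(
        samples=rec.samples[keep],
        fs_hz=rec.fs_hz,
        labels=[rec.labels[i] for i in keep],
        annotations=list(rec.annotations),
        meta=rec.meta,
    )


def _subtract_spans(
    spans: list[tuple[float, float]], holes: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    out = spans
    for h0, h1 in holes:
        nxt = []
        for a, b in out:
            if h1 <= a or h0 >= b:
                nxt.append((a, b))
                continue
            if a < h0:
                nxt.append((a, h0))
            if h1 < b:
                nxt.append((h1, b))
        out = nxt
    return [(a, b) for a, b in out if b > a]


def select_intervals(
    rec: Recording,
    stage: str = "N3",
    first_hours: float = 3.0,
    interval_s: float = 300.0,
) -> list[DataInterval]:
    """Non-overlapping ``interval_s`` intervals of the requested sleep stage
    inside the first ``first_hours`` hours after sleep onset.

    Sleep onset is the start of the first scored non-wake epoch.  Annotated
    artifact spans are excluded; each artifact-free stage span is tiled from
    its own start and a residual shorter than ``interval_s`` is discarded.
    """
    stage_anns = [
        a for a in rec.annotations
        if a.label.strip().lower() in _WAKE_LABELS | _SLEEP_LABELS
    ]
    if not stage_anns:
        raise AnnotationError("recording has no sleep-stage annotations")
    sleep_onsets = [
        a.onset_s for a in stage_anns if a.label.strip().lower() not in _WAKE_LABELS
    ]
    if not sleep_onsets:
        return []
    t0 = min(sleep_onsets)
    t1 = min(t0 + first_hours * 3600.0, rec.duration_s)
    spans = [
        (max(a.onset_s, t0), min(a.onset_s + a.duration_s, t1))
        for a in stage_anns
        if a.label.strip().lower() == stage.strip().lower()
    ]
    spans = [(a, b) for a, b in spans if b > a]
    holes = [
        (a.onset_s, a.onset_s + a.duration_s)
        for a in rec.annotations
        if any(tok in a.label.lower() for tok in _ARTIFACT_TOKENS)
    ]
    spans = _subtract_spans(spans, holes)
    intervals = []
    for a, b in sorted(spans):
        k = math.floor((b - a) / interval_s + 1e-9)
        for j in range(k):
            s = a + j * interval_s
            intervals.append(
                DataInterval(s, s + interval_s, stage=stage, index=len(intervals))
            )
    return intervals


def events_to_frame(events: Sequence[HfoEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": [e.channel for e in events],
            "onset_s": [e.onset_s for e in events],
            "duration_ms": [e.duration_ms for e in events],
            "frequency_hz": [e.frequency_hz for e in events],
            "amplitude_uv": [e.amplitude_uv for e in events],
            "snr": [e.snr for e in events],
            "status": [e.status for e in events],
        }
    )


def write_events(path: str | Path, events: Sequence[HfoEvent]) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, sep="\t", index=False)
    return path


def intervals_to_frame(intervals: Sequence[DataInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [iv.index for iv in intervals],
            "start_s": [iv.start_s for iv in intervals],
            "end_s": [iv.end_s for iv in intervals],
            "stage": [iv.stage for iv in intervals],
        }
    )


def write_intervals(path: str | Path, intervals: Sequence[DataInterval]) -> Path:
    path = Path(path)
    intervals_to_frame(intervals).to_csv(path, sep="\t", index=False)
    return path
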