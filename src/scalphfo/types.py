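"""Core containers shared across the pipeline.

Conventions: samples are channels x time in microvolts, sample indices are
0-based, and event spans are half-open ``[onset, offset)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PatientMeta",
    "Recording",
    "Annotation",
    "DataInterval",
    "GroundTruthEvent",
    "EventOfInterest",
    "HfoEvent",
    "InvalidConfigError",
    "MontageError",
    "AnnotationError",
    "BaselineError",
    "EligibilityError",
    "UndefinedFrequencyError",
]


class InvalidConfigError(ValueError):
    """Raised for degenerate or out-of-range configuration values."""


class MontageError(ValueError):
    """Raised when a bipolar montage cannot be constructed."""


class AnnotationError(ValueError):
    """Raised when required annotations (sleep stages) are missing."""


class BaselineError(RuntimeError):
    """Raised when no low-activity baseline window can be found."""


class EligibilityError(ValueError):
    """Raised when a recording is too short for the requested analysis."""


class UndefinedFrequencyError(ValueError):
    """Raised when an event segment has too few crests to define a frequency."""


@dataclass
class PatientMeta:
    """Clinical metadata for one patient (cohort-table schema)."""

    patient_id: str = ""
    age_years: float = float("nan")
    sex: str = ""
    classification: str = ""  # "focal" | "generalized"
    aetiology: str = ""  # "structural" | "genetic" | "unknown"
    csws: bool = False
    seizures_per_month: float = float("nan")


@dataclass
class Annotation:
    onset_s: float
    duration_s: float
    label: str


@dataclass
class Recording:
    """Multichannel scalp EEG in referential (electrode) space.

    ``samples`` has shape (n_channels, n_times) in microvolts, one row per
    entry of ``labels`` (10-20 electrode names).
    """

    samples: np.ndarray
    fs_hz: float
    labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)
    meta: PatientMeta = field(default_factory=PatientMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidConfigError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.labels):
            raise InvalidConfigError(
                f"{self.samples.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise InvalidConfigError("channel labels must be unique")
        if self.fs_hz <= 0:
            raise InvalidConfigError("sampling rate must be positive")

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            labels=list(self.labels),
            annotations=list(self.annotations),
        )


@dataclass(frozen=True)
class DataInterval:
    """One artifact-free analysis interval, 300 s for the standard pipeline."""

    start_s: float
    end_s: float
    stage: str = "N3"
    index: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def minutes(self) -> float:
        return self.duration_s / 60.0


def total_minutes(intervals: Sequence[DataInterval]) -> float:
    return sum(iv.minutes for iv in intervals)


@dataclass(frozen=True)
class GroundTruthEvent:
    """Simulator-injected event, expressed at a bipolar derivation."""

    channel: str
    onset_s: float
    duration_ms: float
    frequency_hz: float
    amplitude_uv: float
    kind: str = "ripple"  # ripple | high_amplitude_artifact | bilateral_artifact

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_ms / 1000.0


@dataclass
class EventOfInterest:
    """Stage-I candidate on one bipolar channel (sample indices, half-open)."""

    channel: str
    onset_sample: int
    offset_sample: int
    peak_envelope_uv: float

    @property
    def n_samples(self) -> int:
        return self.offset_sample - self.onset_sample


# Stage-III / pipeline statuses
ACCEPTED = "accepted"
REJECTED_AMPLITUDE = "rejected_amplitude"
REJECTED_SNR = "rejected_snr"
REJECTED_BILATERAL = "rejected_bilateral"
REJECTED_STAGE2 = "rejected_stage2"
REJECTED_EDGE = "rejected_edge"


@dataclass
class HfoEvent:
    """One detected ripple-band event with its morphology features."""

    channel: str
    onset_s: float
    offset_s: float
    frequency_hz: float
    duration_ms: float
    amplitude_uv: float
    snr: float
    status: str = ACCEPTED

    @property
    def accepted(self) -> bool:
        return self.status == ACCEPTED

    def overlaps(self, other: "HfoEvent") -> bool:
        """Partial overlap in time on half-open spans (>= 1 shared instant)."""
        return self.onset_s < other.offset_s and other.onset_s < self.offset_s
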