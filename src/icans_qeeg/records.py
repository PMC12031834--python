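"""Core data containers: EEG records, assembled epochs, window sets, patient timelines.

Units: signals in microvolts (µV), sampling rates in Hz, time in seconds from
record start, and study time in days from the CAR T-cell infusion (day 0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The 19 scalp electrodes of the standard international 10-20 montage.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: EEG schedule labels relative to infusion (baseline ≈ 2-3 weeks before; T*n* =
#: n days after).
TIMEPOINTS = ("baseline", "T1", "T3", "T7", "T14", "extra")


@dataclass
class EEGRecord:
    """A multichannel scalp EEG recording.

    ``signal`` is a (channels, samples) float array in µV; ``channel_labels``
    follow the 10-20 naming of :data:`CHANNELS_1020`.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_1020
    patient_id: str = ""
    timepoint: str = "extra"
    record_date_offset: Optional[float] = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (channels, samples) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match signal rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """Artifact-free samples of a record, concatenated in temporal order."""

    signal: np.ndarray
    fs: float
    source_id: str = ""
    channel_labels: tuple[str, ...] = CHANNELS_1020

    @property
    def total_duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class EpochRejection:
    """Returned instead of an :class:`Epoch` when too little clean signal remains."""

    source_id: str
    reason: str
    clean_seconds: float


@dataclass
class WindowSet:
    """Overlapping analysis windows cut from an assembled epoch.

    ``windows`` has shape (n_windows, channels, round(T*fs)); consecutive
    windows are offset by exactly ``dt`` seconds in the parent epoch.
    """

    windows: np.ndarray
    fs: float
    T: float
    dt: float
    parent_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class PatientTimeline:
    """Infusion-anchored EEG schedule and outcome of one patient.

    Day 0 is the infusion. ``icans_day`` is the neurotoxicity onset day, or
    ``None`` if the patient is censored at ``censor_day``. EEGs recorded on or
    after ICANS onset are flagged in ``excluded`` (they describe manifest
    neurotoxicity, not its prodrome) and must not feed risk models.
    """

    patient_id: str
    eeg_days: list[float]
    grades: list[int]
    features: list  # per-EEG RecordFeatures (parallel to eeg_days)
    icans_day: Optional[float]
    censor_day: float
    forms: list = field(default_factory=list)        # per-EEG EEGEvalForm
    eeg_specs: list = field(default_factory=list)    # per-EEG EEGSimSpec
    covariates: dict = field(default_factory=dict)   # name -> per-EEG values or scalar

    def __post_init__(self):
        if self.icans_day is not None and not (0 <= self.icans_day <= self.censor_day):
            raise ValueError("icans_day must lie in [0, censor_day]")
        if list(self.eeg_days) != sorted(self.eeg_days):
            raise ValueError("eeg_days must be sorted")

    @property
    def event(self) -> bool:
        return self.icans_day is not None

    @property
    def end_day(self) -> float:
        """Event day if ICANS occurred, censoring day otherwise."""
        return self.icans_day if self.icans_day is not None else self.censor_day

    @property
    def excluded(self) -> list[bool]:
        """Per-EEG flag: recorded on/after ICANS onset, hence excluded."""
        if self.icans_day is None:
            return [False] * len(self.eeg_days)
        return [d >= self.icans_day for d in self.eeg_days]
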