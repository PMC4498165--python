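"""Core domain types for optetrode session analysis.

All times are in seconds on a single session clock; binning everywhere uses
half-open intervals ``[t, t + dt)``.  Voltages are in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np


class SchemaError(ValueError):
    """Raised when an input file or in-memory table violates the schema."""


class EventKind(str, Enum):
    """Kinds of timestamped behavioral / stimulation events."""

    LICK = "LICK"
    PULSE = "PULSE"
    TRAIN_ONSET = "TRAIN_ONSET"
    REWARD = "REWARD"
    BOUT_ONSET = "BOUT_ONSET"


class UnitLabel(str, Enum):
    """Optogenetic unit classes.

    AGRP
        driven by photostimulation (putative AgRP neuron),
    ARC_INH
        significantly suppressed by >20% (putative POMC-enriched class),
    ARC_OTHER
        not significantly modulated (or only weakly inhibited).
    """

    AGRP = "AGRP"
    ARC_INH = "ARC_INH"
    ARC_OTHER = "ARC_OTHER"


@dataclass
class RawTrace:
    """Multi-channel broadband voltage trace.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz, > 0.
    channel_ids : sequence of str
        Ordered channel labels, one per row of ``samples``.
    t0 : float
        Session-clock time of the first sample (s).
    """

    samples: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise SchemaError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise SchemaError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise SchemaError("trace contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return self.n_samples / self.fs

    def time_axis(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class SpikeTrain:
    """Sorted spike times for one unit, with optional waveforms/features.

    ``waveforms`` holds a 1-ms snippet per spike and channel, shape
    ``(n_spikes, n_channels, n_waveform_samples)``.  ``features`` holds the
    per-channel peak and valley amplitudes, shape ``(n_spikes, 2 * n_channels)``
    (8 values per spike on a tetrode).
    """

    unit_id: str
    times: np.ndarray
    waveforms: Optional[np.ndarray] = None
    features: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise SchemaError("spike times must be a 1-d array")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise SchemaError(
                f"unit {self.unit_id}: spike times must be strictly increasing"
            )
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)
            if self.waveforms.shape[0] != self.times.size:
                raise SchemaError("one waveform per spike required")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != self.times.size:
                raise SchemaError("one feature row per spike required")
            if self.features.size and not np.all(np.isfinite(self.features)):
                raise SchemaError("features must be finite")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def isis(self) -> np.ndarray:
        """Inter-spike intervals in seconds."""
        return np.diff(self.times)

    def shifted(self, offset: float) -> "SpikeTrain":
        """Return a copy with a constant added to every spike time."""
        return SpikeTrain(self.unit_id, self.times + offset,
                          self.waveforms, self.features)


@dataclass
class EventSeries:
    """Timestamped events of one kind (licks, laser pulses, rewards, ...)."""

    kind: EventKind
    times: np.ndarray
    durations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < 0):
            bad = int(np.argmax(np.diff(self.times) < 0)) + 1
            raise SchemaError(
                f"{self.kind.value} events: times decrease at row {bad}"
            )
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=float)
            if self.durations.shape != self.times.shape:
                raise SchemaError("one duration per event required")
            if np.any(self.durations < 0):
                raise SchemaError("event durations must be >= 0")

    @property
    def n_events(self) -> int:
        return self.times.size


@dataclass
class SessionTimeline:
    """Named epoch boundaries of a feeding session (session clock, s).

    A feeding session runs baseline -> lickspout placement -> food available
    -> session end.  At least 5 min of baseline must be available before the
    lickspout time.
    """

    baseline_start: float
    lickspout_time: float
    food_time: float
    session_end: float
    phase: Optional[str] = None  # "AM" or "PM"

    def __post_init__(self) -> None:
        if not (self.baseline_start < self.lickspout_time
                < self.food_time <= self.session_end):
            raise SchemaError(
                "timeline must satisfy baseline_start < lickspout_time "
                "< food_time <= session_end"
            )
        if self.phase is not None and self.phase not in ("AM", "PM"):
            raise SchemaError(f"phase must be AM or PM, got {self.phase!r}")

    @property
    def baseline_span(self) -> float:
        return self.lickspout_time - self.baseline_start


@dataclass
class UnitClassification:
    """Outcome of the optogenetic classification of one unit."""

    unit_id: str
    label: UnitLabel
    t_stat: float = np.nan
    p_first_half: float = np.nan
    p_second_half: float = np.nan
    suppression_fraction: float = np.nan
    sustained_ks_p: float = np.nan
    waveform_xcorr: float = np.nan
    entrained_bins: list = field(default_factory=list)
    weak_inhibition_flag: bool = False
    sustained_flag: bool = False

    def __post_init__(self) -> None:
        self.label = UnitLabel(self.label)
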