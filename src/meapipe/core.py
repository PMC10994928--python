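"""Core containers for multi-well MEA recordings.

The experimental unit is a *well* of a multi-well MEA plate (24 wells with 12
embedded extracellular electrodes each).  A well is recorded for 10 minutes at
each timepoint; each electrode yields either a raw voltage trace sampled at
10 kHz or, after spike detection, a sorted list of spike times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["VoltageTrace", "SpikeTrain", "WellRecording"]


@dataclass
class VoltageTrace:
    """One electrode's extracellular voltage signal.

    Parameters
    ----------
    samples
        Signal in microvolts.
    sampling_rate
        Samples per second (default 10 kHz, the acquisition rate of the
        multi-well system this pipeline targets).
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    electrode_id: str = "e00"
    well_id: str = "w00"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds) for one electrode."""

    times: np.ndarray
    duration: float
    electrode_id: str = "e00"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def firing_rate(self) -> float:
        """Mean rate over the full duration, spikes/s."""
        return self.n_spikes / self.duration

    def shifted(self, offset: float) -> "SpikeTrain":
        """Same train translated in time (must stay inside the recording)."""
        return SpikeTrain(self.times + offset, self.duration, self.electrode_id)


@dataclass
class WellRecording:
    """Spike trains of all electrodes of one well at one timepoint.

    ``duration`` is the *analyzed* duration: masking stimulation windows
    returns a new recording with spikes on a compressed timeline and a
    correspondingly shorter duration, so every downstream rate uses the
    correct denominator.
    """

    trains: Mapping[str, SpikeTrain]
    duration: float
    well_id: str = "w00"
    condition: str = "untreated"
    timepoint_h: float = 0.0
    stimulation_epochs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trains = dict(self.trains)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for eid, train in self.trains.items():
            if train.duration > self.duration + 1e-9:
                raise ValueError(
                    f"train {eid} outlives the recording "
                    f"({train.duration} s > {self.duration} s)"
                )
        for start, end in self.stimulation_epochs:
            if not (0 <= start < end <= self.duration + 1e-9):
                raise ValueError("stimulation epoch outside recording bounds")

    @property
    def electrode_ids(self) -> list:
        return list(self.trains)

    @property
    def n_electrodes(self) -> int:
        return len(self.trains)

    def spike_counts(self) -> dict:
        return {eid: t.n_spikes for eid, t in self.trains.items()}


def electrode_ids(n: int) -> list:
    """Canonical electrode labels ``e00`` .. ``e{n-1}``."""
    return [f"e{i:02d}" for i in range(n)]


def iter_trains(recordings: Iterable[WellRecording]):
    for rec in recordings:
        for train in rec.trains.values():
            yield rec, train
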