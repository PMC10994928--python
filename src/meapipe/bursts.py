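"""Single-channel burst and network-burst detection.

Single-channel bursts use a fixed-parameter max-interval scheme: a burst
opens at a spike pair with inter-spike interval (ISI) <= ``start_isi_max``
(50 ms) and extends while ISIs stay <= ``continue_isi_max`` (100 ms).
Candidate bursts separated by less than ``min_interburst_interval`` (100 ms)
are merged, then candidates with fewer than ``min_spikes`` (4) spikes or
shorter than ``min_burst_duration`` (50 ms) are discarded.

A network burst is a chain of single-channel bursts connected by strictly
positive temporal overlap, provided the chain spans at least
``nb_min_channels`` (8) distinct electrodes and at some instant at least
``nb_min_simultaneous`` (8) bursts are open concurrently.  Zero-length
contact between bursts does not count as overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence

import numpy as np

from .core import SpikeTrain, WellRecording
from .spikes import DetectionConfig, classify_active_electrodes, mean_firing_rate

__all__ = [
    "BurstConfig",
    "BurstInterval",
    "NetworkBurstEvent",
    "WellMetrics",
    "detect_channel_bursts",
    "classify_bursting_channels",
    "detect_network_bursts",
    "well_metrics",
]

# absolute slack on inclusive comparisons of times built by float arithmetic
_EPS = 1e-9


@dataclass(frozen=True)
class BurstConfig:
    min_spikes: int = 4
    start_isi_max: float = 0.050
    continue_isi_max: float = 0.100
    min_interburst_interval: float = 0.100
    min_burst_duration: float = 0.050
    bursting_channel_rate: float = 0.4  # bursts/min
    nb_min_channels: int = 8
    nb_min_simultaneous: int = 8

    def __post_init__(self) -> None:
        if self.start_isi_max > self.continue_isi_max:
            raise ValueError("start_isi_max must be <= continue_isi_max")
        for name in (
            "start_isi_max",
            "continue_isi_max",
            "min_interburst_interval",
            "min_burst_duration",
            "bursting_channel_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be at least 2")


@dataclass(frozen=True)
class BurstInterval:
    electrode_id: str
    start: float
    end: float
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("burst end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class NetworkBurstEvent:
    start: float
    end: float
    channels: FrozenSet[str]
    max_simultaneous: int

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class WellMetrics:
    """Per-well summary at one timepoint.

    ``nbd`` is NaN when the well shows no network bursts: the mean duration
    of zero events is undefined, and the flag propagates into normalization.
    """

    well_id: str
    condition: str
    timepoint_h: float
    mfr: float  # spikes/s over active electrodes
    nbr: float  # network bursts / min
    nbd: float  # mean network-burst duration, s (NaN if no events)
    n_active: int
    n_bursting: int
    n_network_bursts: int
    analyzed_duration: float
    extras: dict = field(default_factory=dict)


def detect_channel_bursts(train: SpikeTrain, cfg: BurstConfig = BurstConfig()) -> List[BurstInterval]:
    """Max-interval burst detection on one electrode's spike train."""
    t = train.times
    if t.size < 2:
        return []
    isi = np.diff(t)
    cont = isi <= cfg.continue_isi_max + _EPS

    # maximal runs of ISIs <= continue_isi_max
    candidates: List[tuple] = []  # (first_spike_idx, last_spike_idx) inclusive
    edges = np.diff(cont.astype(np.int8))
    run_starts = list(np.flatnonzero(edges == 1) + 1)
    run_ends = list(np.flatnonzero(edges == -1) + 1)
    if cont[0]:
        run_starts.insert(0, 0)
    if cont[-1]:
        run_ends.append(isi.size)
    for rs, re in zip(run_starts, run_ends):
        # burst opens at the first ISI in the run that meets the start limit
        seg = isi[rs:re]
        ok = np.flatnonzero(seg <= cfg.start_isi_max + _EPS)
        if ok.size == 0:
            continue
        k = rs + int(ok[0])
        candidates.append((k, re))  # spikes k .. re inclusive

    if not candidates:
        return []

    # merge candidates separated by < min_interburst_interval, then filter
    merged: List[tuple] = [candidates[0]]
    for a, b in candidates[1:]:
        pa, pb = merged[-1]
        if t[a] - t[pb] < cfg.min_interburst_interval - _EPS:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))

    bursts: List[BurstInterval] = []
    for a, b in merged:
        n = b - a + 1
        dur = t[b] - t[a]
        if n >= cfg.min_spikes and dur >= cfg.min_burst_duration - _EPS:
            bursts.append(BurstInterval(train.electrode_id, float(t[a]), float(t[b]), n))
    return bursts


def classify_bursting_channels(
    bursts_by_channel: Mapping[str, Sequence[BurstInterval]],
    analyzed_duration: float,
    cfg: BurstConfig = BurstConfig(),
) -> set:
    """Channels with at least ``cfg.bursting_channel_rate`` bursts/min
    (inclusive boundary)."""
    if analyzed_duration <= 0:
        raise ValueError("analyzed duration must be positive")
    minutes = analyzed_duration / 60.0
    return {
        ch
        for ch, bursts in bursts_by_channel.items()
        if len(bursts) / minutes >= cfg.bursting_channel_rate - _EPS
    }


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def detect_network_bursts(
    bursts_by_channel: Mapping[str, Sequence[BurstInterval]],
    cfg: BurstConfig = BurstConfig(),
) -> List[NetworkBurstEvent]:
    """Chain single-channel bursts into network-burst events.

    Two bursts are chained when their temporal overlap is strictly positive
    (open intervals; endpoint contact is not overlap).  Each connected chain
    becomes an event if it covers >= ``nb_min_channels`` distinct electrodes
    and its boundary sweep reaches >= ``nb_min_simultaneous`` concurrently
    open bursts.  Event span is [earliest start, latest end] of the chain.
    """
    flat: List[BurstInterval] = [b for bs in bursts_by_channel.values() for b in bs]
    if not flat:
        return []
    flat.sort(key=lambda b: (b.start, b.end))
    n = len(flat)
    uf = _UnionFind(n)

    # sweep: when burst i begins, every still-open earlier burst overlaps it
    open_heap: List[tuple] = []  # (end, idx), kept sorted lazily via heapq
    import heapq

    for i, b in enumerate(flat):
        while open_heap and open_heap[0][0] <= b.start + _EPS:
            heapq.heappop(open_heap)
        for _, j in open_heap:
            uf.union(i, j)
        heapq.heappush(open_heap, (b.end, i))

    components: Dict[int, List[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)

    events: List[NetworkBurstEvent] = []
    for idxs in components.values():
        channels = frozenset(flat[i].electrode_id for i in idxs)
        if len(channels) < cfg.nb_min_channels:
            continue
        # boundary sweep; at equal times close before open (open intervals)
        bounds = []
        for i in idxs:
            bounds.append((flat[i].start, 1))
            bounds.append((flat[i].end, -1))
        bounds.sort(key=lambda p: (p[0], p[1]))
        depth = max_depth = 0
        for _, d in bounds:
            depth += d
            max_depth = max(max_depth, depth)
        if max_depth < cfg.nb_min_simultaneous:
            continue
        start = min(flat[i].start for i in idxs)
        end = max(flat[i].end for i in idxs)
        events.append(NetworkBurstEvent(start, end, channels, max_depth))

    events.sort(key=lambda e: e.start)
    return events


def well_metrics(
    well: WellRecording,
    cfg: BurstConfig = BurstConfig(),
    det_cfg: DetectionConfig = DetectionConfig(),
) -> WellMetrics:
    """MFR, NBR and NBD for one well recording.

    NBR is reported per minute of analyzed duration; NBD is the arithmetic
    mean of event durations (NaN when no events).  The caller is responsible
    for masking stimulation windows first (see
    :func:`meapipe.timecourse.mask_stimulation_windows`).
    """
    if well.duration <= 0:
        raise ValueError("analyzed duration must be positive")
    bursts_by_channel = {
        eid: detect_channel_bursts(train, cfg) for eid, train in well.trains.items()
    }
    active = classify_active_electrodes(well, det_cfg)
    bursting = classify_bursting_channels(bursts_by_channel, well.duration, cfg)
    events = detect_network_bursts(bursts_by_channel, cfg)
    minutes = well.duration / 60.0
    nbr = len(events) / minutes
    nbd = float(np.mean([e.duration for e in events])) if events else float("nan")
    return WellMetrics(
        well_id=well.well_id,
        condition=well.condition,
        timepoint_h=well.timepoint_h,
        mfr=mean_firing_rate(well, det_cfg),
        nbr=nbr,
        nbd=nbd,
        n_active=len(active),
        n_bursting=len(bursting),
        n_network_bursts=len(events),
        analyzed_duration=well.duration,
    )
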