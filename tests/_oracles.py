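"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's sweep-line implementation: the
network-burst oracle works on a 1 ms time grid and chains bursts through
shared grid midpoints, which for ms-grid burst intervals is equivalent to
strictly-positive temporal overlap.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np

from meapipe.bursts import BurstConfig, BurstInterval


def grid_network_bursts(
    bursts_by_channel: Dict[str, Sequence[BurstInterval]],
    cfg: BurstConfig,
    dt: float = 0.001,
) -> List[Tuple[float, frozenset, int]]:
    """Grid-based network-burst detection: (start, channels, max_simultaneous).

    Counts, at every grid midpoint, how many bursts strictly contain it;
    bursts sharing a midpoint are chained (union-find); a chain is an event
    when it spans >= cfg.nb_min_channels distinct channels and some midpoint
    is covered by >= cfg.nb_min_simultaneous bursts.  Exact for burst
    endpoints lying on the dt grid.
    """
    flat = [b for bs in bursts_by_channel.values() for b in bs]
    if not flat:
        return []
    t0 = min(b.start for b in flat)
    t1 = max(b.end for b in flat)
    grid = np.arange(t0, t1, dt) + dt / 2.0
    cover = np.zeros((len(flat), grid.size), dtype=bool)
    for i, b in enumerate(flat):
        cover[i] = (grid > b.start) & (grid < b.end)

    parent = list(range(len(flat)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for g in range(grid.size):
        idx = np.flatnonzero(cover[:, g])
        for a, b2 in zip(idx, idx[1:]):
            ra, rb = find(a), find(b2)
            if ra != rb:
                parent[rb] = ra

    comps: Dict[int, list] = {}
    for i in range(len(flat)):
        comps.setdefault(find(i), []).append(i)

    events = []
    for idxs in comps.values():
        chans = frozenset(flat[i].electrode_id for i in idxs)
        if len(chans) < cfg.nb_min_channels:
            continue
        sim = int(cover[idxs].sum(axis=0).max())
        if sim < cfg.nb_min_simultaneous:
            continue
        events.append((min(flat[i].start for i in idxs), chans, sim))
    return sorted(events)


def random_burst_well(
    rng: np.random.Generator,
    n_channels: int = 12,
    max_bursts_per_channel: int = 5,
    duration: float = 60.0,
) -> Dict[str, List[BurstInterval]]:
    """Random per-channel burst lists on a 1 ms grid.

    Within-channel bursts are disjoint with gaps >= 100 ms, as the channel
    burst detector guarantees; start times cluster so cross-channel overlap
    chains actually occur.
    """
    out: Dict[str, List[BurstInterval]] = {}
    # a few "hotspots" make multi-channel overlap likely
    hotspots = rng.uniform(1.0, duration - 2.0, rng.integers(1, 5))
    for c in range(n_channels):
        eid = f"e{c:02d}"
        bursts = []
        cursor = 0.0
        for _ in range(rng.integers(0, max_bursts_per_channel + 1)):
            if rng.random() < 0.7 and hotspots.size:
                center = hotspots[rng.integers(hotspots.size)]
                start = center + rng.integers(-300, 300) / 1000.0
            else:
                start = rng.uniform(0.5, duration - 1.0)
            start = max(start, cursor + 0.1)
            start = round(start * 1000) / 1000.0
            dur = rng.integers(50, 400) / 1000.0
            if start + dur > duration:
                continue
            bursts.append(BurstInterval(eid, start, start + dur, int(rng.integers(4, 20))))
            cursor = start + dur
        out[eid] = bursts
    return out
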