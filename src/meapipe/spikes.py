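"""Spike detection on extracellular MEA traces.

The detection scheme follows the standard multi-well analyzer convention:
band-pass the raw signal (100--3500 Hz), estimate the baseline noise standard
deviation robustly, and call a spike wherever the signal makes an excursion
beyond ``threshold_multiplier`` times that SD (4.5 by default).  Electrodes
firing at >= 0.1 spikes/s count as *active*; the well's mean firing rate (MFR)
averages spikes/s over active electrodes only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Set, Tuple

import numpy as np
from scipy import signal

from .core import SpikeTrain, VoltageTrace, WellRecording

__all__ = [
    "DetectionConfig",
    "band_pass_filter",
    "estimate_noise_sd",
    "detect_spikes",
    "classify_active_electrodes",
    "mean_firing_rate",
]

#: MAD -> Gaussian SD scale factor, 1 / Phi^-1(3/4)
_MAD_SCALE = 1.482602218505602


@dataclass(frozen=True)
class DetectionConfig:
    """Spike-detection parameters.

    Attributes
    ----------
    threshold_multiplier
        Amplitude threshold as a multiple of the baseline-noise SD.
    filter_band
        Band-pass corner frequencies in Hz.
    dead_time
        Events closer than this are collapsed to the first (seconds).
    active_rate_threshold
        Minimum firing rate (spikes/s) for an electrode to count as active.
    polarity
        Which threshold excursions count: "negative", "positive" or "both".
    apply_filter
        If False the trace is taken as already band-passed.
    noise_sd
        Optional precomputed baseline-noise SD (microvolts); when None the SD
        is estimated from the trace itself.
    """

    threshold_multiplier: float = 4.5
    filter_band: Tuple[float, float] = (100.0, 3500.0)
    dead_time: float = 0.001
    active_rate_threshold: float = 0.1
    polarity: str = "both"
    filter_order: int = 4
    apply_filter: bool = True
    noise_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        lo, hi = self.filter_band
        if not (0 < lo < hi):
            raise ValueError("filter_band must satisfy 0 < low < high")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")


def band_pass_filter(
    trace: VoltageTrace,
    band: Optional[Tuple[float, float]] = None,
    order: int = 4,
) -> VoltageTrace:
    """Zero-phase Butterworth band-pass; preserves length and spike timing.

    Forward-backward filtering (``sosfiltfilt``) is used so detected spike
    times are not biased by filter group delay.
    """
    if band is None:
        band = (100.0, 3500.0)
    lo, hi = band
    nyq = trace.sampling_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} invalid for Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def estimate_noise_sd(trace) -> float:
    """Robust baseline-noise SD (microvolts).

    Median absolute deviation scaled to the Gaussian SD; insensitive to the
    small fraction of samples occupied by spikes.  An all-constant trace
    yields 0.
    """
    x = trace.samples if isinstance(trace, VoltageTrace) else np.asarray(trace, dtype=float)
    mad = np.median(np.abs(x - np.median(x)))
    return float(mad * _MAD_SCALE)


def detect_spikes(trace: VoltageTrace, cfg: DetectionConfig = DetectionConfig()) -> SpikeTrain:
    """Threshold-crossing spike detection on one electrode.

    Each contiguous supra-threshold excursion yields one event timed at its
    extremum sample; events closer than ``cfg.dead_time`` are collapsed to
    the first, so a biphasic waveform crossing both polarities is counted
    once.
    """
    work = band_pass_filter(trace, cfg.filter_band, cfg.filter_order) if cfg.apply_filter else trace
    x = work.samples
    sd = cfg.noise_sd if cfg.noise_sd is not None else estimate_noise_sd(x)
    thr = cfg.threshold_multiplier * sd

    if thr == 0:
        # degenerate flat trace: nothing to detect against
        return SpikeTrain(np.empty(0), trace.duration, trace.electrode_id)

    if cfg.polarity == "negative":
        above = x < -thr
    elif cfg.polarity == "positive":
        above = x > thr
    else:
        above = np.abs(x) > thr

    if not above.any():
        return SpikeTrain(np.empty(0), trace.duration, trace.electrode_id)

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [x.size]))

    peak_idx = np.array(
        [s + int(np.argmax(np.abs(x[s:e]))) for s, e in zip(starts, ends)], dtype=np.int64
    )
    times = peak_idx / trace.sampling_rate

    # dead-time collapse: keep the first event of each close-spaced group
    if times.size > 1 and cfg.dead_time > 0:
        keep = [0]
        for i in range(1, times.size):
            if times[i] - times[keep[-1]] >= cfg.dead_time:
                keep.append(i)
        times = times[keep]

    times = np.clip(times, 0.0, trace.duration)
    return SpikeTrain(times, trace.duration, trace.electrode_id)


def classify_active_electrodes(
    well: WellRecording, cfg: DetectionConfig = DetectionConfig()
) -> Set[str]:
    """Electrodes whose firing rate over the analyzed duration is at least
    ``cfg.active_rate_threshold`` spikes/s (inclusive)."""
    if well.duration <= 0:
        raise ValueError("analyzed duration must be positive")
    return {
        eid
        for eid, train in well.trains.items()
        if train.n_spikes / well.duration >= cfg.active_rate_threshold
    }


def mean_firing_rate(well: WellRecording, cfg: DetectionConfig = DetectionConfig()) -> float:
    """Mean firing rate (MFR) of a well, spikes/s.

    Average of spikes/s per electrode over *active* electrodes only; defined
    as 0 when no electrode is active, so a fully silenced well normalizes
    to 0 rather than being dropped.
    """
    active = classify_active_electrodes(well, cfg)
    if not active:
        return 0.0
    rates = [well.trains[eid].n_spikes / well.duration for eid in active]
    return float(np.mean(rates))
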