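"""Synthetic MEA recordings and viability micrographs with known ground truth.

The generator states a simple world matching what the analysis assumes:

* per-electrode background activity is a homogeneous Poisson process;
* network bursts arrive as a Poisson process per well; each event recruits
  each electrode independently and drives a short high-frequency spike run
  (gamma-distributed ISIs, mean 20 ms -- comfortably inside the burst
  detector's ISI window, so detectability is a property of the detector, not
  of generator marginality);
* hypoxia acts through a :class:`TreatmentProfile`: time-dependent
  multipliers on firing rate (MFR), network-burst rate (NBR) and
  network-burst duration (NBD), all equal to 1 at the normoxia baseline;
* viability micrographs place Gaussian-blob nuclei (overlap capped by
  rejection sampling) into a nuclei channel, an apoptosis-reporter channel
  and a death-reporter channel.

Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import SpikeTrain, VoltageTrace, WellRecording, electrode_ids

__all__ = [
    "SimulationConfig",
    "TreatmentProfile",
    "GroundTruth",
    "NetworkBurstTruth",
    "ImageSimConfig",
    "CellImageSet",
    "untreated_profile",
    "neuro_activation_profile",
    "astro_activation_profile",
    "lactate_profile",
    "simulate_well",
    "simulate_plate",
    "simulate_timecourse",
    "render_voltage_trace",
    "biphasic_template",
    "simulate_viability_image",
]


class ParameterError(ValueError):
    """A profile or config produced an invalid parameter value."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated well.

    Defaults emulate a functionally mature culture on a 24-well MEA plate:
    12 electrodes per well, 10-minute recordings, ~2 spikes/s spontaneous
    background per electrode and ~6 network bursts/min of ~1 s duration.
    """

    n_wells: int = 24
    electrodes_per_well: int = 12
    recording_duration: float = 600.0
    background_rate: float = 2.0  # spikes/s per electrode
    nb_rate: float = 6.0  # network bursts / min
    nb_duration_mean: float = 1.0  # s
    nb_participation: float = 0.9  # probability per electrode per event
    intra_burst_isi_mean: float = 0.020  # s
    isi_gamma_shape: float = 5.0
    stim_rate_boost: float = 2.0  # background-rate factor inside stimulation epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.electrodes_per_well < 1:
            raise ValueError("electrodes_per_well must be >= 1")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        for name in ("recording_duration", "nb_duration_mean", "intra_burst_isi_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_rate", "nb_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.nb_participation <= 1:
            raise ValueError("nb_participation must be in [0, 1]")


@dataclass(frozen=True)
class TreatmentProfile:
    """Hypoxia response of one experimental condition.

    Each multiplier maps hours-in-hypoxia to a non-negative factor applied
    to the baseline value of the corresponding metric; all multipliers equal
    1 at t = 0 (normoxia).  ``stimulated`` marks optogenetic-activation
    conditions, which receive 3-minute stimulation epochs every recording.
    """

    name: str
    mfr_multiplier: Callable[[float], float]
    nbr_multiplier: Callable[[float], float]
    nbd_multiplier: Callable[[float], float]
    stimulated: bool = False

    def __post_init__(self) -> None:
        for fn in (self.mfr_multiplier, self.nbr_multiplier, self.nbd_multiplier):
            v0 = fn(0.0)
            if not math.isfinite(v0) or abs(v0 - 1.0) > 1e-9:
                raise ParameterError(f"profile {self.name!r}: multiplier at t=0 must be 1")

    def multipliers(self, hours: float) -> Dict[str, float]:
        out = {
            "mfr": float(self.mfr_multiplier(hours)),
            "nbr": float(self.nbr_multiplier(hours)),
            "nbd": float(self.nbd_multiplier(hours)),
        }
        for key, v in out.items():
            if not math.isfinite(v) or v < 0:
                raise ParameterError(
                    f"profile {self.name!r}: {key} multiplier at t={hours} h is {v}"
                )
        return out


def untreated_profile(mfr_tau_h: float = 8.0, nbr_zero_h: float = 24.0) -> TreatmentProfile:
    """Progressive decline under hypoxia without treatment.

    NBR follows a smooth monotone cosine ramp reaching exactly 0 at
    ``nbr_zero_h`` (complete network-burst inhibition by 24 h); MFR decays
    exponentially with time constant ``mfr_tau_h``.
    """

    def nbr(t: float) -> float:
        if t >= nbr_zero_h:
            return 0.0
        return 0.5 * (1.0 + math.cos(math.pi * t / nbr_zero_h))

    return TreatmentProfile(
        name="untreated",
        mfr_multiplier=lambda t: math.exp(-t / mfr_tau_h),
        nbr_multiplier=nbr,
        nbd_multiplier=lambda t: 1.0,
    )


def neuro_activation_profile(plateau_h: float = 18.0, end_h: float = 24.0, end_value: float = 0.5) -> TreatmentProfile:
    """Optogenetic neuronal activation: NBR held at baseline through
    ``plateau_h`` hours, then declining linearly to ``end_value``."""

    def nbr(t: float) -> float:
        if t <= plateau_h:
            return 1.0
        if t >= end_h:
            return end_value
        return 1.0 + (end_value - 1.0) * (t - plateau_h) / (end_h - plateau_h)

    return TreatmentProfile(
        name="neuro_activation",
        mfr_multiplier=lambda t: 0.6 + 0.4 * math.exp(-t / 24.0),
        nbr_multiplier=nbr,
        nbd_multiplier=lambda t: 1.0,
        stimulated=True,
    )


def astro_activation_profile() -> TreatmentProfile:
    """Optogenetic astrocyte activation: activity preserved, network bursts
    slightly more frequent and markedly shorter."""
    return TreatmentProfile(
        name="astro_activation",
        mfr_multiplier=lambda t: 0.7 + 0.3 * math.exp(-t / 24.0),
        nbr_multiplier=lambda t: 1.0 + 0.3 * (1.0 - math.exp(-t / 6.0)),
        nbd_multiplier=lambda t: 1.0 - 0.4 * (1.0 - math.exp(-t / 4.0)),
        stimulated=True,
    )


def lactate_profile(floor: float = 0.3, tau_h: float = 0.5) -> TreatmentProfile:
    """Exogenous lactate: immediate, concentration-dependent blunting of
    activity (``floor`` = residual fraction)."""
    return TreatmentProfile(
        name="lactate",
        mfr_multiplier=lambda t: floor + (1.0 - floor) * math.exp(-t / tau_h),
        nbr_multiplier=lambda t: 0.1 + 0.9 * math.exp(-t / tau_h),
        nbd_multiplier=lambda t: 1.0,
    )


PROFILES = {
    "untreated": untreated_profile,
    "neuro_activation": neuro_activation_profile,
    "astro_activation": astro_activation_profile,
    "lactate": lactate_profile,
}


@dataclass(frozen=True)
class NetworkBurstTruth:
    start: float
    end: float
    electrodes: Tuple[str, ...]


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    spike_times: Dict[str, np.ndarray] = field(default_factory=dict)
    network_bursts: List[NetworkBurstTruth] = field(default_factory=list)
    multipliers: Dict[str, float] = field(default_factory=dict)
    cell_labels: Optional[list] = None  # list of (x, y, radius, class) per nucleus


def _segment_poisson(rng: np.random.Generator, rate: float, start: float, end: float) -> np.ndarray:
    if rate <= 0 or end <= start:
        return np.empty(0)
    n = rng.poisson(rate * (end - start))
    return rng.uniform(start, end, n)


def simulate_well(
    cfg: SimulationConfig,
    profile: TreatmentProfile,
    hours_in_hypoxia: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    stimulation_epochs: Sequence[Tuple[float, float]] = (),
    well_id: str = "w00",
) -> Tuple[WellRecording, GroundTruth]:
    """One well at one timepoint: Poisson background + network-burst events.

    Background spikes arrive at ``background_rate * mfr_multiplier(h)``
    (boosted by ``stim_rate_boost`` inside stimulation epochs of stimulated
    profiles); network bursts arrive at ``nb_rate * nbr_multiplier(h)``, each
    recruiting each electrode with probability ``nb_participation`` and
    emitting at least 5 spikes at gamma ISIs over a duration drawn around
    ``nb_duration_mean * nbd_multiplier(h)``.
    """
    if hours_in_hypoxia < 0:
        raise ValueError("hours_in_hypoxia must be >= 0")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    mult = profile.multipliers(hours_in_hypoxia)
    T = cfg.recording_duration
    eids = electrode_ids(cfg.electrodes_per_well)

    # --- network-burst events ---------------------------------------------
    event_rate = cfg.nb_rate / 60.0 * mult["nbr"]
    event_dur = cfg.nb_duration_mean * mult["nbd"]
    margin = min(2.0 * event_dur + 0.5, 0.5 * T)
    n_events = rng.poisson(event_rate * T) if event_rate > 0 else 0
    starts = np.sort(rng.uniform(0.0, T - margin, n_events)) if n_events else np.empty(0)
    # refractory separation: cultures do not fire network bursts back to
    # back, and the burst detector cannot distinguish events closer than its
    # 100 ms merge window; enforce a minimum start-to-start gap
    min_sep = event_dur + 0.5
    kept = []
    for s in starts:
        if not kept or s - kept[-1] >= min_sep:
            kept.append(s)
    starts = np.asarray(kept)

    burst_spikes: Dict[str, list] = {eid: [] for eid in eids}
    truth_events: List[NetworkBurstTruth] = []
    for s in starts:
        dur = rng.gamma(10.0, event_dur / 10.0) if event_dur > 0 else 0.0
        recruited = [eid for eid in eids if rng.random() < cfg.nb_participation]
        if not recruited:
            continue
        ev_start, ev_end = np.inf, -np.inf
        for eid in recruited:
            t0 = s + rng.uniform(0.0, 0.005)
            # at least 5 spikes so each channel burst passes the detector's
            # spike-count and duration filters even for very short events
            n_min = 5
            isis = rng.gamma(
                cfg.isi_gamma_shape, cfg.intra_burst_isi_mean / cfg.isi_gamma_shape, n_min - 1
            )
            t = t0 + np.concatenate(([0.0], np.cumsum(isis)))
            while t[-1] - t0 < dur:
                step = rng.gamma(cfg.isi_gamma_shape, cfg.intra_burst_isi_mean / cfg.isi_gamma_shape)
                t = np.append(t, t[-1] + step)
            t = t[t < T]
            if t.size:
                burst_spikes[eid].append(t)
                ev_start = min(ev_start, t[0])
                ev_end = max(ev_end, t[-1])
        if np.isfinite(ev_start):
            truth_events.append(NetworkBurstTruth(float(ev_start), float(ev_end), tuple(recruited)))

    # --- background --------------------------------------------------------
    bg_rate = cfg.background_rate * mult["mfr"]
    epochs = sorted((float(a), float(b)) for a, b in stimulation_epochs)
    boost = cfg.stim_rate_boost if profile.stimulated else 1.0
    trains: Dict[str, SpikeTrain] = {}
    truth_spikes: Dict[str, np.ndarray] = {}
    for eid in eids:
        pieces = []
        cursor = 0.0
        for a, b in epochs:
            pieces.append(_segment_poisson(rng, bg_rate, cursor, a))
            pieces.append(_segment_poisson(rng, bg_rate * boost, a, b))
            cursor = b
        pieces.append(_segment_poisson(rng, bg_rate, cursor, T))
        pieces.extend(burst_spikes[eid])
        t = np.unique(np.concatenate(pieces)) if pieces else np.empty(0)
        t = t[(t >= 0) & (t <= T)]
        trains[eid] = SpikeTrain(t, T, eid)
        truth_spikes[eid] = t

    rec = WellRecording(
        trains=trains,
        duration=T,
        well_id=well_id,
        condition=profile.name,
        timepoint_h=hours_in_hypoxia,
        stimulation_epochs=list(epochs),
    )
    truth = GroundTruth(spike_times=truth_spikes, network_bursts=truth_events, multipliers=mult)
    return rec, truth


def simulate_plate(
    cfg: SimulationConfig, profile: TreatmentProfile, hours_in_hypoxia: float = 0.0
) -> List[Tuple[WellRecording, GroundTruth]]:
    """``cfg.n_wells`` independent wells with per-well random substreams."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_wells)
    return [
        simulate_well(
            cfg,
            profile,
            hours_in_hypoxia,
            rng=np.random.default_rng(child),
            well_id=f"w{i:02d}",
        )
        for i, child in enumerate(children)
    ]


#: default stimulation epoch: light delivered for the first 3 min of each
#: 10-min recording ("3 min every 2 h" protocol)
DEFAULT_STIM_EPOCH = (0.0, 180.0)


def simulate_timecourse(
    cfg: SimulationConfig,
    profile: TreatmentProfile,
    timepoints: Sequence[float],
    well_id: str = "w00",
) -> List[Tuple[WellRecording, GroundTruth]]:
    """One recording per timepoint for a single well.

    Timepoints are hours in hypoxia; the first must be 0 (the normoxia
    baseline).  Stimulated profiles get a 3-minute stimulation epoch in each
    hypoxia recording; the baseline recording is never stimulated.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    if sorted(timepoints) != timepoints:
        raise ValueError("timepoints must be sorted ascending")
    if timepoints[0] != 0:
        raise ValueError("first timepoint must be 0 (normoxia baseline)")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(timepoints))
    out = []
    for child, h in zip(children, timepoints):
        epochs = [DEFAULT_STIM_EPOCH] if (profile.stimulated and h > 0) else []
        out.append(
            simulate_well(
                cfg,
                profile,
                h,
                rng=np.random.default_rng(child),
                stimulation_epochs=epochs,
                well_id=well_id,
            )
        )
    return out


def biphasic_template(sampling_rate: float = 10_000.0) -> np.ndarray:
    """Biphasic extracellular spike template, ~1.2 ms, negative peak = -1.

    A dominant narrow negative lobe followed by a smaller positive
    after-wave; spectral content sits around 1--2 kHz, inside the 100--3500
    Hz detection band.
    """
    t = np.arange(-0.0006, 0.00061, 1.0 / sampling_rate)
    w = -np.exp(-((t / 0.00012) ** 2)) + 0.45 * np.exp(-(((t - 0.00035) / 0.00018) ** 2))
    return w / np.max(np.abs(w))


def render_voltage_trace(
    train: SpikeTrain,
    noise_sd: float = 2.0,
    spike_amplitude: float = 20.0,
    waveform: Optional[np.ndarray] = None,
    sampling_rate: float = 10_000.0,
    rng: Optional[np.random.Generator] = None,
) -> VoltageTrace:
    """Gaussian noise plus a scaled spike template at each spike time.

    The template's negative peak lands on the sample nearest each spike
    time, so detected spike times can be compared to truth at sub-ms
    precision.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(train.duration * sampling_rate))
    if train.times.size and train.times[-1] > train.duration:
        raise ValueError("spike time beyond trace duration")
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    w = biphasic_template(sampling_rate) if waveform is None else np.asarray(waveform, float)
    peak = int(np.argmax(np.abs(w)))
    for t in train.times:
        i = int(round(t * sampling_rate))
        lo = i - peak
        hi = lo + w.size
        wlo = max(0, -lo)
        whi = w.size - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        if lo < hi:
            x[lo:hi] += spike_amplitude * w[wlo:whi]
    return VoltageTrace(x, sampling_rate, train.electrode_id)


# ---------------------------------------------------------------------------
# viability image simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSimConfig:
    """Synthetic three-channel viability micrograph parameters.

    Nuclei are 2-D Gaussian blobs; rejection sampling keeps pairwise disk
    overlap at or below ~10% of nucleus area (center distance >= 1.6 radii),
    emulating the sparse high-magnification fields the assay uses.
    """

    image_size: Tuple[int, int] = (512, 512)
    n_live: int = 100
    n_apoptotic: int = 20
    n_dead: int = 10
    nucleus_radius_mean: float = 8.0  # pixels
    nucleus_radius_sd: float = 0.8
    background_noise_sd: float = 100.0  # 16-bit intensity units
    background_level: float = 300.0
    peak_intensity_mean: float = 15000.0
    peak_intensity_sd: float = 2000.0
    channel_bleed: float = 0.02
    double_positive_fraction: float = 0.3  # dead cells also caspase-positive
    min_center_distance_factor: float = 1.6
    max_placement_tries: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_live", "n_apoptotic", "n_dead"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.channel_bleed < 1:
            raise ValueError("channel_bleed must be in [0, 1)")
        h, w = self.image_size
        n = self.n_live + self.n_apoptotic + self.n_dead
        # coarse feasibility: packed disks at the minimum spacing must fit
        cell = (self.min_center_distance_factor * self.nucleus_radius_mean) ** 2
        if n * cell > 0.7 * h * w:
            raise ValueError("image too small to place all nuclei at the stated radius")


@dataclass
class CellImageSet:
    """Three aligned fluorescence channels of one field of view."""

    nuclei_channel: np.ndarray
    apoptosis_channel: np.ndarray
    death_channel: np.ndarray
    pixel_size: float = 0.085  # um/pixel at 40x
    assay_variant: str = "caspase_pi"

    def __post_init__(self) -> None:
        shapes = {
            self.nuclei_channel.shape,
            self.apoptosis_channel.shape,
            self.death_channel.shape,
        }
        if len(shapes) != 1:
            raise ValueError("channels must share one shape")
        if self.assay_variant not in ("caspase_pi", "nucblue_nucgreen"):
            raise ValueError(f"unknown assay_variant {self.assay_variant!r}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.nuclei_channel.shape


class PlacementError(RuntimeError):
    """Nucleus placement failed after bounded retries (density infeasible)."""


def _place_nuclei(cfg: ImageSimConfig, rng: np.random.Generator) -> List[tuple]:
    h, w = cfg.image_size
    total = cfg.n_live + cfg.n_apoptotic + cfg.n_dead
    placed: List[tuple] = []  # (y, x, r)
    tries = 0
    margin = cfg.nucleus_radius_mean
    while len(placed) < total:
        tries += 1
        if tries > cfg.max_placement_tries:
            raise PlacementError(
                f"placed {len(placed)}/{total} nuclei after {tries - 1} tries"
            )
        r = float(np.clip(rng.normal(cfg.nucleus_radius_mean, cfg.nucleus_radius_sd), 3.0, None))
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        ok = True
        for (py, px, pr) in placed:
            dmin = cfg.min_center_distance_factor * 0.5 * (r + pr)
            if (y - py) ** 2 + (x - px) ** 2 < dmin**2:
                ok = False
                break
        if ok:
            placed.append((y, x, r))
    return placed


def _render_blobs(shape, blobs, rng, cfg) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    for (y, x, r, peak) in blobs:
        sigma = r / 2.0
        half = int(math.ceil(3 * sigma))
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(0, yi - half), min(shape[0], yi + half + 1)
        x0, x1 = max(0, xi - half), min(shape[1], xi + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += peak * np.exp(
            -(((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
        )
    return img


def simulate_viability_image(
    cfg: ImageSimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[CellImageSet, GroundTruth]:
    """Render one three-channel field with known per-nucleus labels.

    Every nucleus appears in the nuclei channel; apoptotic nuclei also in
    the apoptosis channel; dead nuclei also in the death channel (a
    configurable fraction of dead nuclei is additionally caspase-positive,
    the "yellow" double-positive phenotype).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    placed = _place_nuclei(cfg, rng)
    classes = (
        ["live"] * cfg.n_live + ["apoptotic"] * cfg.n_apoptotic + ["dead"] * cfg.n_dead
    )
    rng.shuffle(classes)

    labels = []
    nuc_blobs, apo_blobs, dead_blobs = [], [], []
    for (y, x, r), cls in zip(placed, classes):
        peak = float(np.clip(rng.normal(cfg.peak_intensity_mean, cfg.peak_intensity_sd), 4000, 60000))
        nuc_blobs.append((y, x, r, peak))
        if cls == "apoptotic":
            apo_blobs.append((y, x, r, peak))
        elif cls == "dead":
            dead_blobs.append((y, x, r, peak))
            if rng.random() < cfg.double_positive_fraction:
                apo_blobs.append((y, x, r, peak))
        labels.append((float(x), float(y), float(r), cls))

    shape = cfg.image_size
    nuc = _render_blobs(shape, nuc_blobs, rng, cfg)
    apo = _render_blobs(shape, apo_blobs, rng, cfg)
    dead = _render_blobs(shape, dead_blobs, rng, cfg)
    # symmetric bleed-through between the two reporter channels
    apo_b = apo + cfg.channel_bleed * dead
    dead_b = dead + cfg.channel_bleed * apo

    def finish(img: np.ndarray) -> np.ndarray:
        img = img + cfg.background_level + rng.normal(0.0, cfg.background_noise_sd, shape)
        return np.clip(img, 0, 65535).astype(np.uint16)

    images = CellImageSet(
        nuclei_channel=finish(nuc),
        apoptosis_channel=finish(apo_b),
        death_channel=finish(dead_b),
    )
    truth = GroundTruth(cell_labels=labels)
    return images, truth
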