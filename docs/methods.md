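# Methods notes

## Scope and data model

The pipeline operates on wells of a multi-well MEA plate. Each well holds
12 extracellular electrodes sampled at 10 kHz; a *recording* is 10 minutes
of activity at one timepoint (normoxia baseline, then every 2 h of
hypoxia). The in-memory containers are `VoltageTrace` (one electrode's
signal), `SpikeTrain` (sorted spike times + duration) and `WellRecording`
(all trains of a well at one timepoint, with condition, timepoint and
stimulation-epoch metadata).

## Spike detection

* Band-pass 100–3500 Hz, 4th-order Butterworth, applied forward–backward
  (`sosfiltfilt`) so spike times carry no group-delay bias.
* Baseline noise SD via median absolute deviation scaled by 1.4826. The
  MAD is used because threshold crossings occupy a small fraction of
  samples and would inflate a plain SD; on spike-free Gaussian noise the
  estimator agrees with the sample SD to well under 1% at 10 s of data.
* Threshold = 4.5 × SD. Both polarities are detected by default (the
  extracellular waveform is biphasic; polarity is configurable). Each
  contiguous supra-threshold excursion yields one event at its extremum
  sample; events closer than a 1 ms dead time collapse to the first, so a
  waveform crossing both polarities is counted once. The dead time and
  polarity convention are implementation choices documented here; they are
  not externally specified.
* Empirical false-positive rate on pure band-limited Gaussian noise at
  these settings is ≈ 5/min (frozen regression bound: ≤ 12/min). This is
  consistent with level-crossing theory for a 100–3500 Hz Gaussian process
  (upcrossing rate ≈ 2050·exp(−4.5²/2) Hz ≈ 5/min per polarity), i.e. it
  is a property of the stated world, not a detector defect.
* Electrode activity gate: rate ≥ 0.1 spikes/s, boundary inclusive. MFR
  averages rates over active electrodes; with no active electrode the MFR
  is defined as 0 so a fully silenced well normalizes to 0 instead of
  dropping out of the time-course.

## Burst detection (max-interval)

"ISI between 50 and 100 ms" is implemented as the two-threshold
max-interval scheme of the commercial multi-well analyzers: a burst *opens*
at an ISI ≤ 50 ms and *continues* while ISIs ≤ 100 ms. A literal lower
bound of 50 ms would exclude fast bursts (ISIs of a few ms), contradicting
burst physiology. Candidates separated by < 100 ms merge **before** the
≥ 4 spike and ≥ 50 ms duration filters are applied, because those filters
describe final bursts. All inclusive comparisons carry a 1 ns float slack
so grid-constructed trains (e.g. exact 50 ms spans built from 10 ms steps)
sit on the intended side of each boundary.

## Network bursts

Bursts across channels are chained by strictly positive temporal overlap
(open intervals; contact at a point is not overlap). Chains are built with
a sweep line + union-find: when a burst starts, it unifies with every
burst still open. Per chain, a boundary sweep (ends processed before
starts at equal times) yields the maximal number of concurrently open
bursts. An event requires ≥ 8 distinct channels *and* ≥ 8 concurrent
bursts; its span is [earliest start, latest end] of the chain. The
equivalence of this detector with a brute-force 1 ms-grid detector is part
of the acceptance suite (500 random wells, zero disagreements).

By default *all* detected channel bursts may participate in network
bursts; the 0.4 bursts/min "bursting channel" gate is computed and
reported separately (`WellMetrics.n_bursting`) rather than filtering
participation — the gate's published role is channel classification, and
gating participation would make network-burst detection discontinuous in
borderline channels. NBR is reported per minute of analyzed duration; the
unit cancels under baseline normalization. NBD is the arithmetic mean of
event durations and is NaN (flagged, not zero) when a well has no events.

## Time-course

* Stimulation masking removes spikes inside the stimulation epochs and
  compresses the remaining spikes onto the concatenated unmasked timeline;
  the analyzed duration shrinks accordingly, so masking-then-analysis is
  *identical* to analyzing the concatenation of unmasked segments (this is
  a tested invariant, not an approximation). NBD is computed on the
  analyzed window only.
* Normalization divides each metric by the same well's normoxia value.
  Wells with a zero or undefined baseline for a metric are excluded from
  that metric's aggregate (division is undefined, and a well without
  baseline network bursts was not functionally mature); other metrics of
  the same well are kept.
* Aggregates are mean ± SEM (sample SD / √n; NaN for n = 1) per condition
  per timepoint.
* Statistics delegate to scipy/statsmodels: Lilliefors-corrected
  Kolmogorov–Smirnov normality screen (both groups, α = 0.05, n ≥ 5
  required, otherwise rank test), then unpaired t-test or Mann-Whitney;
  factorial designs get a two-way ANOVA (condition × timepoint, OLS,
  type-II) plus per-timepoint pairwise tests. Bonferroni adjustment is
  min(1, m·p) with the family m = number of timepoints per condition pair.
  The ANOVA treats timepoints as independent groups, not repeated
  measures within wells; this matches common practice for these plate
  experiments but slightly overstates degrees of freedom.

## Synthetic recordings

The generator states the world the analysis assumes; defaults describe a
functionally mature culture and are not tuned per experiment:

| parameter | default | rationale |
|---|---|---|
| electrodes/well, wells | 12, 24 | plate geometry |
| recording duration | 600 s | 10-min recordings |
| background rate | 2 spikes/s | typical mature-network spontaneous MFR |
| network-burst rate | 6 /min | typical synchronized culture |
| event duration | 1 s (gamma, shape 10) | typical NBD scale |
| participation | 0.9 | most electrodes join each event |
| intra-burst ISI | 20 ms (gamma, shape 5) | inside the detector's ISI window, so detectability is the detector's property, not generator marginality |
| stimulation boost | ×2 background during epochs | makes masking consequential |

Background spiking is homogeneous Poisson (spontaneous statistics are not
otherwise specified; adequate for exercising detectors). Network-burst
events arrive as a Poisson process thinned to a minimum start-to-start
separation of (event duration + 0.5 s): cultures do not emit network
bursts back-to-back, and events closer than the detector's 100 ms merge
window are indistinguishable from one event by construction. Each event
recruits each electrode independently and emits ≥ 5 spikes (so every
participating channel passes the 4-spike/50 ms filters even for very short
events). Treatment profiles are configurable multiplier curves with
figure-level shapes: untreated NBR follows a smooth cosine ramp hitting
exactly 0 at 24 h with exponential MFR decay (τ = 8 h); neuronal
activation holds NBR at 1 through 18 h then declines linearly to 0.5 at
24 h; astrocyte activation raises NBR ≤ +30% and shortens NBD by up to
40%; lactate blunts activity immediately (τ = 0.5 h). All multipliers
equal 1 at t = 0 by contract.

Voltage rendering adds a ~1.2 ms biphasic template (dominant negative
lobe, 45% positive after-wave, spectral content ~1–2 kHz) to Gaussian
noise at the spike times.

What a green test does *not* establish: the generator has no electrode
heterogeneity, no slow non-stationarity, no waveform variability or
overlapping units, and its hypoxia response is exactly the stated
multiplier curves — recovery tests validate the pipeline's arithmetic and
detection logic, not biological inference on real recordings.

## Synthetic micrographs and viability

Nuclei are 2-D Gaussian blobs (σ = radius/2, radius ≈ N(8, 0.8) px in a
512×512 field) placed by rejection sampling with center distance
≥ 1.6 × mean radius, capping pairwise disk overlap at ~10% of nucleus
area. Apoptotic nuclei re-appear in the apoptosis channel; dead nuclei in
the death channel (30% of them also in the apoptosis channel — the
double-positive phenotype); 2% symmetric bleed-through couples the two
reporter channels; channels get a constant background plus Gaussian noise
and are quantized to 16-bit.

Analysis-side choices: Otsu thresholding per channel with a robust floor
at median + 5 scaled MADs — pure-noise channels (no signal to bisect)
yield an essentially empty mask instead of Otsu's half-split of the noise.
Segmentation filters connected components by area ([0.15, 6]·πr²) and
splits touching nuclei by a smoothed distance-transform watershed.
Reporter positivity requires the reporter mask to cover ≥ 30% of the
nucleus area, guarding against bleed-through. Double-positive nuclei count
as dead only (they are listed with dead cells in the assay definitions),
so the count identity live + apoptotic + dead = total holds exactly.

## Parameter-recovery sweeps (`meapipe.validation`)

Each analysis constant is recovered as an empirical decision boundary. The
spike-threshold sweep injects critically-sampled biphasic pulses (one
dominant negative sample) at 100 sites per 10 s band-limited unit-SD noise
trace, 40 noise repetitions, amplitudes 2–7 in 0.1 steps; a site is hit if
a spike lands within 0.5 ms. A single pulse site would put the boundary at
4.5 minus that site's noise value; the 50% detection crossing over ~4000
sites estimates the median of that distribution — the threshold itself —
with SE ≈ 0.02. The trace is generated already band-limited and the
detector run in pre-filtered mode so amplitudes are true detector-input
amplitudes (re-filtering would attenuate a narrow template by ~8% and bias
the boundary accordingly). The remaining sweeps are deterministic
(run-length, channel-count, rate, burst-count and span sweeps).

## Known limitations

* No spike sorting; multi-unit threshold crossings only.
* Fixed-parameter burst detection only (no adaptive/log-ISI detectors).
* The statistics harness implements plain factorial ANOVA, not
  repeated-measures or mixed models.
* Viability segmentation is tuned for sparse fields (~10% max overlap);
  dense clumps would need stronger declumping than the default watershed.
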