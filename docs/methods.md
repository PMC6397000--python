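# Methods

This note documents the models, estimators and numerical choices behind
`placecode`, and what the synthetic benchmark does and does not show.

## Session model and coordinates

A session is a head-fixed virtual linear-track recording: a 200 cm track
sampled at 50 Hz, alternating forth/back trials separated by
teleportations (the animal is turned in place, so position is continuous
but direction flips), per-unit spike times, and one LFP channel at
1250 Hz. Positions are in cm with 0 at one end; spatial bins are
half-open `[k·s, (k+1)·s)` and 0-indexed. The two running directions are
analysed separately on the same axis. The reward zones (first and last
10% of the track) are excluded from every analysis; the remaining 80
2-cm bins per direction are the *analyzed* bins. Object zones (OZ,
30–70 cm and 160–180 cm) contain the virtual 3D objects of the cue-rich
condition; individual object zones (crane 30–46, cube 60–70, tree
164–180 cm) are used only for object-responsive-cell detection.
Locomotion epochs are samples with speed > 2 cm/s; speed is a
within-trial finite difference, so teleportations never produce spurious
speed.

## Rate maps

Per trial and direction, spike counts and occupancy are accumulated in
2-cm bins from locomotion samples and each vector is smoothed with a
Gaussian kernel whose half-width parameter is the kernel standard
deviation (10 bins, truncated at ±3σ). Smoothing is mass-preserving at
the edges: each source bin's kernel column is renormalized to unit sum,
so total spike count and occupancy are conserved (an alternative FWHM/2
reading of "half-width" is a config switch). The smoothed count vector is
divided by the smoothed occupancy vector; bins with < 1 ms smoothed
occupancy get rate 0. The heavy smoothing matters downstream: detected
fields are substantially wider than the underlying tuning curves.

Cells are putative pyramidal iff mean rate < 20 Hz and (burst index > 0
or spike duration > 0.4 ms), and track-active iff in some direction the
locomotion mean rate exceeds 0.5 Hz, the mean-map peak exceeds 1.5 Hz,
and the cell spikes in at least half the trials. The burst index is not
defined by the upstream reference we could consult; we use log2 of the
observed over Poisson-expected fraction of inter-spike intervals ≤ 6 ms
(positive = burstier than Poisson) and document it as a stand-in.

## Place-field detection

Detection is a per-bin bootstrap against a trial-wise homogeneous
Poisson null: for each trial, a surrogate train at that trial's mean
locomotion rate is mapped through the real trajectory, smoothed and
divided like the data, and the surrogate mean rate vectors give a
one-sided add-one p-value per bin, p = (1 + #{surrogate ≥ observed}) /
(1 + n_boot), n_boot = 1000. Because a homogeneous Poisson train binned
through the trajectory yields independent Poisson counts with mean
rate × occupancy, the surrogate counts are drawn directly as Poisson
variates — identical in distribution to simulating 1 ms spike trains,
and much faster. Candidate fields are runs of > 3 contiguous analyzed
bins with p < 0.01; fields whose closest edges are ≤ 5 bins apart are
merged (iterated to a fixed point; merging is order-independent); edges
extend by ≤ 5 bins per side while p < 0.30, never across a neighboring
candidate; candidates longer than 45 bins are rejected; surviving fields
must be stable (per-trial map vs mean map Pearson r > 0.60, other fields'
bins excluded, in ≥ 40% of trials; constant trials count as failures).
The primary field has the highest peak (leftmost peak on ties). The same
procedure without the stability criterion runs per lap; a lap field is
kept iff it overlaps its closest mean field by ≥ 1 bin.

Field geometry: width is the distance between the two interpolated
crossings of min + 0.3·(max − min) around the peak and is defined only
when both crossings exist inside the analyzed region ("complete"
fields); dispersion is bin_size × RMS distance of lap-field centers
around the mean center; the out/in ratio divides the mean rate over
analyzed bins outside all detected fields by the in-field mean. A field
peaking on the first or last analyzed bin is an End-Track field.
Object-responsive cells are bidirectional place cells with a field
peaking inside the same individual object zone in both directions
(peak-in-zone is the strictest membership reading and is the documented
choice).

## Spatial metrics

* Stability index: mean Pearson correlation over all trial pairs
  (analyzed bins; constant pairs skipped). Identical trials give 1 for
  any trial count.
* Spatial information (bits/spike): Skaggs formula over all 100 bins
  with occupancy weights, FR the occupancy-weighted mean rate;
  zero-rate bins contribute 0. Uniform maps give 0; firing confined to
  one of N equally occupied bins gives log2 N. SI is invariant to rate
  rescaling.
* Mutual information: samples are the (trial, bin) rate entries over
  analyzed bins weighted by occupancy; the second variable is the rate
  quartile from pooled interpolated quantiles (zeros included; heavy
  ties degrade the quartiles and raise a warning). MI is z-scored
  against 1000 surrogates built by circularly time-shifting the spike
  train (uniform shift ≥ 1 s) and re-binning it through the trajectory —
  the shift preserves ISI structure while destroying position alignment
  and thereby corrects the baseline-rate bias of raw MI.
* Local stability: per analyzed bin, Pearson correlation between the
  even-trial and odd-trial mean maps over a 5-bin window truncated at
  the analysis edges.
* Field-position uniformity: the statistic is the SD of per-10-cm-bin
  field percentages after excluding values above the 93rd and below the
  6th percentile; the null redistributes the field count uniformly
  (1000 draws), p = P(null SD ≥ observed). The trimming deliberately
  prevents a single extreme bin from driving the statistic — all fields
  in one bin is trimmed to SD 0 and is *not* rejected; concentration
  across several bins is. Under a uniform null the rejection rate at
  0.05 is nominal (calibrated in the acceptance suite).
* Map similarity: per back-and-forth trial, each direction's trial map
  is correlated with the same-direction template mean (the cue-rich
  condition's average; leave-one-out when the lap belongs to the
  template condition) and the two values averaged.

## Position decoding

The memoryless Bayesian decoder evaluates, per non-overlapping 150 ms
window tiled over locomotion epochs, P(x|n) ∝ Π_i f_i(x)^{n_i} ·
exp(−τ Σ_i f_i(x)) with a uniform prior over the analyzed bins, assuming
Poisson spiking and independence. Tuning curves are leave-one-out: the
decoded trial never enters its own curves. Rates are clamped at
10⁻³ Hz inside the likelihood to avoid zero-probability lockout. The
decoded position is the posterior mode; error is the center-to-center
distance to the real bin; accuracy is the posterior at the real bin
(chance = 1/n bins: 0.01 on the full grid, 1/80 over analyzed bins).
The drop-cell procedure decodes with 50 random subsets of 5k cells and
keeps the per-(window, bin) median posterior, renormalized. The FRV
decoder correlates each 100 ms population count vector with every bin's
template across cells; constant windows are excluded and counted.
Windows are tiled from the start of each run epoch; partial trailing
windows are dropped.

## Theta analyses

Phase: zero-phase 4th-order Chebyshev-II band-pass (4–12 Hz, 40 dB
stopband) and analytic-signal phase; or a waveform method (half-cycles
from 4–10 Hz zero crossings, extrema in the 1–40 Hz signal, linear
interpolation between peak/trough landmarks) that preserves cycle
asymmetry. Both are rotated by one session-level offset so the pooled
pyramidal spike-phase distribution peaks at 180°. Spike phases are
interpolated on the unwrapped phase.

Phase locking: circular mean, mean resultant length, Rayleigh p (Zar's
approximation); locked cells require p < 0.05, ≥ 10 spikes.

Phase precession: the slope maximizes the resultant length of
φ − s·u over s ∈ [−4π, 4π] rad per normalized field unit (10⁻² cycle
grid plus bounded refinement; boundary hits flagged); the correlation is
circular-circular (Jammalamadaka) between φ and |s|·u, its sign carrying
the precession direction. Significance permutes spike positions and
re-runs the whole fit (slope refit on a coarse grid) — a fixed-slope
permutation is anti-conservative because only the observed statistic
would be slope-optimized. In the cue-poor condition fits are restricted
to spatially stable trials (in-field r > 0.6, ≥ 3 trials). Single-lap
fits average over laps with ≥ 4 spikes and a significant negative-slope
fit; cells need ≥ 3 qualifying laps.

Spike/LFP spectral shift: multitaper spectra (time-bandwidth 3, 5
tapers) of the 8 ms-binned spike train and the decimated LFP,
interpolated to a 0.02 Hz grid over 4–12 Hz; cells qualify when the
spike-spectrum theta modulation index (mean power within ±0.5 Hz of the
peak over mean power below 5 or above 9 Hz) exceeds 1.4; the shift is
the non-negative lag (≤ 2 Hz) maximizing the cross-correlation of the
z-scored spectra. The LFP against itself gives exactly 0.

Speed modulation: instantaneous frequency from unwrapped-phase
differences × fs (a peak-to-peak cycle method is the cross-check;
they agree within 0.1 Hz RMS on chirps), amplitude as the normalized
analytic modulus; Pearson r of each against speed over locomotion
samples.

Pair offsets: cross-correlograms of the two cells' in-field spikes
(a switch allows all spikes); the behavioral offset is the peak of the
0–2 Hz zero-phase-FIR-filtered CCG (±1 s, 3 ms bins), the theta offset
the peak of the 0–20 Hz-filtered CCG (±200 ms, 1 ms bins, peak searched
within ±100 ms). Pairs need overlapping fields and a theta-CCG mean bin
count ≥ 1 count/ms. The ensemble statistic is the Pearson correlation
between the two offsets across included pairs.

## Synthetic sessions

The generator is the ground-truth source for every stage. Trajectory:
alternating full-track traversals at ~15 cm/s (Ornstein-Uhlenbeck speed
modulation clipped above half the mean; stationary pauses at a
configurable rate). LFP: instantaneous frequency 6.7 Hz plus an optional
speed gain, phase integrated exactly (the unwrapped truth is returned),
optional within-cycle asymmetry warp and amplitude speed gain, Gaussian
noise. Spikes: inhomogeneous Poisson on a 1 ms grid with intensity
(baseline + peak·Gaussian(x; center ± per-trial jitter, σ)) ×
(1 + m·cos(φ − ψ(x))), ψ advancing linearly by the precession slope over
the field span center ± 2σ along the travel direction. Phase-dependent
intensity yields both single-cell precession and theta-timescale pair
compression from one mechanism. Ensembles add non-spatial active cells
(1.5–5 Hz, weakly theta-locked), silent cells (0.05 Hz), interneurons
(30 Hz Poisson, metadata burst index −0.5 / duration 0.25 ms — waveforms
are not simulated, so classification operates on metadata), and
object-responsive cells (bidirectional, same IOZ center).

Condition presets fix the study conditions once: the cue-rich preset
("OT-like": σ 9 cm, peak 8 Hz, baseline 0.8 Hz, jitter 2 cm, slope
−2 rad/U, modulation 0.6, theta-speed gain 0.02 Hz per cm/s, ensemble
22 place / 8 non-spatial / 10 silent / 3 interneurons) and the cue-poor
preset ("NT-like": σ 12, peak 7, baseline 3.5 Hz, jitter 8 cm, slope 0,
modulation 0.4, gain 0, ensemble 6/24/10/3). Field width, rates, place
fractions, theta frequency and speed were chosen to sit near the values
hippocampal VR recordings report for these conditions. Place cells
default to one random direction each; benchmark ensembles that need
full coverage use bidirectional cells explicitly.

What the generator does *not* emulate: rate remapping, directional rate
asymmetries, waveforms and spike sorting artifacts, sharp-wave ripples
and non-theta states, reward-related firing, and any mechanistic account
of why cues change coding (the presets are emulation conveniences).
Passing tests therefore demonstrate that the estimators recover known
structure of this generative form at realistic noise levels — not that
real recordings would yield any particular published values.

## Benchmark problem sizes and numerical choices

The acceptance benchmarks (also exercised by `tests/test_acceptance.py`
and recomputed by `scripts/acceptance.py`) use desk-scale sizes chosen
once: 30-trial sessions and 50 planted + 50 uniform cells for detector
recovery/specificity; a 25-trial, 20-cell bidirectional ensemble for
decoding (ISI-shuffled trains as the chance-level null — circular
time-shifts do not reach chance because back-and-forth trials are
quasi-periodic and a constant shift remaps fields coherently); a
100-trial session with 8 precessing cells for slope recovery (per-cell
slope spread at modulation depth 0.6 is ~0.45 rad/U even at 600 spikes,
so the ensemble mean is the pinned quantity); 24 cells tiled every ~2 cm
at modulation depth 0.85 for the pair-compression correlation (offsets
only correlate when pair separations span a range); 500 replicates for
the uniformity-test calibration; and a 20-trial two-condition run for
the qualitative contrast. Degenerate inputs are handled as documented
per function (constant vectors skip correlations, empty trains return
empty results, flat fields have undefined width, quartile ties warn).

Known limitations: the waveform phase method needs several clean cycles
and degrades at high noise; the spectral-shift estimator assumes
stationary theta over the session; the drop-cell median posterior is
computed per window and can be slightly over-confident after
renormalization; run-epoch gating by the theta/delta power ratio (> 2 in
1 s windows) is available as an alternative to the speed gate but is not
exercised by the benchmarks.
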