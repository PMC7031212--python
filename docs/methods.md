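# Methods

This note documents the models, conventions and numerical choices behind
`sowave`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what validation on synthetic data does and does not
establish about real recordings.

## Signal model and units

All signals are extracellular LFP in microvolts, time in seconds, positions
in millimetres, rates in hertz. Recordings are channels × samples arrays
with a sampling rate (5 kHz is the working default for anesthetized-style
data) and an electrode geometry: a 16-channel linear depth probe at 0.1 mm
spacing or a 32-channel (8 × 4) surface grid at 0.55 mm spacing.

## MUA estimation

Population firing rate is estimated from the 200–1500 Hz band of a
short-time Hann spectrogram (window 5 ms, hop 1 ms by default). Each
frequency bin is divided by its own time average over the whole recording,
then normalized bins are averaged across the band (in power, not amplitude).
The per-bin normalization removes any frequency-dependent electrode response
and the spectral background, and cancels channel gain exactly; the resulting
MUA has mean 1 per channel by construction, so only ratios (Up vs Down) are
physically meaningful. `log_mua` is floored at 10⁻³ before the log because
near-silent Down windows can produce arbitrarily small estimates.

Choices that are conventions rather than measurements: the 5 ms/1 ms
window/step (state-transition resolution far below Up durations; exposed in
config), the whole-recording normalization denominator (no baseline epoch is
defined for these recordings), and power-domain band averaging (under which
a high-band SD contrast of 3 appears as a MUA ratio of 9). All three are
recorded in the MUA output metadata.

## Up/Down detection and SO metrics

The log MUA is smoothed with a 20 ms moving average, and a per-channel
threshold is placed at the minimum of the smoothed log-MUA histogram between
its two largest modes (modes below 10% of the histogram peak are ignored as
tail wiggles; a unimodal histogram falls back to the midpoint of the
10th/90th percentiles). Runs shorter than 50 ms are merged into the
flanking state, shortest first, so the segmentation always alternates and
tiles the analyzed span. Interval edges sit midway between MUA window
centres, so boundary error is bounded by one MUA step (1 ms).

Metrics exclude the edge-truncated first and last intervals. SO frequency
is the mean of per-cycle inverse (Up + following Down) durations — per-cycle
language rather than the inverse of the mean cycle; the two differ under
variability and the choice is recorded in output metadata. CVs use the
population (÷N) standard deviation. The Down→Up slope is the arctangent,
in degrees, of a least-squares line fitted to log MUA around each
transition with time in units of the mean cycle and amplitude in units of
the log-MUA span; degrees are meaningless without such an axis convention,
which is configurable, so slopes are comparable only within one convention.
Up-state band powers (alpha 8–12, beta 15–32, gamma 32–100 Hz) come from
Hann/50%-overlap Welch segments (0.25 s) taken inside Up epochs; epochs
shorter than one segment are dropped. The task-locked firing-rate
timecourse divides windowed mean MUA by the window at task initiation.

## Wave propagation

Per-channel Down→Up transitions are merged greedily in time order: a
transition joins the open wave if it is within 250 ms of the wave's running
mean and its channel is not yet in the wave (defaults for the "majority of
channels in a reasonable interval" rule: max span 250 ms, minimum
participation half the channels). Lags are re-centred to zero mean per
wave; channels without a transition stay missing (never imputed as zero).
Lags are interpolated with an exact thin-plate spline (zero smoothing,
degree-1 polynomial tail, so planar fields are reproduced to machine
precision) on a regular grid (0.05 mm default) over the array bounding box.
Speed is 1/|∇T| by central differences; the one-pixel border and points
implying speeds above 10 m/s (locally flat wavefronts, where 1/|∇T|
diverges) are masked, and the summary speed is the median over the valid
mask. Pattern entropy projects the complete-wave lag matrix onto its first
two principal components and takes the Shannon entropy (base 2) of an
8 × 8 occupancy histogram spanning the data extent; the entropy depends on
the bin count, which is therefore reported alongside. Waves with missing
channels are excluded from the PCA by default (mean imputation is available
behind a flag). Linear probes have no 2-D lag field; wave analysis targets
the surface grid.

## Functional connectivity

Wideband analysis decimates (anti-aliased polyphase) to 250 Hz; band
analyses (SO 0.1–1, alpha 8–12, beta 15–32, low/mid/high gamma 32–50,
50–70, 70–100 Hz) use a zero-phase (forward–backward) Butterworth of order
4 and decimate to roughly 4× the band top. Pairwise Pearson correlation
gives W; D = 1/W, with correlations at or below a floor (0.05) treated as
absent edges, because the reciprocal of a vanishing or negative correlation
is not a usable distance. Louvain community detection (networkx
implementation, resolution 1, 20 seeded restarts, best modularity kept —
the heuristic is stochastic) runs on the floored weights; characteristic
path length is the mean Dijkstra shortest-path distance over reachable
ordered pairs, with the unreachable fraction reported. Functional
complexity uses M = 20 equal bins of |r| on [0, 1]:
C = 1 − (M/(2(M−1))) Σ|pₘ − 1/M|, which is 0 for a delta-like correlation
histogram and 1 for exactly uniform occupancy. Group-level correlation
matrices are element-wise means across animals; graph metrics are computed
per animal and compared at the group level.

## Synthetic generator

The generator is statistical, not biophysical: no conductances or spiking
network, only the features the analysis measures.

- **States.** Up/Down durations are gamma-distributed with configurable
  mean and CV (positive support, CV directly controllable; degenerate
  constant at CV = 0), alternating from Down, tiling the recording.
  Defaults follow wild-type anesthetized group means: Up 0.39 s (CV 0.51),
  Down 0.82 s (CV 0.49).
- **Trace composition.** A smoothed two-level slow deflection (Up negative
  at depth, 30 μV), a stochastic-phase gamma sinusoid (60 Hz, 10 μV)
  confined to Up states, Gaussian 200–1500 Hz noise whose SD is
  `hf_scale` × the state's firing-rate level (5 μV/unit; rates 3 Up / 1
  Down), and a colored background (40 μV SD). The background power falls
  as 1/f² by default (exponent configurable): enough low-frequency power to
  keep channels from being trivially correlated, while leaving the MUA band
  nearly clean, as in real LFP where spiking dominates above 200 Hz.
- **Propagation.** Each global Down→Up transition is one wave; channel
  copies are shifted by position-projection/speed (planar, alternating
  between two directions by default) or centre-distance/speed (radial),
  lags re-centred per wave and stored as ground truth. Speed defaults to
  20 mm/s — a literature-typical value, since no quantitative speed anchor
  exists for these cohorts.
- **Correlation structure.** Mixing replaces a fraction of each channel
  with common signals: `shared_fraction` f per community and
  `global_fraction` g across all channels
  (√(1−f−g)·own + √f·c_community + √g·c_global, commons scaled to the
  channel's SD), so within-community correlation is ≈ f+g and
  across-community ≈ g for independent inputs. Commons are band-limited to
  1–15 Hz by default so that sharing models low-frequency coherence without
  contaminating the beta/gamma Up-state PSD contrasts; correlation analysis
  at 250 Hz still sees most of the variance.
- **Cohorts.** The WT-like preset uses the defaults with f = 0.25,
  g = 0.08 over two communities (array halves). The WBS-like preset
  differs only in: lower Up firing-rate level (2.35), lower Up gamma
  amplitude (8.2 μV), higher Down-duration CV (0.60), and higher global
  sharing (g = 0.25). Per-animal parameters get 5% multiplicative
  lognormal jitter (RNG seeded from (seed, animal index)) to create
  between-animal variance. Everything is reproducible from the seed via
  spawned substreams.

**What synthetic validation shows — and does not.** Passing recovery tests
demonstrates that the estimators are unbiased and correctly scaled for
signals whose band content, state process, propagation and correlation
structure match the generator's assumptions. Real recordings add
non-Gaussian spike waveforms, nonstationary anesthesia depth, movement and
line artifacts, electrode drift and volume-conduction structure that the
generator does not emulate; detection thresholds and the weight floor may
need tuning there, and absolute PSD values depend on amplifier calibration.
The group-direction tests show the pipeline separates cohorts whose
generating parameters differ in the modeled directions (lower Up firing
rate and gamma, more variable Down states, globally elevated correlation
with lower modularity and path length); they are not evidence about any
real genotype. One known emulation artifact: because low-frequency sharing
is spectrally flat within 1–15 Hz, the alpha-band PSD rises slightly with
the sharing fraction, so the (non-significant, direction-unconstrained)
alpha contrast of the modeled condition is not reproduced.

## Problem sizes and determinism

Default cohort work uses 60 s recordings (~48 SO cycles; duration-recovery
studies use 120 s), 16 channels at 5 kHz; the power-replicate study in the
test suite uses 20 s, which is ample for the large preset firing-rate
contrast. All stochastic steps (generation, jitter, Louvain restarts) are
seeded; identical configuration and seed reproduce outputs bit-for-bit.

## Known limitations

- Wave clustering is greedy in time order; two waves closer than the merge
  span on most channels would fuse. With SO cycle lengths ≫ span this does
  not occur in practice.
- The PC-plane entropy depends on the occupancy bin count (8 per axis by
  default) and is reported together with it; values from different binnings
  are not comparable.
- The 1/W distance is undefined for anticorrelated pairs; the weight floor
  removes such edges, which can disconnect sparse graphs (the unreachable
  fraction is reported, and fully disconnected graphs raise).
- `mann_whitney_u` switches from the exact to the tie-corrected normal
  null above n = 8 per group; at that size the two differ by < 0.02 in p.
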