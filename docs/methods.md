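# Methods

This note documents the models and numerical choices behind the `hdemg`
pipeline: what the signal chain computes, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Signal model and conditioning

A monopolar HD-sEMG channel is modelled as an amplitude-modulated broadband
carrier: during a contraction the interference pattern of many motor-unit
action potentials is well approximated, at the envelope level, by zero-mean
noise band-limited to 20–450 Hz whose standard deviation follows the
activation profile. The conditioning chain assumes exactly this structure:

- **Band-pass** 20–450 Hz, Butterworth of order 4 (as counted per band edge,
  i.e. `scipy.signal.butter(4, [20, 450], "bandpass")`), removing motion
  artifacts below 20 Hz and out-of-band noise.
- **Notch** at 50 Hz, second-order IIR, Q = 50. The notch is applied after
  the band-pass; for LTI filters the order is immaterial, but it is fixed for
  bit-reproducibility.
- **Envelope**: full-wave rectification followed by a third-order 2 Hz
  Butterworth low-pass. For a Gaussian carrier of standard deviation σ the
  envelope converges to σ·√(2/π) ≈ 0.798 σ (the folded-normal mean) — the
  factor linking carrier scale to envelope scale throughout the package.
- All filtering is **zero-phase** (forward–backward). The analysis is
  offline; zero-phase filtering avoids group delay that would bias onset
  estimates. Note that a forward–backward pass squares the magnitude
  response, which only sharpens the stated stop-band attenuations.
- Tiny negative excursions after the envelope low-pass are clamped to zero:
  envelopes are amplitudes.

## Faulty channels

Faulty electrodes are repaired by the sample-wise mean of their non-faulty
8-neighbours; rows wrap around the forearm cylinder and the longitudinal
extremes use their five available neighbours. Repair uses only non-faulty
sources, so it is order-independent and idempotent. A channel with no
non-faulty neighbour raises an error rather than guessing.

The automatic fault detector is an explicit, reproducible stand-in for the
visual time/frequency inspection used in practice: a channel is flagged when
its **rest-level amplitude** (lower-quartile rectified amplitude — with an
on/off protocol the lower quartile falls inside rest periods) exceeds 5× or
falls below 0.05× the median channel's. Using whole-record RMS instead would
misclassify strongly active electrodes as saturated; the rest-level statistic
separates electrode faults from genuine activity. A manually supplied faulty
list always overrides the rule.

## Segmentation

The onset threshold is baseline mean + k·SD with k = 10. The baseline is the
lead-in rest interval minus its first 500 ms (filter settling); the summary
trace is the mean of per-channel normalized envelopes over channels whose
within-recording normalization factor exceeds the 25th percentile — robust to
dead channels, with a single-channel mode available. After each detected
contraction the trace must fall back below threshold before the next onset is
searched, which makes the detector immune to plateau ripple. Contraction
windows span 3 s from onset; the steady-state window is the middle 1 s
(configurable via the steady-window length). A recording with fewer bursts
than repetitions raises a segmentation error reporting the count found — no
automatic recovery is attempted.

On synthetic sessions with signal-to-noise ratio 20 (template peak over
baseline SD), detected onsets sit within ±35 ms of the planted ramp start
(the ±100 ms recovery criterion passes 100/100 seeds); the residual bias
comes from the symmetric smoothing of the 2 Hz zero-phase envelope filter
acting on the 250 ms activation ramp.

## Normalization and heatmaps

Each electrode's normalization factor is the maximum of its 1-s
moving-averaged envelope across the participant's complete dataset (all
gestures plus the maximal-effort reference). The moving average guards
against single-sample artifacts: a one-sample spike of 100 µV on a 1 µV
envelope moves the factor by 99/2048 µV, not to 100 µV. Because the
steady-state mean is itself one value of that moving average, normalized
steady-state heatmaps are bounded by 1 by construction.

The COG is the amplitude-weighted centroid of cells at or above 80 % of the
map maximum (ties included). The row (circumferential) centroid is a weighted
**circular mean**: the rows encircle the forearm, and a planar centroid would
be wrong for activity straddling the row-0/row-7 seam. When the included
cells are perfectly balanced around the cylinder (e.g. a uniform map) the
circular mean is undefined and the planar centroid is used. A planar mode is
available for comparison with grid-on-a-plane COG conventions. Physical
coordinates place the centre of row i at (i + 0.5)·CID along the
circumference and column j at 20 % of forearm length plus (j + 0.5)·2 cm from
the elbow; the half-pitch offset is a declared convention (the exact cell
origin at the 20 % line is a free choice).

## Dimensionality

PCA operates on the 64 × 70 concatenation of all repetition heatmaps, with
the 70 heatmap vectors as variables (columns, mean-centred over the 64
electrode observations) — the orientation under which the centred matrix has
at most 63 components. No variance scaling is applied. The dimensionality is
the smallest component count whose cumulative variance explained exceeds
90 %.

A consequence of per-map centering worth knowing: non-negative, spatially
localized patterns are never exactly orthogonal after centering — two
disjoint activation bumps acquire a negative inner product of order −S²/64
(S the bump's cell sum), so the "sum of all patterns" direction is
structurally weak. Planted-rank recovery is therefore exact for narrow,
well-separated templates (the generator's orthogonal planted-rank
conditions), while broad overlapping templates can fold their weakest
direction below the 90 % threshold. With the default healthy profile (five
broad base patterns) the pipeline typically reports 4 components — the
qualitative healthy-vs-DMD contrast (more components for healthy) is
preserved, but the recovered count for broad patterns is a lower bound on the
planted one.

## Myocontrol

Classification follows the classical time-domain protocol: per channel and
200 ms window (100 ms overlap), mean absolute value, zero crossings,
slope-sign changes (both with a configurable dead-band, default 0) and
waveform length, computed on the band-pass-filtered steady-state segments.
Windows do not straddle the splice between concatenated 1-s segments (9
windows per segment, 90 per gesture); a straddle mode (99 windows) exists for
compatibility with pipelines that window the full 10-s concatenation.

The classifier is LDA with Ledoit–Wolf shrinkage of the pooled covariance
(`solver="lsqr", shrinkage="auto"`), preceded by per-feature z-scoring with
training-set statistics: 4 × 64 = 256 features against a few hundred training
windows make the unregularized covariance ill-conditioned. Validation is
three-split Monte Carlo cross-validation with stratified 70/30 partitions —
stratification protects the 30 % test split from empty classes. Window-level
sampling is the default; because neighbouring windows overlap by 100 ms,
train/test leakage inflates offline accuracy somewhat, which is the
recognised behaviour of this protocol (a segment-blocked splitting mode can
be built from the per-segment feature matrices).

## Synthetic cohorts

`hdemg.synth` generates cohorts whose ground truth the pipeline is asked to
recover:

- **Spatial templates**: isotropic Gaussian bumps in grid units, wrapped
  circumferentially (the forearm is a cylinder). Column weights are truncated
  to the largest support symmetric about the centre, so the unthresholded
  amplitude-weighted centroid is exactly the planted centre for centres on
  the half-integer lattice.
- **Sessions**: trapezoidal activation (250 ms ramps — the instructed
  transitions are abrupt, but a finite ramp makes onset detection realistic)
  modulating band-limited Gaussian carriers, independent per channel
  (cross-talk is out of scope); additive band-limited baseline noise
  (default SD 2 µV), a 50 Hz powerline sinusoid with per-channel phase
  (default 1 µV), and optional faulty channels ("dead" = 1 % of baseline
  noise; "saturated-noise" = 50×). Everything is reproducible from the seed.
- **Group profiles** plant the study contrasts. Healthy: 5 distinct base
  patterns, spread 1.4 electrode pitches, comfortable activation at 26 % of
  maximum, 89 µV envelope scale. DMD: 3 base patterns, spread 1.0 (smaller
  activation areas), activation at 63 % of maximum, 35 µV scale. The
  `absolute_scale` is the target *envelope* amplitude; the carrier SD is
  larger by 1/√(2/π). Base centres sit on two longitudinal rings with rows
  evenly spaced per ring, keeping all pattern pairs well separated on the
  cylinder.
- **Normalization ground truth**: each participant includes a maximal-effort
  reference recording that cycles the base patterns at full amplitude with a
  background of 20 % everywhere (maximal dynamic effort co-contracts the
  whole forearm). Without the background, electrodes far from every pattern
  would be normalized by their noise floor and report spurious near-unity
  activations.
- **Correlated gestures**: gestures beyond the distinct-pattern count blend
  neighbouring base pairs (0.7/0.3; 0.55/0.45 on the second wrap), so extra
  gestures never add rank. Repetition-to-repetition variability has two
  components: amplitude jitter (SD 10 %) and **mixing jitter** in
  base-weight space (SD 0.05 healthy, 0.12 DMD) — the latter models
  co-activation variability and is what makes correlated DMD gestures
  genuinely confusable for the classifier. No quantitative description of
  DMD co-contraction structure exists to calibrate against; the blend matrix
  and jitter levels are modelling choices, fixed once.

What the generator does **not** emulate: motor-unit discharge structure,
volume conduction and electrode cross-talk, electrode-skin impedance,
fatigue, and within-contraction force drift. Passing recovery tests
therefore demonstrates that the pipeline correctly inverts the generative
model it assumes (amplitude-modulated band-limited activity on a cylindrical
grid) — not that it is robust to every artifact of clinical recordings.

## Problem sizes

Synthetic validation runs at 1,024 Hz sampling — the full 20–450 Hz EMG band
is preserved — with the standard 3 s on / 3 s off protocol; cohort-level
experiments use 6–10 repetitions per gesture and 1–11 participants depending
on the experiment, sizes at which every recovery statistic is stable across
seeds. All defaults in the public API remain at the study values (2,048 Hz,
10 repetitions, 8 + 3 participants).

## Known limitations

- The recovered dimensionality of broad overlapping patterns under-counts
  the planted rank (see above); reported group contrasts are directional.
- Group-level aggregation of the DMD dimensionality mixes participants; the
  per-participant list is always emitted alongside the mean.
- The normalized activation recovered from cohort pipelines carries a small
  positive bias (~0.03–0.07) relative to the configured level: the per-map
  maximum over 64 cells is an extreme-value statistic and inherits
  cell-level noise.
- The delimited-text import assumes a matrix export (columns = channels);
  proprietary amplifier containers are deliberately not parsed.
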