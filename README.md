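# hdemg

Spatiotemporal analysis of forearm **high-density surface EMG (HD-sEMG)**
during hand/wrist gestures: from raw 64-channel monopolar recordings to
activation heatmaps, center-of-gravity (COG) spatial statistics,
repeatability and inter-gesture similarity matrices, activation-pattern
dimensionality, and offline myocontrol (gesture classification) performance.

The package targets researchers in neurophysiology and assistive robotics who
study how muscle-activation patterns differ between healthy individuals and
people with neuromuscular conditions such as Duchenne muscular dystrophy
(DMD), and who assess whether those patterns can drive myoelectric control of
hand exoskeletons. Every analysis stage is exercisable without clinical
recordings through a synthetic-cohort generator with planted ground truth.

## The analysis chain

Recordings come from an 8×8 electrode grid wrapped around the forearm
(longitudinal inter-electrode distance fixed at 2 cm; circumferential
distance = circumference / 8), sampled at 2,048 Hz, with a protocol of 10
repetitions of 3 s contractions separated by 3 s rest, for 7 gestures.

1. **Conditioning** — faulty-channel repair by 8-neighborhood interpolation
   (rows wrap around the forearm), zero-phase 4th-order Butterworth band-pass
   20–450 Hz, 2nd-order IIR notch at 50 Hz (Q = 50).
2. **Envelopes** — full-wave rectification, 3rd-order 2 Hz Butterworth
   low-pass.
3. **Segmentation** — contraction onset at the first sample where the summary
   envelope exceeds baseline mean + 10 baseline SD; each contraction window is
   3 s from its onset; the steady-state window is the middle 1 s.
4. **Normalization** — per electrode, by the maximum of the 1-s
   moving-averaged envelope across the participant's complete dataset.
5. **Heatmaps** — per repetition, each grid cell holds the mean steady-state
   envelope of its electrode; gesture maps are averages of the 10 repetitions.
6. **Spatial statistics** — COG = amplitude-weighted centroid of cells
   ≥ 80 % of the map maximum, with a circular (wrap-aware) row centroid,
   mapped to % of forearm circumference (COGx) and length (COGy).
7. **Motor metrics** — repeatability and gesture similarity as squared
   Pearson R² between vectorised heatmaps (45 repetition pairs per gesture,
   21 gesture pairs per participant); dimensionality as the number of
   principal components explaining > 90 % of the variance of the 64 × 70
   heatmap concatenation.
8. **Myocontrol** — Hudgins time-domain features (MAV, ZC, SSC, WL) over
   200 ms windows with 100 ms overlap on the concatenated steady-state
   segments, classified by shrinkage LDA under three-split Monte Carlo
   cross-validation (stratified 70/30), for gesture counts k = 2…7.

## Worked example

```python
from hdemg.pipeline import StudyConfig, run_study

config = StudyConfig(n_healthy=1, n_dmd=1, fs=1024.0, n_repetitions=6,
                     rest_s=2.0, seed=1)
report = run_study(config)

act = report.activations.groupby("group")["max_normalized"].mean()
dim = report.dimensionality.set_index("participant")["n_pcs_90"]
acc = report.accuracy.query("k == 7").groupby("group")["mean_accuracy"].mean()
print(act.round(3).to_dict())
print(dim.to_dict())
print((100 * acc).round(1).to_dict())
```

prints

```
{'dmd': 0.69, 'healthy': 0.283}
{'HP1': 4, 'DP1': 3}
{'dmd': 95.3, 'healthy': 100.0}
```

The DMD-profile participant performs comfortable gestures much closer to
maximal contraction level (normalized activation 0.69 vs 0.28), needs fewer
principal components to cover the gesture space (3 vs 4), and loses more
classification accuracy as all seven gestures are included — the group
contrasts the synthetic profiles are designed to plant.

The same pipeline is available from the shell:

```bash
hdemg synth --group dmd --n 1 --seed 1 --out cohort/   # session bundles + ground truth
hdemg validate cohort/DP1/hand_open
hdemg run --seed 1 --out report/                       # full study, CSV + JSON report
```

## Data formats

A session bundle is a directory with `metadata.json` plus `signals.f32`
(little-endian float32, channels × samples, row-major) — documented,
language-neutral, and bit-exact under round-trip. Delimited CSV (one column
per channel, microvolts) is supported for import/export of externally
recorded data. Synthetic cohorts carry a JSON ground-truth sidecar (template
centers, planted rank, onset times, seeds).
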