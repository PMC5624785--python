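# Methods

Conventions, model assumptions and numerical choices behind `dtraf`. The
package implements the quantification methods of a live-cell study of
dendritic secretory trafficking; because the original raw microscopy data are
not deposited, every measurement is validated instead on synthetic data with
recorded ground truth, generated by `dtraf.synthgen`.

## Geometry and calibration conventions

* All physical coordinates are Euclidean 2D positions in micrometres (µm).
  Pixel `(row, col)` has its **center** at
  `x = (col + 0.5) · pixel_size_um`, `y = (row + 0.5) · pixel_size_um`.
  Rasterization assigns a pixel to a polygon iff its center lies inside.
* Frame `k` occurs at `k · frame_interval_s`; frame 0 is the release/bleach
  reference.
* No operation accepts pixel data without calibration. Stacks read from disk
  must carry `pixel_size_um` in the JSON sidecar; a missing field raises an
  error naming it — a pixel size is never silently assumed.
* `ImageStack` holds float64 counts in memory so noise-free synthetic data
  round-trip measurement arithmetic exactly; quantization to uint16 happens
  only on disk (TIFF per channel + JSON sidecar).

## The synthetic generator

`SynthConfig` defaults describe a plausible cultured-neuron field at typical
confocal calibration: 0.1 µm pixels, 0.25 s frame interval, Gaussian PSF with
σ = 0.13 µm, background 50 counts inside the cell, Poisson photon noise plus
Gaussian read noise (SD 2), punctum amplitude 2000 counts (integrated). The
default geometry is a circular soma (radius 8 µm) with straight horizontal
dendrites (length 80 µm, half-width 1 µm) carrying spines every 4 µm.

What the generator **does** emulate:

* diffraction-limited emitters (sum-normalized Gaussian stamps), shot noise,
  read noise, a uniform cellular background, 16-bit clipping;
* organelle coupling: a Bernoulli(`p_couple`) subset of puncta placed at a
  folded-normal radial offset |N(0, σ)| from a partner punctum, resampled
  until inside the cell mask;
* vesicle motion as run/pause/reverse steps along the dendrite
  (1 µm/s runs, p_pause 0.3, p_reverse 0.05 per frame), with an independent
  per-frame marker-channel localization jitter (SD 0.05 µm) on
  double-positive tracks and a population of marker-only distractor tracks
  (25% of the cargo count by default);
* photoconversion profiles: intensity decaying as `exp(−d/λ)` with arc
  distance `d` from the conversion-zone edge;
* spine fields with Bernoulli RE occupancy (`p_re`) and conditional cargo
  gain (`p_gain`), and surface-delivery time courses (below).

What it does **not** emulate: z-sectioning and out-of-focus light (single
plane; `max_project` exists for real z-stacks), dendrite curvature and taper,
photobleaching, chromatic offset, stage drift, and molecular detail of any
kind. These are irrelevant to validating the estimators, which is the
generator's only job.

## Measurement choices

**Puncta detection** finds local maxima with a prominence ("tolerance")
criterion after Gaussian smoothing, restricted to an analysis mask. The
production path uses morphological reconstruction by dilation
(scikit-image); an independent union-find descending-flood implementation is
kept as a test oracle and must agree exactly. Detection operates on smoothed
float images, where tied neighbouring maxima do not occur.

**Proximity null.** Dendrites are thin, elongated regions; colocalization
must be judged against randomization *within the morphology mask*, not the
bounding box. `randomize_in_mask` redraws target positions uniformly over
mask pixels (uniform within the pixel); the empirical p-value uses the
add-one estimator `p = (1 + #{null ≥ observed}) / (n_rand + 1)`, which can
never return 0.

**Soma fraction** is the background-subtracted integrated converted signal in
the soma mask divided by the same over the whole-cell mask. The background
per pixel is either supplied or estimated from outside the cell mask.

**Length constant.** `fit_length_constant` fits `I(d) = A · exp(−d/λ)` by
least squares on the per-punctum (distance, intensity) pairs. λ follows the
standard 1/e convention: at distance λ the signal has decayed *to* 1/e
(≈ 36.8%) of its zone-edge value. Fits hitting the upper bound (10⁴ µm) are
reported as unconfined rather than as a number.

**Cotrafficking.** Per-frame detections are linked greedily by nearest
neighbour (ties broken by distance then track id; a track closes when the
frame gap exceeds `max_gap_frames`). Mobile tracks require ≥ 3 frames and
≥ 1 µm net displacement. A mobile cargo track is double-positive when a
marker detection lies within the match radius in at least 75% of its frames.

**Spine occupancy.** A spine is positive for a channel when the maximum over
its ROI disc exceeds the shaft mean + 2 SD. Shaft-mask pixels are excluded
from the ROI maximum: they belong to the very background population the
threshold is estimated from, and including them makes the max of ~50
Poisson-background pixels exceed mean + 2 SD routinely (a ~16% false-positive
rate in validation against generator truth; zero after the exclusion).

**Delivery kinetics.** Surface signal fold-change over baseline follows
`fold(t) = 1 + (plateau − 1) · (1 − exp(−max(t − delay, 0)/τ))`: unity at
and before the delay, saturating exponential rise to the plateau afterwards.
This is the only form consistent with both a fold-change of 1 at t = 0 and a
long-time plateau; a formulation in which the plateau multiplies the whole
rise term would start at `plateau` instead of 1 and is rejected.

**Resolution estimate.** `estimate_resolution` converts a measured bead FWHM
to an instrument resolution by quadrature **subtraction** of the bead size:
`sqrt(FWHM² − bead²)`. The source study reports ~60 nm from a 72 nm FWHM
measured with 40 nm beads, which matches subtraction
(`sqrt(72² − 40²) ≈ 59.9`), although its printed formula reads as an
addition; addition would make the "resolution" exceed the measured FWHM,
which is physically impossible, so the subtraction (deconvolution)
convention is implemented.

## Statistics: implemented, not delegated

The two-sample Kolmogorov–Smirnov test (pooled-ECDF D statistic, asymptotic
p via the Kolmogorov series with the effective-n correction) and the
two-sample t-test (pooled and Welch variants, p via the regularized
incomplete beta function) are implemented in this package; the scipy
versions appear only as independent cross-checks in the test suite. The
Clopper–Pearson exact binomial confidence interval (`binomial_ci`) uses the
beta-quantile closed form.

## Validation problem sizes

Sizes used in the acceptance runs are the package's own choices, made for
estimator accuracy and recorded here:

* **Cotrafficking at n = 2000** runs the full render → detect → link → match
  pipeline on 2000 cargo tracks split across independent 60-µm dendritic
  segments (2000 resolvable vesicles cannot coexist in one field). Track
  density was set by *measured estimator bias*, not by outcome:
  misclassification is one-directional (true double-positives lost to link
  swaps at track crossings), with bias ≈ −3.3% at 20 tracks/segment, −1.1%
  at 5, −0.5% at 3 and 0 at 1. The frozen default is 3 cargo tracks per
  segment over 40 frames — residual bias well inside the binomial 99% CI
  half-width at n = 2000 — at ≈ 0.4 s/segment.
* **Spine occupancy at ~2000 spines** uses a 41-dendrite field with 2 µm
  spine spacing (2009 spines) rendered in one frame.
* **Constructed soma-fraction images** carry a 600 000-count photon budget so
  that shot noise perturbs the image's realized somatic fraction by
  σ ≈ 0.08%, an order of magnitude below the ±1% recovery tolerance; at a
  ten-fold smaller budget the realized fraction itself fluctuates by ~0.6%
  and the construction no longer pins down the quantity being recovered.

## Reproducing the acceptance targets

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Targets: t1 length constant (µm); t2/t3 somatic percentage of converted
signal after dendritic/somatic conversion; t4/t5 double-positive
cotrafficking percentage at the 150-min and 1-h reference probabilities;
t6 cargo-gain percentage among RE-positive spines; t7 spine RE-occupancy
percentage; t8 dendritic percentage of fusion events. Per-target seeds are
derived as `(seed · 1000003 + salt) mod 2³¹` so every target sees an
independent stream.
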