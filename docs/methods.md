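# Methods

This document records the physical model, the numerical design decisions and
the known limitations of `holoflow`. It is written for a reader who wants to
verify or extend the package, not for an end user (see the README for that).

## 1. Hologram formation model

A frame of the simulated camera records

```
I(x, y) = R² + A(x, y)² + 2 R A(x, y) cos(2π (fx·x + fy·y) + φ(x, y))
```

with reference amplitude `R = 1`, object amplitude `A ≤ 1`
(Beer–Lambert absorption through the phantom) and object phase

```
φ = 2π · OPD / λ,       OPD in the same length unit as λ.
```

Defaults model a HeNe setup: `λ = 632.8 nm`, effective pixel pitch
`0.16 µm/px` at the sample, carrier frequency `0.35 cycles/px` at `45°`,
coherent pupil (numerical-aperture low-pass) with cutoff `0.11 cycles/px`.
OPD values are carried in nanometres throughout the package.

Internally the complex object field is low-pass filtered by a hard circular
pupil of radius `na_cutoff` **before** interference; this models the finite
NA of the imaging system and is also what makes the round-trip criterion
well-posed: the reconstruction can only ever recover the pupil-filtered
field, so ground truth for round-trip comparisons is
`imaged_opd(...)` (the phantom's OPD passed through the same pupil), not the
raw analytic projection.

Intensity noise is Gaussian, `σ = noise_sigma × mean(I)`, clipped at zero;
frames are stored as uint16 TIFF via a fixed scale factor so the video
round-trips losslessly to ~1.5e-5 relative precision.

### Carrier snapping

`OpticalConfig.snap_carrier(shape)` moves the requested carrier to the
nearest integer FFT bin for the given frame shape (at most half a bin, and
idempotent). Two reasons:

1. With an on-grid carrier, `demodulate_exact` (multiply by the conjugate
   carrier, low-pass) and `extract_wavefront` (shift the located sideband
   peak) agree to machine precision, which turns the reconstruction tests
   into exact statements instead of tolerance haggling.
2. Off-grid carriers leak energy across bins and create a deterministic but
   shape-dependent bias in the recovered phase tilt; snapping removes it at
   the source rather than fitting and subtracting a residual ramp.

Validation enforces `carrier ≥ 3 × na_cutoff` so the sideband, its
conjugate and the autocorrelation (DC) term never overlap — the standard
off-axis separability condition.

## 2. Reconstruction chain

`hologram_to_opd` is the composition:

1. **Demodulation.** FFT, select the sideband. Two implementations:
   `extract_wavefront` locates the sideband peak in a half-plane (excluding
   a DC radius of 0.08 cycles/px), windows it with radius = half the
   carrier–DC distance, and recentres it; `demodulate_exact` multiplies by
   `exp(−2πi(fx·x + fy·y))` and low-passes, which is exact for any carrier,
   on-grid or not. The pipeline uses the peak-locating variant (it needs no
   prior knowledge of the carrier); tests cross-check the two.
2. **Background compensation.** Divide by the demodulated field of a
   cell-free background frame. This cancels the reference tilt, pupil
   ringing and any fixed-pattern amplitude. The divisor is regularised by a
   floor of `1e-6 × max|background|`; an identically zero background is
   rejected as an error rather than silently regularised.
3. **Sign resolution** (`positive_bias`). The two spectral sidebands give
   `±OPD`; the sign is resolved by choosing the branch whose mean OPD over
   the frame is positive, which is correct for cells (positive dry mass) on
   an empty background. `conjugate=True` selects the other sideband
   explicitly; the acceptance suite checks the two reconstructions are
   antisymmetric to < 1 nm RMSE.
4. **Unwrapping.** `skimage.restoration.unwrap_phase`; verified on a
   wrapped linear ramp to < 1e-6 rad residual (up to the global constant,
   which unwrapping cannot determine).
5. **OPD conversion.** `OPD = φ λ / 2π`, exact by construction
   (`phase_to_opd(2π, λ) == λ` bitwise).
6. **Background zeroing.** `zero_background` subtracts the median of an
   8-pixel border ring, pinning the empty-field OPD at 0 nm.

`stability_maps` reports per-pixel temporal standard deviation and
per-frame spatial standard deviation of a reconstructed OPD stack — the
usual empty-field stability figures of merit.

## 3. Phantoms and class design

Phantoms are analytic, piecewise-constant refractive-index bodies: an
ellipsoidal cytoplasm (Δn ≈ 0.02–0.04 against the medium), an ellipsoidal
nucleus, and optional spherical granules. Projection along the optical axis
is computed by supersampled analytic chord lengths (no voxelisation), so
the integrated OPD is conserved under rotation to < 2 % — the projections
of a rigid body from different angles must carry the same dry mass, and
the tests enforce this.

The three classes are designed so the two headline comparisons have
something real to detect:

* **class 0** — smooth cell, no granules: baseline.
* **class 1** — same envelope plus ~10 small *absorbing* granules. Their
  OPD contribution is small; their signature lives mainly in the amplitude
  (Beer–Lambert) channel. This is what makes "hologram ≥ OPD" a fair,
  physically motivated test: a phase-only OPD map demonstrably discards
  class-1's strongest cue.
* **class 2** — an elongated class 1 (axis ratio 1.5). A single projection
  of an elongated body viewed end-on is nearly indistinguishable from
  class 1; multiple rolling views disambiguate it. This is what makes the
  multi-view benefit real rather than an artifact of extra averaging.

## 4. Scene simulation and ground truth

`FlowScene` spawns cells at the left edge with Poisson-thinned arrivals,
advects them along the column axis at 40 px/frame (with ±1 px jitter), and
rolls them about an axis perpendicular to the flow between frames.
Non-rolling datasets freeze the orientation instead. Ground truth records
per frame and per cell: centroid, class label and orientation, and is
written as a plain CSV.

## 5. Detection, filtering, tracking

Detection: background model = per-pixel temporal median of the hologram
video; per-frame absolute deviation from it is smoothed, thresholded
(Otsu with a floor), and labelled; region properties come from
`skimage.measure.regionprops`.

Filter gates (all must hold; ranges inclusive, single-sided gates strict):

| quantity | gate |
|---|---|
| area (px) | 300 ≤ a ≤ 7100 |
| minor/major axis ratio | > 0.62 (ratio defined as 1.0 when major = 0) |
| circularity 4πA/P² | > 0.26 |
| eccentricity | < 0.85 |
| equivalent diameter (px) | 38 ≤ d ≤ 120 |
| fully in frame | bounding box touches no border |

Track gates between a track's last detection and a candidate in a later
frame (all strict): perpendicular distance < 21 px, along-flow displacement
in [0, 480) px, |Δarea| < 890 px², |Δminor| < 14 px, |Δmajor| < 21 px.
Linking is greedy per frame in sorted frame order: candidate pairs are
sorted by (distance, detection index, track index); each detection joins at
most one track and each track takes at most one detection per frame; a
track is eligible only if its last frame precedes the current one.

These exact semantics are frozen by brute-force oracles in the test suite
(`tests/test_segtrack.py`): literal re-implementations of the published
thresholds, exercised on 1000 boundary-biased random records and on the
detections of 50 simulated scenes.

`crop_and_pad` cuts a centred square of fixed pad size around each tracked
detection (raising if the detection is larger than the pad); a track's
crops, capped at 10 projections, form a `ProjectionSet` — the unit the
classifier consumes.

## 6. Re-fringing augmentation

`refringe` demodulates a hologram crop at its (known or located) carrier
and re-synthesizes the interference pattern on a new random carrier,
optionally with fresh noise. Because demodulation is exact, the underlying
complex field — hence the reconstructed OPD — is invariant to < 2 nm RMSE
over random carriers (acceptance criterion 4). This gives the
hologram-domain classifier carrier-frequency invariance without ever
reconstructing phase during training.

## 7. Classifier

`holoflow.nn` is a small pure-numpy CNN engine: im2col convolutions,
depthwise convolutions, inverted-residual blocks (MobileNet-v2 style with
ReLU6), global average pooling, dense head, softmax cross-entropy, Adam.
Pure numpy keeps the dependency set text-only and portable, makes bitwise
determinism straightforward (single-threaded deterministic BLAS paths, all
randomness through seeded `numpy.random.Generator`s), and is fast enough
at desk scale (a full 25-run sweep trains in ~14 min on one CPU).

Every layer is verified by central-difference gradient checking at
float64 (module-global dtype is switched for the test). One subtlety worth
recording: gradcheck must randomize all parameters away from zero first,
because zero-initialised biases put pre-activations exactly on the ReLU6
kink where the numerical derivative is ill-defined.

`FusionModel` runs K backbone heads (optionally weight-shared) over K
projections of a cell and fuses by concatenating the K latent vectors into
one dense softmax head. `initialize_from_single_view` warm-starts a K-head
model from a trained single-view model. Inputs are per-crop standardised
and centre-cropped to 96 px (the informative cell region; full 128-px pads
waste compute on empty fringes).

Training recipe (desk scale, fixed before any acceptance outcome was
observed): batch 16, Adam lr 2e-3, 15 epochs, best-epoch restore on the
validation split; splits are stratified 80/10/10 by cell with deterministic
fold cycling. `paired_one_sided_pvalue` is a paired one-sided t-test over
seeds (scipy), used by the acceptance comparisons.

## 8. The experiment (`multiview_experiment`)

Two datasets of 150 cells/class × 3 classes with 5 projections each,
generated directly from the phantom sampler (bypassing detection, so the
comparison isolates the classifier): a *rolling* dataset (seed 11) and a
*fixed-orientation* dataset (seed 12). Four sweeps, 5 seeds each:

* rolling, hologram domain, K ∈ {1, 3, 5}
* rolling, OPD domain (same crops, reconstructed), K ∈ {1, 5}
* non-rolling, hologram domain, K ∈ {1, 5}

K ∈ {1, 3, 5} (rather than every K) keeps the full sweep inside a 15-minute
CPU budget; the OPD and non-rolling arms only need the endpoints their
criteria compare. Pilot runs during development gave rolling-hologram
accuracies ≈ 0.89 / 0.96 / 0.97 at K = 1/3/5 and OPD-domain accuracies
lower by ≈ 0.1–0.2 at each K.

## 9. Determinism

All stochastic code takes explicit seeds and derives child generators via
`numpy.random.default_rng` spawning; the engine is single-threaded numpy.
Re-running simulation, detection/track CSV export, training histories and
the full pipeline with the same seed reproduces byte-identical artifacts
(criterion 7 and the pipeline tests assert this). Run directories carry a
`provenance.json` with the seed and a SHA-256 over the canonicalised
configuration.

## 10. Limitations

* The optical model is scalar, unit-magnification, aberration-free apart
  from the hard circular pupil; no speckle, no coherent shot-noise model
  (noise is Gaussian in intensity).
* Phantoms are piecewise-constant and convex-ish; no membranes, no
  subresolution texture. Class separability is therefore easier than for
  real cytology data; the accuracies reported here are not claims about
  real cells, only about the relative comparisons (multi-view vs single,
  hologram vs OPD) under a controlled forward model.
* Rolling is rigid-body rotation at a fixed rate; real cells deform.
* Tracking assumes a single dominant flow axis and no cell crossings at
  the default density; purity degrades in denser scenes.
* The unwrapping step inherits `skimage`'s limitations for phase maps with
  residues; the default phantoms stay well below 2π per pixel gradients.
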