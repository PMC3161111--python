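# Methods

## Line-scan velocimetry model

A capillary is scanned repeatedly along its axis at 1–4 lines/ms. The
resulting image I(x, t) has rows sampling position along the vessel
(Δx µm/pixel) and columns sampling time (Δt ms/pixel). An unlabelled
cell moving at speed v traces the line x = x₀ + v·t, i.e. a streak of
pixel slope s = v·Δt/Δx (rows per column). An oriented pattern f(x − s·t)
has its Fourier energy on the central line k_t = −s·k_x, perpendicular
in pixel-frequency coordinates to the streak direction. Measuring the
angle θ of that line from the temporal-frequency axis gives
tan θ = −1/s, hence v = (Δx/Δt)·|cot θ|. The sign of θ encodes flow
direction and is reported separately; the speed is a magnitude.

### Estimator details and numerical choices

- **DC handling.** The scalar image mean is subtracted before the FFT
  and the radial sum starts at r = 1. Without this, the DC bin and its
  leakage dominate every ray and produce spurious maxima at θ = 0 or
  ±π/2. The centre bin is pinned to exactly zero after mean
  subtraction.
- **Angular grid.** 180 bins, θ_k = −π/2 + k·π/180. Antipodal rays are
  redundant for real input (verified against a brute-force antipodal
  resampling in the tests), so only the half circle is scanned. Ties in
  the argmax break toward the smallest index, for determinism.
- **Radial limit.** R = floor(min(shape)/2) − 1 (255 for 512×512), so
  every bilinearly interpolated polar sample lies inside the array;
  points outside contribute zero.
- **Non-square images.** The polar grid lives in array-index space; on
  an N_space × N_time image a ray at index angle θ_idx corresponds to
  the physical frequency angle arctan(tan(θ_idx)·N_time/N_space). The
  estimator converts the profile peak to the physical angle before the
  cot mapping (identity for square images). Without the conversion,
  speeds from elongated crops are wrong by the aspect ratio.
- **Windowing.** No apodization by default; an optional 2D Hann flag
  exists because rectangular-window leakage along the axes can matter
  for short windows. Temporal windows < 8 pixels are rejected; 8–31
  pixels warn, because estimate scatter grows sharply below 32 pixels
  (reproduced in the window-dependence tests for both the FFT and Radon
  estimators).
- **Angle-to-speed degeneracy.** The relative quantization error of one
  angular bin is ≈ (π/180)/(sin θ·cos θ): it exceeds 5% for θ within
  ~10° of either axis. Accuracy tests therefore match Δt (0.25–1
  ms/pixel, as an operator would) to each speed so that θ stays in the
  well-conditioned range; speeds whose angle falls within ~2 bins of an
  axis are out of the measurable range for that sampling.
- **Spectral-ridge interference.** On frames smaller than ~256², the
  streak ridge is modulated by interference between randomly placed
  streaks and the peak can wander 1–3 bins; 512×512 frames (the
  reference acquisition size) show sub-bin accuracy in all tested
  conditions.
- **Band-pass filter.** An annular mask in cycles/pixel applied to the
  centred spectrum and inverse-transformed. The all-pass band is the
  identity to ~1e-9. Removing the lowest radial frequencies rescues the
  estimate when a strong smooth background corrupts the profile peak.

### Comparator estimators

Both comparators search the same π/180 grid and share the Δx/Δt
geometry (image-space streak angle φ; v = (Δx/Δt)·|tan φ|; θ = φ ∓ π/2).

- **Radon.** Projection variance per angle, computed with
  `skimage.transform.radon` (`circle=False`, which zero-pads so steeply
  rotated thin windows are not clipped). A streak at angle φ from the
  time axis is integrated coherently at Radon angle 90° − φ.
- **SVD.** The mean-subtracted image is embedded in a square zero
  canvas, rotated over the grid (bilinear, zero fill), and the ratio of
  the leading singular value to the singular-value sum (separability)
  is maximised. Aligning streaks with either image axis makes the image
  near rank-1, so the best rotation is ambiguous by 90°; the ambiguity
  is resolved by testing whether the leading left (row) or right
  (column) singular vector carries the variance — horizontal streaks
  put the structure in the row vector. These are behavioural
  reimplementations for cross-validation, not line-by-line
  reproductions of the original methods.

## Synthetic line-scan scenes

The generator renders unit plasma background attenuated multiplicatively
by Gaussian-profile streaks (FWHM 4 µm — RBC scale for vessels under
6 µm) at fractional contrast 0.5. Streak positions follow a Poisson
process at 100 cells/mm (≈ one cell per 10 µm, a typical capillary
lineal density); streaks entering or leaving the window are clipped, as
in real acquisitions. Additive Gaussian noise (default SD 0.05 of the
background; 0.1 in the robustness experiments) models detector noise;
Poisson shot noise is available behind a flag. Identical parameters and
seed give bit-identical images, and the reported ground-truth angle fed
to the speed formula returns the programmed speed in closed form.

**Non-vascular surround.** For uncropped-field experiments a stated
fraction of spatial rows is replaced by surround whose mean matches the
vessel's time-averaged brightness plus uncorrelated noise (default SD
0.4), optionally with quasi-static smooth structure behind a flag.
Brightness matching is deliberate: a large static step between vessel
and surround concentrates energy exactly on the spatial-frequency axis
and can out-vote the streak peak — a genuine limitation of
scalar-mean-subtracted orientation analysis (listed below). With the
noisy surround, the angular profile keeps a single dominant peak while
the Radon projection variance acquires an angle-independent pedestal
that hides the peak height relative to a cropped vessel band — the
qualitative uncropped-versus-cropped contrast the robustness tests
assert. The margins used there (peak prominence ≥ 2 on ≥ 90% of seeds;
median uncropped/cropped prominence ratio ≥ 0.9 for the FFT and ≤ 0.7
for Radon) were fixed from pilot runs of these frozen conditions before
the tests were finalised.

What passing these tests does *not* show: performance under structured,
static tissue autofluorescence, strong vessel/surround brightness
steps, multiple vessels with different flow patterns in one window, or
pulsatile/time-varying flow — none of which the generator emulates by
default.

## Bolus transit model and AVTT pipeline

Each vessel pixel follows baseline + amplitude·σ((t − t_a − 3τ)/τ) +
noise, with τ = 50 ms wash-in, baseline 0.1, amplitude 1.0, noise SD
0.02, imaged at 14.2 frames/s with 10 pre-injection baseline frames.
Arrival times t_a are drawn i.i.d. per pixel from segment-specific
normals truncated at zero (arterial 0.29 ± 0.28 s, venous 1.43 ± 0.48 s
by default). The 3τ offset keeps the pre-arrival logistic tail below
baseline-noise thresholds; because the wash-in shape is shared by both
segments, its detection delay cancels in the AVTT difference. Pixels
whose arrival exceeds the stack duration are flagged unreachable in the
ground truth and are always excluded by the pipeline.

Pipeline choices:

- **Median filter** 3×3, per frame (spatial only). The filter bleeds
  vessel signal one pixel across mask borders; segment masks should not
  hug vessel edges.
- **Baseline statistics** use the sample SD (n−1 denominator).
- **Appearance rule.** Threshold = baseline mean + k·SD (k = 2);
  detection at the earliest post-baseline frame f such that frames
  f..f+P all *strictly* exceed threshold (P = 5: the appearance frame
  plus five subsequent time points, a six-frame run). Runs truncated by
  the end of the stack do not qualify. Raising k can only delay or
  remove detections (tested). Times are reported from the first
  post-baseline frame; only differences (AVTT) are physically
  meaningful, since injection timing within the baseline window is not
  modelled.
- **Segments** are mask-driven (binary images aligned to the stack), as
  vascular segmentation is normally drawn by hand from the spatial
  continuity of the appearance time. `segment_assist` automates that
  criterion by running-mean region growing from seed pixels; it is an
  extension, suitable when the within-segment arrival spread is small
  against the tolerance, and earlier-seeded labels win conflicts.
- **Area fractions** are reported relative to the full frame and
  rounded to the nearest integer percent.

**Truncation bias.** Drawing from N(0.29, 0.28²) truncated at zero
raises the arterial mean to ≈ 0.367 s (venous is barely affected), so
the expected pipeline AVTT on the default scene is ≈ 1.065 s rather
than the 1.14 s difference of the untruncated means; measured values
across seeds are 1.04–1.07 s. This is a property of the stated arrival
distributions, not of the pipeline, which recovers the generator's true
mean difference to < 0.02 s.

## Known limitations

- Single dominant flow pattern assumed: one vessel, one speed
  population per window. Mixed or reversing flows need windowed
  estimation and per-window inspection.
- Static structured backgrounds project onto the ±π/2 rays of the
  angular profile and can dominate it; row-mean (temporal-static)
  removal would suppress them but would also erase genuinely stationary
  streaks, so it is not applied.
- Angular quantization makes very fast flow (θ near 0) and near-static
  flow (θ near ±π/2) ill-conditioned at a given sampling; choose Δx/Δt
  so the expected angle is mid-range.
- The SVD comparator at full π/180 resolution is roughly an order of
  magnitude slower than the spectral estimator; its grid step is
  configurable.
- Wall-clock timings are logged for information only; they are
  hardware-bound and never asserted.
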