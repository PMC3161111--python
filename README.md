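# rbcflow

Microvascular blood-flow analysis for two-photon microscopy: mean red
blood cell (RBC) speed in single capillaries from line-scan (kymograph)
images, and arteriovenous transit time (AVTT) from dye-bolus time-lapse
movies of the cortical surface.

## Who this is for

Labs measuring cerebral microvascular perfusion with laser-scanning
microscopes. Repeatedly scanning a line along a capillary filled with a
fluorescent plasma marker yields a space × time image in which
unlabelled RBCs appear as slanted dark streaks; the streak slope encodes
their speed. Tracking single cells fails in low-contrast or deep-tissue
images, so `rbcflow` estimates the *mean* speed of the whole RBC
population from the global orientation of the image spectrum — no cell
detection, no cropping, no prior information.

## The estimator

For a line-scan image with spatial sampling Δx (µm/pixel) and temporal
sampling Δt (ms/pixel):

1. Subtract the image mean and take the squared-modulus 2D FFT
   (zero-frequency bin centred; it is exactly zero after mean removal).
2. Resample the power spectrum to polar coordinates (bilinear
   interpolation) and sum radially:
   g(θ) = Σ_{r=1..R} F(r, θ), over θ ∈ [−π/2, π/2) at π/180 resolution,
   with R = 255 for a 512 × 512 image (half the pixel number).
3. The angle θ̂ of maximum g, measured from the temporal-frequency axis,
   locates the spectral line perpendicular to the streaks.
4. Mean speed:  **v = (Δx/Δt) · |cot θ̂|**  (µm/ms ≡ mm/s).
   θ̂ = ±π/2 means stationary cells; θ̂ = 0 is out of measurable range.

Two comparator estimators are included for cross-validation: the Radon
transform method (projection angle of maximal variance) and the SVD
method (rotation maximising the leading-singular-value concentration).
The AVTT pipeline maps per-pixel dye appearance times (earliest frame at
which the pixel and the five following frames exceed the pre-injection
baseline mean + 2 SD), aggregates them over artery/vein masks, and
reports venous − arterial appearance time. Synthetic generators provide
line-scan scenes of known speed and bolus stacks of known arrival times
for every test.

## Worked example

Simulate a 512 × 512 line scan programmed at 1.1 mm/s with the
representative sampling (Δx 0.20 µm/pixel, Δt 1 ms/pixel), then estimate:

```bash
$ rbcflow simulate linescan --speed-mm-s 1.1 --seed 3 --out demo.tif
{
  "speed_mm_s": 1.1,
  "slope_px_per_px": 5.5,
  "theta_spectral_rad": -0.1798534997924781,
  ...
}
$ rbcflow speed demo.tif
{
  "speed_mm_s": 1.1342563639235417,
  "theta_rad": -0.17453292519943298,
  "peak_prominence": 126.48780089371144,
  "window_pixels": 512,
  "method": "fft",
  "direction": 1
}
```

The true spectral angle is −0.17985 rad (−10.31°); the π/180 grid puts
the peak at −10°, giving 1.134 mm/s — a 3% quantization error, within
the one-bin resolution of the angular grid. `peak_prominence` is the
peak-to-median ratio of g(θ) (here ≈126, an unambiguous orientation);
`direction` reports the flow sign along the scan axis separately from
the speed magnitude. The same image analysed with `--method radon` or
`--method svd` returns the identical speed on clean scenes.

The AVTT side is exercised the same way: `rbcflow simulate bolus`
writes a stack plus artery/vein masks, and `rbcflow avtt` produces the
appearance-time map (float TIFF, NaN = excluded pixel), per-segment CSV
and an AVTT JSON.

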