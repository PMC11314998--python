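# Methods

## Model

A critical-illumination microscope images a square source of side `S` (mm)
onto the specimen through a collimator (focal length `f_col`) and objective
(`f_obj`); the specimen reflects the field back through the objective and a
tube lens (`f_tube`) onto the detector. Paraxially the in-focus conjugate
image has total magnification `M = f_tube / f_col` (the objective's two
passes cancel), so the in-focus field width on the detector is

```
w0 = S · M / pixel_pitch        [px],   pixel_pitch = detector_side / detector_pixels.
```

With the default geometry (S = 1 mm, f_col = 12 mm, f_tube = 200 mm, 20 mm /
4000 px detector) this gives `M = 16.67` and `w0 = 3333.3 px`.

Defocus `z` (µm; negative toward the lens) changes the effective
magnification and blurs the edges. The simulator uses a phenomenological
model in place of ray tracing:

```
w(z)     = w0 · (1 + α·z + γ·z²)      plateau width, px
σ(z)     = σ0 + β·|z|                 Gaussian edge blur, px
I(x, y)  = B + A · E(x) · E(y) + ε    E = blurred-box profile (difference of erfs)
```

with plateau amplitude `A = peak_intensity · intensity_scale`, background
`B`, and additive Gaussian noise `ε ~ N(0, noise_sd²)` per pixel (optional
Poisson shot noise). The square field is separable, so a frame is the outer
product of two 1-D profiles; every frame is a pure function of
(config, z, offset, intensity_scale, seed).

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α | −1.0 × 10⁻³ | 1/µm | largest round value for which `w(z)/2 + 3σ(z)` stays on the 4000 px detector over the full ±100 µm declared range; gives a native metric slope `k = w0·α ≈ −3.33 px/µm`. (Real instruments report steeper slopes on interpolated grids; the native-pixel slope is the honest unit here.) |
| γ | 1.0 × 10⁻⁸ | 1/µm² | mild large-defocus nonlinearity. A linear d₀ fitted over ±50 µm absorbs the curvature mean (≈ 850·γ·w0 px), which becomes a systematic closed-loop offset of `850·γ/|α|` ≈ 8.5 nm — kept an order of magnitude below the 78 nm actuator step, matching the observation that the fine range is essentially linear and curvature appears only beyond it. |
| σ0, β | 2 px, 0.5 px/µm | | edges stay resolvable (σ ≤ 52 px) over ±100 µm. |
| peak, background | 60 000, 500 | counts | bright plateau on a 16-bit detector, ~92 % of saturation. |
| noise_sd | 10 | counts | sCMOS-scale read/dark noise in counts; laser ripple and shot noise can be emulated via `intensity_jitter` and `shot_noise`. |

## Measurement pipeline

1. **Profile** — mean over the centered band of rows (`band_fraction`,
   default 0.5). Averaging 2000 rows suppresses pixel noise by ~45×; a
   single line cut remains available (`band_fraction → 1 row`).
2. **Smoothing** — Gaussian pre-smoothing of the profile
   (`smooth_sigma = 5 px` by default). This plays the role of the image
   interpolation step used on real instruments: without it, at large
   defocus the gradient peak is nearly flat over one pixel spacing and the
   3-point refinement becomes noise-dominated. A symmetric kernel shifts
   both edges equally, so `d` is unbiased. `smooth_sigma = 0` restores the
   raw finite-difference path.
3. **Gradient** — forward difference `G[i] = p[i+1] − p[i]`, sample `i` at
   coordinate `i + 0.5` so a symmetric edge yields a symmetric extremum.
4. **Edge pair** — global maximum (rising) and minimum (falling) of `G`;
   the field has exactly one of each, and global search needs no window
   tuning. Ties resolve to the smaller index; a minimum preceding the
   maximum raises `inverted-edges`; a missing sign raises
   `no-field-detected`.
5. **Sub-pixel refinement** — parabolic vertex through the extremum and its
   neighbours, `offset = 0.5(y₋ − y₊)/(y₋ − 2y₀ + y₊) ∈ (−0.5, 0.5)`;
   scale- and offset-invariant; a flat triple returns offset 0 with a flag.
   Chosen over raster upsampling for equivalent precision at far lower
   cost.
6. **Metric** — `d = x_fall − x_rise`, `t = d − d₀`, `ẑ = t/k`.

## Calibration

`d` is fitted against `z` by ordinary least squares (`numpy.polyfit`),
default family linear, optional quadratic for ±100 µm stacks. `d₀` is the
*fitted* value at z = 0 rather than a single in-focus measurement: it is
noise-robust and makes `t(0) = 0` exact by construction. `R² = 1 −
SS_res/SS_tot`. Curves with `|k|` below `DEFAULT_K_FLOOR = 0.01 px/µm` are
rejected as degenerate. Protocol defaults: fine stack at 1 µm steps over
±50 µm; coarse stack at 5 µm steps over ±100 µm. No outlier rejection is
applied.

The sensitivity `1/|k|` is the defocus change that moves the metric by one
pixel — the detection limit at native pixel resolution; sub-pixel
refinement and row averaging push the practical repeatability well below
it.

## Closed loop

Each iteration captures `schedule[i]` frames (default `(1, 1, 16)`),
averages the per-frame estimates, and commands the stage by the full
negative estimate (proportional gain 1, justified by the linearity of the
curve), rounded half-to-even to an integer number of actuator steps
(default 78 nm). The loop stops early when `|ẑ| ≤ stop_tol` (default one
step). A detection failure is retried once with fresh frames, then aborts.

With round-to-nearest quantization the worst post-move residual is
`min_step/2 + bias`, where `bias ≈ 850·γ/|α|` is the curvature offset
absorbed by the linear calibration (≈ 8.5 nm at defaults) — hence the final
residual stays within one actuator step. Strict monotone contraction of
`|z|` cannot hold below the quantization floor (a ±39 nm residual is
re-randomized within the floor); the guaranteed and tested property is
`|z_{i+1}| ≤ max(|z_i|, min_step)`.

## What the simulator does and does not emulate

Emulated: magnification-driven width change with mild nonlinearity,
defocus-dependent edge blur, additive detector noise, optional shot noise,
lateral field displacement, laser intensity fluctuation, 16-bit saturation,
actuator quantization.

Not emulated: wave-optical PSFs and aberrations, speckle and fiber mode
structure, non-Gaussian edge asymmetries, stage drift/hysteresis,
temperature-dependent optics, exposure timing. Passing tests therefore
demonstrate the correctness and noise behaviour of the *algorithm* under
the stated field model, not the performance of any physical instrument;
real hardware adds error sources (vibration, speckle, drift) that the
robustness knobs (`offset_jitter_px`, `intensity_jitter`, `shot_noise`)
only approximate.

## Numerical choices and problem sizes

- Frames are rendered in float32 (noise included) and profiles reduced in
  float64; a full-size frame is 16 Mpx, so stacks are streamed
  (`iter_stack`, `measure_simulated_stack`) rather than materialized.
- The fitted-curve inversion for the quadratic family uses the root
  continuous with the linear solution, in a numerically stable form.
- Degenerate inputs: flat gradient → `no-field-detected`; flat extremum
  triple → offset 0 + flag; zero z-variance or < 3 calibration samples →
  invalid argument.
- Test and acceptance problem sizes: 101-frame fine calibration stacks,
  41-frame coarse stacks, 17 × 3 single-shot sweep over ±40 µm, 41-point
  sweep over ±100 µm, and 21 closed-loop starts at 10 µm spacing — the full
  pipeline at the instrument's native 4000 × 4000 px frame size. Unit tests
  use a geometrically similar 800 px instrument (same magnification chain,
  0.2 mm source) for speed.

## Known limitations

- The native-pixel slope (|k| ≈ 3.33 px/µm at defaults) is geometry-bound:
  detectors smaller than the ±100 µm field sweep require either a narrower
  declared range or interpolation-based gain, which this package reports in
  native pixel units instead.
- The quadratic width term is deliberately small; instruments with strong
  large-defocus curvature should calibrate with `family="quadratic"` or
  restrict the linear curve's validity range.
- The 3-point parabolic refinement approaches its noise floor when the
  blurred gradient peak is much wider than a pixel and smoothing is
  disabled; the default pipeline (row averaging + smoothing) avoids this
  regime.
- Timing figures of real hardware (exposure, actuator latency) are carried
  as informational metadata only and never asserted.
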