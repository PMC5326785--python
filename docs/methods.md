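# Methods

This note records the models implemented in `veinicf`, the parameter choices
that matter, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer would want to know about.

## The mixture model and the cylindrical fit

A vein crossing an image slice is modeled as an elliptical disk; each voxel's
QSM value is a linear mixture `chi_i = rho_i chi_vein + (1-rho_i)
chi_background` with `rho_i` the vein volume fraction. The fit
(`icf_core.fit_slice`) iterates four steps:

1. **Background subtraction.** `chi_background` is the mean over the crop
   outside the dilated vein mask, estimated once and held fixed — there is
   no update step for it in the iteration, by design.
2. **Segment areas.** Per axis, the brightest line of the
   background-subtracted image is located (ties broken toward the crop
   center, which is stable under symmetric noise). The summed intensity
   strictly beyond each of its two bounding half-integer grid lines, divided
   by the total, estimates the circular-segment area fractions `A1, A2`,
   clipped to [0, 1]. A vessel that only touches a grid line yields `A = 0`
   and is treated as tangent — the documented single-grid-crossing behavior
   for sub-voxel vessels; no further special-casing.
3. **Chord geometry.** `A = (theta - sin theta)/(2 pi)` is inverted by
   bracketed root finding (Brent, residual < 1e-12; the map is strictly
   monotone on (0, 2 pi)). Center and radius per axis follow in closed form.
   The denominator `cos(theta_1/2) + cos(theta_2/2)` is guarded at 1e-6:
   below it both chords would be near-diametral, which is inconsistent for
   adjacent grid lines, and the axis is flagged degenerate. One degenerate
   axis borrows the other axis' radius and centers on the brightest line;
   two degenerate axes invalidate the slice fit.
4. **Partial-volume rasterization.** The fitted ellipse (semi-axes = the two
   per-axis radii, rotated by the in-plane angle) is rasterized by 32x32
   fixed-grid sub-sampling per voxel — deterministic, with rim error of
   order 1/subsample (measured max ~1.5e-3 against a 512x512 reference).

Convergence: |change in mean-squared residual| < 1e-3 (map units squared;
ppm² for QSM), at most 15 iterations. Non-convergent slices are reported
with `converged=False` and retained in aggregates. After the loop,
`chi_vein` is the closed-form least-squares solution of the mixture over the
whole crop.

### Angle conventions and the tilt correction

`tilt` is the angle between the vessel axis and the slice normal (0 =
perpendicular vein = circular cross-section); `inplane` is the azimuth of
the vessel's in-slice projection from the first array axis. With this
convention the combined radius `R = (Rx fx + Ry fy)/2` with
`fx = sqrt((sin(ip) cos(t))^2 + cos^2(ip))`, `fy = sqrt((cos(ip) cos(t))^2 +
sin^2(ip))` reduces to the plain average for a perpendicular vein, which is
the property used to fix the convention. Applied to the exact axis extents
of a tilted cylinder's elliptical cross-section this combination carries a
systematic factor `(cos t + sec t)/2` independent of azimuth: +1.0% at 30°,
+6.1% at 45°. It is a deliberate small-angle-style approximation, not an
exact inversion; within the ±45° tilt range of the study conditions the bias
is below the stochastic fit error.

### Multi-slice segments

`fit_vein_segment` runs two passes: pass 1 assumes perpendicular slices;
the tilt and azimuth are then estimated from an inverse-fit-error-weighted
line through the per-slice centers, and pass 2 refits with those angles.
The tilt update is accepted only below 60° from the slice normal: beyond
that the vessel no longer presents a usable elliptical cross-section and a
three-point center-drift estimate is noise-dominated, so the
perpendicular-assumption fit is kept. Aggregate radius and center are
inverse-fit-error-weighted means; the vein susceptibility is re-estimated
with the aggregate geometry on the middle slice (simulation mode) or per
slice (in-vivo mode). Fewer than three usable slices keeps the pass-1 tilt
with a warning.

When ground truth is available (simulation mode), the per-slice fit errors
used for weighting are evaluated over the union of true and estimated vein
voxels, so a stray fit that parks its ellipse on a noise blob is penalized
for the residual it leaves at the real vein. Without truth (in vivo) the
estimated support is used — the only definition available there.

## Synthetic phantoms

`cylinder_phantom` emulates an infinite paramagnetic cylinder (the vein,
susceptibility contrast 0.30 ppm) in a uniform background at 7 T:

- **Signal.** Spoiled-GRE with saturation-recovery longitudinal weighting:
  `S = PD (1 - e^{-TR/T1}) e^{-TE/T2*} e^{i gamma dB TE}`. No flip-angle /
  steady-state term is modeled — the simulated protocol specifies none, and
  the term would only rescale both compartments. Tissue values: T2* 7.4 /
  33.2 ms, T1 2587 / 2132 ms, PD 0.90 / 0.77 (vein / background), TE 7.65
  ms, TR 25 ms by default.
- **Field.** Standard infinite-cylinder expressions: inside
  `dChi B0 (3cos^2 a - 1)/6`, outside `dChi B0 sin^2 a cos(2b) R^2/(2 r^2)`,
  `a` the axis-to-field angle. The `parallel`/`perpendicular` switch rotates
  B0, not the cylinder, so the image-grid geometry ranges stay fixed.
- **Rasterization.** 200 uniform random points per voxel, complex mean, on a
  high-resolution grid (numba kernel with an inline xorshift64* stream;
  a 3rd-order series replaces cos/sin where |phase| < 0.03 rad, relative
  error < 1e-9). Fully deterministic per seed.
- **Downsampling.** Centered k-space truncation with DC-preserving scaling;
  the crop size realizes the requested apparent radius (quantized; the
  achieved value is recorded as truth). Gibbs ringing near the vein is the
  expected, physical consequence.
- **Noise.** i.i.d. Gaussian on the real and imaginary channels of the
  downsampled volume (Rician magnitude). The volume is first normalized by
  the analytic noiseless background magnitude, so `noise_std` is expressed
  relative to background signal (background SNR = 1/noise_std). The raw
  saturation-recovery magnitudes at the stated TR/T1 are ~0.007, which would
  make an absolute noise std of 0.1 meaningless; the relative convention
  reproduces a contrast-to-noise range (~1.5–16 over the 0.05–0.5 sweep
  through the TKD stage) in which the method's documented CNR≈3 failure
  threshold and CNR>10 bias regime both occur inside the sweep.
- **Truth.** Ground-truth partial-volume maps by dense sub-sampling (16³ per
  boundary voxel, analytic fill elsewhere) and the achieved geometry.

"Infinite" is realized as a full-grid-length cylinder under periodic FFT
boundary conditions; only central slices are analyzed.

What the phantom does **not** emulate: flow/inflow, multi-echo acquisition,
coil combination, parallel-imaging artifacts, background fields from outside
the volume, non-cylindrical vessel shapes, and spatially varying hematocrit.
Passing tests therefore demonstrate correctness of the estimator under the
stated mixture and signal model, not performance on in-vivo data.

## Susceptibility reconstruction

The simulated phase is converted to susceptibility by a deliberately simple,
fully specified pipeline (`qsm`): phase → field (single-echo relation;
FFT-based Laplacian unwrapping enabled automatically when the analytic
intravascular phase can exceed ~2.5 rad at the phantom's echo time), then
thresholded k-space division against the unit dipole kernel
`D = 1/3 - (k·b)^2/|k|^2` with threshold 0.2 (values below it replaced by
`sign(D)·0.2`, DC set to zero), then an additive shift pinning the
outside-mask mean to the known background susceptibility. There is no
background-field removal stage: the simulation contains no sources outside
the volume.

A bypass route feeds exact mixture maps built from the true partial-volume
map directly to the fit, separating geometric-fit error from reconstruction
error.

Two consequences of this stage are worth knowing when reading simulation
results. First, thresholded division amplifies complex-domain noise several
times more than regularized iterative inversions do, so a given `noise_std`
yields a lower measured CNR here than a production QSM pipeline would give.
Second, for veins below ~2 voxels across, the complex-sum phase of boundary
voxels under-represents the vein (the vein's T2*-shortened magnitude is only
~0.43 of background at the default TE) while truncation overshoot inflates
the center voxel; the reconstructed vein is therefore more concentrated than
the true partial-volume profile, which biases the fitted radius low and the
fitted susceptibility high in noise-free systematic tests. Both effects are
properties of the reconstruction stage, not of the cylindrical fit — the
reconstruction-free oracle suite shows sub-3% geometry recovery.

## Study conditions and problem sizes

The validation study (`experiments`) runs three sweeps — TE 3–24 ms, noise
std 0.05–0.5, apparent radius 0.56–2.1 voxels — each under parallel and
perpendicular fields; every phantom draws a sub-voxel center offset in
[-0.5, 0.5]², a tilt in ±45° and an in-plane angle in 0–45°, all uniform.
The fit sees the middle three slices and a truth-derived mask dilated by
three voxels (6-connected); MIV/NPC/PPC are read off the middle slice;
`chi_background` for OEF is the measured outside-mask mean. Per-image seeds
derive from the base seed by counter (`numpy` SeedSequence), so results are
independent of execution order; failed images are recorded and excluded from
pooled statistics.

Grid presets: the default desk preset uses a 64³ high-resolution grid with
input radius 4 — the same truncation ratios, and hence the same final grid
sizes (9³–34³), as the full-scale 128³/radius-8 configuration, at a quarter
of the cost. The systematic-error study (three center positions × two field
orientations, zero noise, perpendicular vein) uses 256³/radius-16; the
full-scale 512³/radius-32 configuration is available via the
`systematic_paper` preset. The shipped study sizes (25 phantoms per
condition; 256³ systematic) were chosen so the complete replication runs in
minutes on a single CPU; standard errors on pooled OEF errors are then
~1–2 percentage points, which bounds how finely the full-scale study's
values can be compared.

## Known limitations

- The fit needs the vessel to cross two grid lines per axis for full
  accuracy; below ~0.75 voxels radius the tangent-boundary fallback gives
  partial correction only, and errors inflate (reproduced in the radius
  sweep).
- Low CNR (below ~3) makes the brightest-line selection unreliable; such
  slices are retained but discounted by the inverse-fit-error weights.
- The tilt correction is approximate ((cos t + sec t)/2 factor, above) and
  the tilt itself comes from a line through as few as three slice centers.
- Isotropic voxels are assumed throughout; anisotropic inputs trigger a
  warning, not a correction.
- The estimated in-plane angle enters the rasterized ellipse as a rotation
  of the per-axis radii, which is exact only when the tilt azimuth is
  grid-aligned; within the ±45° study range the residual is small against
  the stochastic error.
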