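# Methods

This note documents the models, estimators and numerical choices behind
afmetrics, and what the synthetic validation does and does not demonstrate.

## The measurement model

A tapping-mode SFM scan is a calibrated scalar field z(x, y): surface height
in nm sampled on a raster of known pixel size (nm/px).  All analysis in this
package operates on that field after vendor decoding; no filtering or
flattening is applied internally.  Raw scans are assumed to have been
flattened (first-order plane-fit subtraction) in the acquisition software
beforehand — residual tilt is exactly what the gradient-based detector is
robust to, but large uncorrected bow is out of scope.

Coordinates are 0-based (row, col) with row 0 the top scan line; selections
are half-open.  Pixel sizes are carried separately per axis and enter every
length/area/volume formula, so non-square scan rasters are handled.

### Calibration at ingestion

* **NanoScope v5**: `height = raw_int16 × Zscale × Zsensitivity / 2^16`, all
  three factors from the text header; pixel size = scan size / pixel count.
  Other header versions are rejected, not guessed.
* **JPK TIFF**: `height = offset + multiplier × stored`, with the two
  documented private-tag layouts (which pair of tags holds multiplier/offset
  changed with the acquisition-software version) tried in order; the
  thumbnail page is skipped.
* **Igor binary wave v5**: parsed from the published binary layout; the first
  2-D layer is used unless a layer label contains "height" (case-insensitive),
  which wins — deterministic and matching common AFM exports.  Wave and axis
  units (m, µm, nm) are converted to nm.
* **ASCII x-y-z**: header lines are skipped up to the first fully numeric row;
  the scattered points must tile a complete rectangular grid; pixel size comes
  from the coordinate spacing.
* **Rasters (TIFF/JPEG/PNG)**: intensity × user-supplied nm-per-unit scale.
  Rasters carry no physical calibration, so the pixel size is a required
  argument, never silently assumed.  RGB inputs are collapsed by luminance
  with a logged warning — convenience inputs, not metrology-grade.

Format dispatch precedence is explicit hint > magic bytes > file extension.

## Particle detection

Segmentation works in the gradient domain.  With 3×3 Sobel kernels
(edge-replicated borders), G = √(Gx² + Gy²) in nm per pixel index — keeping
the threshold behaviour identical across scan sizes for the same content.
The automatic base threshold is 4 × RMS(G), a standard automatic Sobel edge
level; the user's stringency is a multiplicative factor f on it, so the raw
edge set is monotone non-increasing in f.  The edge rings are then closed
(3×3 square), hole-filled, opened (3×3), and 8-connected components touching
the border are suppressed (their geometry is truncated and would bias every
statistic).  The resulting mask only *selects* pixels; all measurements use
the unmodified heights.

Why gradients: an additive background plane shifts every height but adds only
a constant to the gradient, so the detected support barely moves, whereas a
fraction-of-maximum intensity threshold couples directly to the tilt.  The
package ships `intensity_threshold_mask` as that conventional baseline, and
the validation quantifies the difference as mask IoU against the untilted
reference (measured ≈ 0.99 for gradient vs ≈ 0.10 for 15 %-of-max intensity
under a tilt of 20 % of the particle height across the image).

The background is the mean height outside *all* detected particles — the same
estimator in single-particle and high-throughput modes.

Stringency guidance: f = 1 is a reasonable default for noisy scans.  For
noiseless synthetic surfaces the validation uses f = 0.2, which extends the
mask to ≈ 3σ of a Gaussian bump so that ≥ 99 % of its analytic volume is
captured; at f = 1 the mask stops near 2σ and clips ~5–13 % of the volume.
On real, noisy images a low f admits noise edges — the stringency trades tail
capture against false structure, exactly the "adjust threshold" slider of
interactive tools.

## Volume

V = Σ_mask (h − background) × Δx Δy, in nm³.  Adding a constant to all
heights leaves V invariant (the background shifts identically).  Absolute SFM
volumes are distorted by tip-sample convolution, hence the linear
volume-to-mass map against a standard of separately measured volume and known
mass (mass = V × M_std / V_std), e.g. E. coli RNA polymerase at 450 kDa.

## Paths, profiles and widths

Freehand traces are sub-pixel (row, col) polylines.  Length is the sum of
segment lengths with per-axis pixel sizes.  For profiles the path is
resampled at uniform arc steps (default 1 px) and heights are read by
bilinear interpolation.

The width tool takes, at each resampled point, the cross-section orthogonal
to the central-difference tangent (stable against hand jitter), samples it at
0.25 px steps over ± half_width, and fits A·exp(−(s−c)²/2σ²) + b by least
squares.  The four-parameter form matters because AFM cross-sections sit on a
nonzero local background.  Initialisation: A = max−min, c = argmax,
σ = half-width at half max of the raw samples, b = min.  A fit is rejected
when the optimiser fails, σ exceeds the sampling window, the center leaves
the window, or A ≤ 2 × residual RMS; additionally, converged fits with
amplitude below 5 % of the strongest cross-section along the path are
demoted — those sections have left the molecule and would otherwise
contribute arbitrary widths to the summary.  FWHM = 2√(2 ln 2)·σ ≈ 2.35 σ,
converted to nm with the physical length of a pixel step along the
cross-section direction.

**Interpolation choice.**  Cross-sections are sampled with cubic-spline
interpolation, not bilinear.  Bilinear sampling convolves the profile with a
triangle kernel of variance 1/6 px², inflating fitted widths by ≈ +2 % at
σ = 2 px and ≈ +5 % at σ = 1.2 px — comparable to the effects being measured
(probe-radius differences).  Cubic interpolation reconstructs the profile to
≲ 0.5 % at σ = 1.2 px.  The plain height profile keeps bilinear interpolation
(documented, visually faithful, and its absolute accuracy is not
width-critical).  The spline prefilter is computed once per call, so the cost
is one pass over the image.

## Skeleton contour length

The support heights ≥ T is thinned to a one-pixel-wide, topology-preserved
skeleton after discarding 8-connected components smaller than min_pixels.
Length is computed from the 8-adjacent pixel pairs of the skeleton, each pair
once, under one of two metrics:

* `chain` (default): orthogonal steps count Δx (or Δy), diagonal steps
  √(Δx²+Δy²).  Simple and exactly matched by a brute-force pair-enumeration
  oracle, but a digitised straight line at angle θ is overestimated by
  cosθ + (√2−1)·sinθ − 1 relative — up to +8.2 % at 22.5° and +5.5 % on
  average over orientations.  This bias is inherent to the metric, not to the
  thinning.
* `calibrated`: Kulpa's weights (0.948 per orthogonal step, 1.340 per
  diagonal step, scaled by the physical pixel diagonal for anisotropic
  rasters), the standard digitised-curve length estimator.  It is unbiased in
  expectation over orientations; residual per-orientation error (±2–5 % on
  perfectly straight lines) averages out along curved molecules.  On the
  validation filaments (smooth random walks, 400–1200 nm at 2 nm/px,
  σ = 2.5 px) it recovers the true centerline length to within ~1 %, where
  the plain chain metric sits at +4.5…+6.5 %.

For contour-length studies of curved molecules use `calibrated`; `chain`
remains the default because its values are exactly reproducible by hand and
by the enumeration oracle.

Freehand tracing of the same filament overestimates length (dense sampling
plus hand jitter adds detours): with 1 px resampling and 0.3 px Gaussian
jitter the inflation is ≈ +9 %, and the skeleton estimate is never longer
than the jittered trace in the validation suite.  This reproduces the
characteristic freehand-vs-skeleton gap seen in practice.

The B-form dsDNA reference length, contour = base pairs × 0.332 nm, is
provided as `bform_contour_length_nm` for sanity-checking DNA measurements
(2686 bp → ≈ 892 nm).

## Angles and display

Angles between user points are computed in physical nm coordinates (so
anisotropic pixels do not distort them), clipped into [0°, 180°].  The 10×
display upsampling uses 4×4-neighbourhood cubic interpolation and divides the
stored pixel sizes by the factor; it is display-only and never feeds a
measurement.  The saved display render is a hillshaded 2-D image under a
perceptually uniform, red-green-colorblind-safe colormap (cividis).

## High-throughput records

Per-particle shape descriptors come from the ellipse with the same second
moments as the particle's pixel set: solidity (area / convex hull area),
eccentricity, full minor/major axis lengths scaled to nm.  The exported
"sum of pixel intensity" is the background-subtracted height sum in nm, so
sum × pixel area = volume exactly.  Axis lengths use pixel_size_x; for
non-square pixels the moment ellipse would need metric moments — a documented
limitation (records still carry both pixel sizes via the volume).  Folder
batches apply one stringency to every image, visit files in sorted order
(deterministic output) and skip unreadable files with a logged warning.
Histograms use equal-width bins over [v_min, v_max]; out-of-range particles
are excluded, and Σcounts equals the number of in-range records.

## Synthetic ground truth: what it shows and what it does not

The validation surfaces are Gaussian bumps h = A·exp(−r²/2σ²) (analytic
volume 2πσ²A·ΔxΔy; the discrete sum converges to the integral for σ ≥ 2 px)
and constant-cross-section ridges around exact centerlines (straight, arc, or
curvature-limited smooth random walk).  The Gaussian cross-section emulates
tip-sample convolution to first order: a blunter probe is a wider σ.  Seeded
plane tilt and i.i.d. Gaussian noise model residual background and
instrument noise.

Validation problem sizes (chosen to exercise the estimators well inside
asymptotic regimes): 20 blobs with σ ∈ [2, 6] px and A ∈ [0.5, 5] nm; 10
filaments of 400–1200 nm at 2 nm/px with σ = 2.5 px; probe-width comparison
at σ = 2.5 vs 1.2 px; oracle checks on 100 random 5×5 images and 50 random
thin curves.

What passing does *not* show: real scans add correlated line noise, drift,
imperfect flattening, touching molecules and genuine (non-Gaussian) tip
dilation.  Detection stringency must be chosen per dataset; volumes remain
calibration-relative; skeletons of touching or self-crossing molecules branch
and their summed branch length is not a single contour.  The generators also
refuse geometries the pipeline is documented not to handle (support within
4σ of the border, self-approaching walks), regenerating random walks with the
next seed, deterministically and logged.

### Fixture files

Each reader is exercised end-to-end through a minimal writer for its dialect
(NanoScope v5, both JPK tag layouts, IBW v5 with and without layer labels,
ASCII ± headers, float32 TIFF, 16-bit PNG, 8-bit JPEG), with the quantization
bound of each encoding reported by the writer and asserted on read-back
(JPEG, being lossy, is checked by correlation).  Writers are test/dev API
only: the package does not claim vendor-format authoring support.

## Degenerate inputs and tie-breaks

Empty masks raise (no particle); a mask covering the whole image raises (no
background).  Equal-area largest-particle ties resolve to the smallest label,
i.e. first in row-major scan order.  Empty skeletons return length 0 with a
warning when queried directly, but skeletonizing an empty support raises.
Cross-section windows that extend past the image edge are clamped to the
border values; fits there are subject to the usual rejection rules.
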