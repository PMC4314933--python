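# afmetrics

A scriptable metrology toolbox for scanning force microscopy (SFM/AFM) height
images of biomolecules — DNA, nucleoprotein filaments, and irregular protein
complexes.  It reproduces, as a Python library plus CLI, the analysis workflow
of interactive SFM metrology tools: open a vendor-format height map, select a
region, segment molecules from the background, and measure volume, contour
length, height/width profiles and angles per complex, or collect per-particle
statistics over whole images and folders.

## Who it is for

Single-molecule biophysics labs that image DNA and protein complexes by
tapping-mode SFM and need quantitative, reproducible geometry from the scans:
particle volumes for stoichiometry, contour lengths for DNA conformation,
cross-section widths (FWHM) for filament characterisation, kink angles for
architecture.

## What it computes

**Ingestion.**  NanoScope v5 binary (`.spm`/`.001`), JPK TIFF (calibrated by
the vendor's linear law `height = offset + multiplier × stored value`, trying
both private-tag layouts), Igor binary wave v5 (Asylum Research), ASCII x-y-z
tables with or without header lines, and plain TIFF/JPEG/PNG rasters.  Every
reader normalises to a `HeightMap`: heights in nm, pixel sizes in nm/px.

**Detection.**  Molecules are segmented from the *gradient* of the surface,
not its raw heights: the Sobel magnitude `G = √(Gx² + Gy²)` is thresholded at
`f × 4·RMS(G)` (`f` is the user stringency), the edge rings are closed,
filled, opened, and components touching the image border are discarded.
Because an additive background tilt contributes only a constant to `G`, this
is far more robust to residual slope than thresholding intensities — the
package ships an intensity-threshold baseline so the comparison is one
function call.

**Metrology** (always on the unmodified heights):

- volume `V = Σ (h − background) · Δx·Δy` over the selected particle, with the
  background estimated as the mean height outside all detected particles;
- freehand path length, height profile with mean ± SD;
- width profile: at each point of a traced path, the orthogonal cross-section
  is fitted to a Gaussian `A·exp(−(s−c)²/2σ²) + b` and reported as
  `FWHM = 2√(2 ln 2)·σ ≈ 2.35 σ`;
- contour length by topology-preserving skeletonization of the
  above-threshold support, with a plain (1, √2) chain metric or Kulpa's
  orientation-calibrated weights (recommended for curved molecules);
- angles between user-defined points, in physical coordinates;
- per-particle records (volume, background-subtracted intensity sum, solidity,
  eccentricity, ellipse axes) for whole images or folders, volume histograms,
  and linear volume→mass calibration against a standard of known mass
  (e.g. *E. coli* RNA polymerase, 450 kDa).

Everything is validated against synthetic surfaces with exact ground truth:
Gaussian blobs of analytic volume `2π σ² A`, filaments of exact centerline
length, seeded noise and tilt.  See `docs/methods.md` for the model details.

## Worked example

```sh
$ afmetrics synth --kind filament --seed 7 --size 200 --length 100 \
      --out demo.txt --truth demo.json
wrote filament image -> demo.txt
ground truth -> demo.json

$ afmetrics info demo.txt
file:        demo.txt
format:      ascii
dimensions:  200 rows x 200 cols
pixel size:  1 x 1 nm/px
height min:  0 nm
height max:  2 nm

$ afmetrics measure demo.txt --threshold-factor 0.2 \
      --skeleton-threshold 1.0 --min-pixels 10 --out results.csv
appended complex '1': volume 1048.58 nm^3 -> results.csv
```

`results.csv` then holds one row per measured complex (plus `#` provenance
comments recording input, format, pixel size, threshold and version):

```
image,label,volume_nm3,background_nm,...,skeleton_length_nm,angle_deg
demo.txt,1,1048.58,0.000105527,...,106.77,
```

The demo filament has a true centerline length of 100 nm and a Gaussian
cross-section of σ = 2 px and A = 2 nm amplitude.  A ridge like that carries
√(2π)·σ·A ≈ 10 nm² of cross-sectional area per nm of length, so ~1000 nm³
over 100 nm — the measured 1048.58 nm³ includes the rounded end caps.  The
skeleton length of 106.77 nm is the plain chain metric, which carries a known
positive digitisation bias on oblique runs; `length_estimator="calibrated"`
in the library API removes it (see `docs/methods.md`).  The `edges`
subcommand produces the per-particle table and histogram for whole images or
folders, and `detect` exports the binary mask as a PNG.

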