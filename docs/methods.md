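# Methods

`wellcyto` implements an automated whole-well fluorescence cytometer as a
library: from tiled multi-channel microscope rasters of a multiwell plate
to absolute per-population cell counts and per-cell features. This note
documents the models, parameters, and numerical choices.

## Measurement model

A well is imaged as a grid of abutting tiles (10×10 tiles of 1,600×1,600 px
for a 48-well plate, 19×19 for a 12-well plate; the well center is the
acquisition origin) that are stitched into one whole-well raster per
channel. Counting every cell in the whole well, rather than a handful of
representative fields, removes the sampling error caused by non-uniform
cell settling — the package quantifies this directly (see *Partial-well
sampling*).

Cells are counted through their nuclei: a DNA stain (DAPI-like) gives one
compact, well-separated blob per cell, which makes the nuclear channel the
counting anchor. Whole-cell extent is recovered separately, either from a
cytoplasmic stain (a filled cell body) or a surface/antibody stain (a ring
around the membrane).

## Preprocessing

**Rolling-ball background subtraction** (`preprocess.subtract_background`,
default radius 50 px). The background is the grayscale opening of the
raster by a non-flat ball element of height `sqrt(r² − d²)`; subtracting it
removes slowly varying background including the broad autofluorescence ring
at the well edge, while objects narrower than the ball survive. For radii
above 16 px the opening is computed on a block-minimum-shrunken copy of a
3×3-mean-smoothed raster (so the ball rides the local mean rather than the
noise minima), re-expanded by bilinear zoom, and capped at the input — the
same speed/accuracy compromise the classic implementation of this operator
makes. Small radii use the exact opening, which matches an exhaustive
ball-placement oracle to machine precision. Output is clipped at zero and
never exceeds the input.

**Contrast enhancement** (`preprocess.enhance_contrast`) is a linear
rescale clipping a chosen fraction of pixels at each end (default 0.0035,
the named tool's convention; the workflow only needs it for faint stains).
Pixel rank order is preserved outside the clipped tails.

**Illumination correction** (`preprocess.correct_illumination`) works per
tile, because vignetting is a per-exposure artifact: the tile is heavily
Gaussian-smoothed (default scale 64 px), a least-squares quadratic
illumination surface is fitted to the smoothed interior (the interior
margin avoids the boundary bias every local smoother has), and the tile is
divided by this surface after mean-normalizing and clamping it to
[0.25, 4]. The clamp keeps the division stable when the input is a
background-subtracted stain whose background is near zero. The tile's mean
intensity is preserved.

**Stitching / montage cropping** are exact mutual inverses on divisible
shapes; non-divisible rasters are zero-padded bottom/right (a documented
dialect).

## Nuclear segmentation

`segment.segment_nuclei`: Gaussian denoise (σ = 1 px) → threshold →
4-connected hole fill → debris removal → distance-watershed declumping →
per-object size filter → contiguous relabel. Conventions fixed for
reproducibility: 8-connectivity for objects, 4-connectivity for background;
objects touching the image or well edge are **counted** (the whole-well
design exists precisely to include the edge); equidistant watershed pixels
go to the lower seed label.

*Thresholding.* Otsu's method is the default and is reliable whenever a
genuinely brighter class exists. On blank or nearly blank wells its
histogram split collapses into background texture, so the split is accepted
only when the foreground class separates from the background class by at
least 4 background standard deviations; otherwise the threshold falls back
to a background ceiling extrapolated from upper quantiles
(`q99.9 + 3·(q99.9 − q84)`). A minimum-contrast floor at 20 % of the
dynamic range (top taken at the 99.99th percentile so isolated hot pixels
cannot inflate it) suppresses faint residue such as an incompletely
removed edge ring. These guards are what make counting exact down to a
single cell per well. A fixed-threshold override is available.

*Declumping.* Touching nuclei are split by watershed on the smoothed
(σ = 1 px) euclidean distance transform, seeded at local maxima separated
by at least `min_diameter_px`. The minimum-diameter cut (default 4 px
equivalent diameter) runs **before** declumping to drop debris; both the
minimum and maximum (default 60 px) cuts run per object **after**
declumping, so clumps of touching nuclei are split rather than discarded.
Size bounds describe the expected object scale and should be set to match
the pixel scale of the data, exactly as any segmentation tool requires.

## Secondary (whole-cell) identification

`segment.segment_secondary` grows each nuclear seed into one whole-cell
region inside a cell-stain channel. Growth is restricted to
supra-threshold stain pixels plus the seed pixels; contested pixels go to
the seed with the shorter regularized geodesic distance, where an
8-connected step of euclidean length `s` between intensities `I_u, I_v`
costs `s + λ·|I_u − I_v|` (λ = `regularization`, default 0). Ties go to the
lower seed label, making the result order-independent and deterministic.
Every seed yields exactly one connected region containing it, so secondary
counts always equal seed counts. The implementation is a multi-source
Dijkstra; the suite verifies it against an exhaustive relaxation oracle.

## Co-culture population assignment

Primary segmentation of cytoplasmic/surface stains degrades badly for
spindly or inhomogeneously stained cells, so populations are identified by
masking instead: each population's stain is thresholded into an
**inclusive mask** — interior holes up to `max_hole_px` (default 2000 px)
are filled, so a surface ring becomes a disk that retains the nuclei
contained within, and regions below `min_region_px` (default 32 px) are
dropped. Each nucleus is then tested against every mask independently
(pixel-overlap fraction ≥ `min_overlap_fraction`, default 0.5 —
majority overlap is stable for near-inclusive masks). The resulting
per-nucleus barcode (e.g. `A+B−`) classifies it as single-positive for one
population, multi-positive, or negative; ambiguous nuclei are reported as
their own classes rather than force-assigned, because silent reassignment
would bias absolute counts. Class totals always sum to the number of
nuclei.

Absolute counts are the primary output. Relative counts (percentages) are
provided but can invert the apparent direction of an effect between
conditions — a population's share can rise while its absolute count falls
whenever another population falls faster — which the suite demonstrates on
a constructed two-condition fixture.

## Per-cell features

`cytometry.measure_cells` reports, per secondary region: area (pixel
count), per-channel mean fluorescence intensity, eccentricity and
orientation from second central moments (degrees, (−90, 90]), neighbor
count, and first-closest-object distance. Neighborhood features use
**centroid** distances (a documented convention; a boundary-distance
variant would be a possible extension); the contact radius defaults to
twice the well's mean equivalent cell radius. A lone cell reports zero
neighbors and a missing closest distance; empty classes report missing
means, never zero, so condition normalization is not corrupted.

Dilution regressions (`cytometry.fit_dilution`) are ordinary least squares
of measured on plated counts, R² against the mean-only model (never
negative for OLS with intercept); replicates enter as individual
observations.

## Partial-well sampling

`cytometry.sample_partial_well` reproduces the three ways a well can be
assayed: five random fields, a central box crop, or the whole well. Counts
on the sub-rasters are scaled by the sampled fraction of the circular well
footprint. On wells with a center-weighted density gradient the estimate
variance across replicate wells drops strictly from random fields to box
crop to whole well — whole-well imaging is the only strategy whose
"sampling" error is zero by construction.

## Synthetic well renderer

The renderer (`synthetic`) produces the validation substrate: multi-channel
rasters with exact per-cell ground truth.

* **Nuclei** are Gaussian-profiled disks (peak at the centroid,
  σ = radius/1.5) whose footprint is the exact discretized disk, so truth
  areas are integers an enumeration oracle can verify.
* **Cell bodies** are area-preserving ellipses (`elongation` > 1 with
  random orientation for spindly cells) with a mild interior intensity
  taper; the cytoplasmic stain fills the body, the surface stain paints its
  2 px boundary band. Within-cell staining inhomogeneity is a smoothed
  multiplicative noise field of relative amplitude `stain_inhomogeneity/2`.
* **Placement** forbids nucleus–nucleus overlap (cell bodies may touch —
  the contact confound real plates show); `spacing="cell"` keeps whole
  bodies disjoint for controlled co-culture fixtures. An over-confluent
  well raises an explicit error naming the achieved count. `radial_bias`
  concentrates cells toward the well center to emulate non-uniform
  settling.
* **Confounds**, applied in order: per-tile radial vignetting (quadratic
  falloff, `vignette_strength` at the tile corner), an additive
  autofluorescence ring at the well boundary (Gaussian cross-section,
  width 0.12 × well diameter), then sensor noise (optional Poisson gain,
  additive Gaussian), clipped at zero. Intensities are floating point,
  quantized to 16 bits with saturation only on write.
* **Determinism**: one top-level seed; dilution plates derive per-well
  seeds as `seed + well_index`; identical specs render bit-identical
  rasters.

Ground-truth mean intensities are recorded from each cell's own clean
contribution before vignetting, the ring, and noise.

What the renderer does **not** emulate: optical point-spread functions,
focus errors, 3-D structure, stain bleed-through between channels,
debris/artifacts, and real staining-intensity distributions (intensity
scales are free parameters, not calibrated to any instrument). Passing
tests therefore demonstrate the correctness of the algorithmic chain under
controlled confounds, not instrument-level performance on real plates.

## Standard validation conditions

The validation experiments in `wellcyto.benchmarks` fix these conditions:
nucleus radius 5 ± 0.5 px, peak nuclear intensity 3000 (16-bit scale),
additive Gaussian noise sd 150 (5 % of peak signal), 10 % vignetting, edge
ring amplitude 400. Wells are rendered at reduced raster scale relative to
the 16,000 px instrument rasters — 600 px wells for the 1–100-cell
sensitivity series, 800 px for the 100–1,000 dilution series — preserving
the cell-size-to-well geometry. The dynamic-range series (1 to 10⁵ cells)
shrinks nuclei to 3 ± 0.3 px and sizes each well to keep nucleus packing
below 25 % of the well area (about 3,800 px for 10⁵ cells); the
rolling-ball radius scales with the raster (50 px at the 600 px reference
scale, clamped to [15, 50]) so the ball still rolls over the miniature
well's edge ring. The co-culture fixture uses one round cytoplasmic
population (120 cells) and one spindly surface-stained population
(80 cells, elongation 2) with disjoint cell bodies and the standard noise.

## Configuration reference

Run configuration is plain YAML mirroring `wellcyto.RunConfig`; every key
is validated before any computation and errors name the offending key.

```yaml
preprocess:
  rolling_ball_radius: 50        # px; background-subtraction ball radius
  enhance_contrast: null         # saturated fraction per tail; null = off
  illumination_smoothing_px: 64  # flat-field smoothing scale, px
nuclei:
  threshold_method: otsu         # otsu | fixed
  fixed_threshold: null          # intensity, with threshold_method: fixed
  min_diameter_px: 4             # equivalent-diameter bounds for objects
  max_diameter_px: 60
  declump: distance_watershed    # distance_watershed | none
  smoothing_sigma_px: 1.0        # Gaussian denoise before thresholding
  fill_holes: true
populations:                     # co-culture only; order = barcode order
  - name: tumor
    stain_channel: cytoplasmic   # channel holding this population's stain
    threshold_method: otsu
    fill_holes: true
    max_hole_px: 2000            # interior holes up to this size filled
    min_region_px: 32            # smaller mask regions dropped
min_overlap_fraction: 0.5        # nucleus-in-mask membership threshold
contact_radius_px: null          # null = 2 x mean equivalent cell radius
secondary_regularization: 0.0    # intensity weight in geodesic growth
output_dir: out
seed: 0
log_level: INFO
```

Outputs per well: a per-cell event CSV, a barcode CSV (co-culture), a
class-count summary CSV, label maps as TIFF, and a PNG QC overlay of
object outlines.

## Known limitations

* Thresholding assumes foreground is a minority of the raster; wells
  beyond ~50 % confluency would need a fixed threshold.
* The geodesic secondary propagation is a Python priority-queue search;
  it is exact and deterministic but not suited to rasters much beyond a
  few thousand pixels square with dense stains.
* Tile stitching assumes zero-overlap abutting tiles; there is no
  registration or blending.
* The "granularity" texture feature and hypothesis testing between
  conditions are out of scope.
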