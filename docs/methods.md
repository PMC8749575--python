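# Methods

## Image preparation

Scanner frames arrive as single-frame DICOM or common raster containers.
DICOM `MONOCHROME1` frames are inverted so larger always means brighter;
multi-frame files are rejected with instructions to export a single frame.
RGB frames are collapsed with ITU-R BT.601 luma weights (0.299, 0.587,
0.114) and rounded half-up; these weights are the de-facto default of
mainstream imaging libraries, chosen because the conversion step in the
workflow this package implements is otherwise unspecified.  16-bit grey
samples are min–max rescaled to 8 bits with the same linear stretch used
for normalization.

Byte-scale normalization maps each image onto the full display range:

    G_i = 255 · (f_i − f_min) / (f_max − f_min)

with `f_min`/`f_max` the **whole-image** extrema (not the ROI), computed
before any region statistic; the result is rounded half-up so outputs are
bit-exact across platforms.  The transform is idempotent, and invariant to
affine pre-scaling of the input up to ±1 grey level of rounding.  A
constant frame has no defined stretch; it becomes all zeros with a warning
rather than an error so batch runs survive degenerate frames.  Coordinates
are 0-based `(row, col)`, row-major, everywhere.

## Spot meters and MPI/MPH

Echotexture is measured through four identical circular spot meters
(default diameter 33 px, user-overridable).  A pixel belongs to a spot when
its center lies **strictly** within `diameter/2` of the spot center
(Euclidean); strict inequality makes membership deterministic and
grid-independent.  Note a consequence at small diameters: a diameter-3 spot
at an integer center contains the full 3×3 block, because the diagonal
neighbours sit at √2 ≈ 1.414 < 1.5.  Spot sets must be pairwise
non-overlapping (center distance strictly greater than the diameter, so
tangent circles are rejected) and fully inside the image.

Per spot the mean and the *sample* (n−1) standard deviation of the grey
levels are computed — the (n−1) convention matches the statistical packages
used in this field and is documented so tests can be bit-exact.  Image
level:

* **MPI** = arithmetic mean of the four spot means;
* **MPH** = arithmetic mean of the four per-spot SDs (default), or the SD
  *across* the four spot means under `mph_mode="across-spots"`.

The phrase "standard deviation of the mean pixel values" is ambiguous in
the literature; the per-spot convention matches first-order texture
methodology and is the default, with the alternative behind the mode
switch.  Spot means/SDs are accumulated in sorted order so permuting the
spots changes nothing, exactly.  Spot placement is primarily manual via a
CSV (`bird_id, plane, spot_index, center_row, center_col, diameter`); a
centered 2×2 grid layout is provided as a convenience.

## Synthetic speckle

Fully developed speckle is simulated as the envelope `√(g₁² + g₂²)` of two
independent zero-mean Gaussian fields of scale σ, i.e. Rayleigh(σ) per
pixel, chosen over log-compressed or Rician variants because its closed-form
moments (mean σ√(π/2), SD σ√(2 − π/2)) give analytic oracles for tests;
display-style log compression is available as an option.
`calibrate_sigma(target)` inverts the mean formula so frames hit a wanted
MPI.  Optional anisotropic Gaussian smoothing (aspect ratio ≥ 1) emulates
the streaky, "linear" texture of muscle scanned along its fibers; the
shipped per-plane ratios (L 3.0, T 1.0, O1 1.5, O2 2.5) are stylized flavor
only.  Smoothing preserves the envelope mean and reduces its SD.

Because byte-scale normalization rescales by the frame extrema, a bare
speckle field would lose its calibrated mean under normalization (its
maximum is a random Gumbel-ish value well below 255).  Real scanner exports
contain near-black masked regions and a saturated transducer-interface
echo, which pin the extrema; the generator's `scene` flag paints a black
border and a 255-level interface band for the same reason, making
normalization neutral over the parenchyma so calibrated MPI survives the
analysis round trip.

## Synthetic trait tables

The shipped scenario is a three-diet study (groups C, Exp1, Exp2; n = 15
birds/group) with 8 echotexture variables (4 planes × MPI/MPH) and 29
physicochemical/sensory traits whose group means and SEMs are fixed data in
`echotex.defaults`.  Only mean ± SEM are available, so marginals are
Gaussian with SD = SEM·√15; heavier tails are out of scope.  Per bird a
latent multivariate-normal vector is drawn with unit variances and the
requested echotexture–trait correlations planted in the correlation matrix
(validated positive semi-definite; a non-PSD request is rejected naming the
likely offending triple).  Traits are otherwise mutually independent —
within-group covariance among traits is not modeled because no such
information is available to calibrate it.

Sensory traits are snapped to the panel grid (1 to 5 in 0.5 steps) *after*
correlation planting; the attenuation and occasional within-group constancy
this causes (scores cluster tightly around 4.4–4.65, so a group's column
can collapse to a single grid value and be skipped by the screen) is a
measured property of the generator, not corrected.  A planted correlation
holds within each group; pooling across groups attenuates it through
between-group mean differences, so recovery is always evaluated
within-group.

Randomness: one master seed; the pipeline spawns stream 0 for the trait
table and stream 1 for images (bird-major, plane-minor).  Fixed seed gives
bit-identical images and tables across runs and platforms.

## Statistics

* **Pearson screen.**  r, the least-squares line `y = a + bx` (which passes
  through the sample means by construction), and a two-tailed p from
  `t = r√((n−2)/(1−r²))` with n−2 df — the standard product-moment test.
  No multiple-testing correction is applied, matching the raw-α screening
  convention of the workflow; an optional Benjamini–Hochberg column can be
  annotated and is marked as an extension.  Constant vectors within a group
  are skipped with a logged notice, not a run abort.  Candidate bookkeeping
  uses the study design (planes × variables × traits × groups); the trait
  count in the denominator is a config value (default 26 even though 29
  trait columns are generated, mirroring the reference scenario's own
  enumeration — the discrepancy is inherited from that scenario and
  documented rather than resolved).  Percentages are rounded to one
  decimal.  Equation strings use ASCII signs and two decimals, extended
  below 0.01 until the first significant digit shows (a slope of 0.007
  prints as 0.007).
* **Strength labels.**  |r| bands slight < 0.2 ≤ low < 0.4 ≤ moderate
  < 0.7 ≤ high < 0.9 ≤ very high, with configurable edges — published use
  of such labels is not always consistent with any single banding, so the
  bands are data, not doctrine.
* **One-way ANOVA + Tukey.**  Textbook sums of squares (so degenerate
  inputs are controlled: all-identical data gives F = 0, p = 1); Tukey HSD
  p-values from the studentized-range implementation in scipy,
  cross-checked against statsmodels in tests.  Compact letters come from
  the insert-and-absorb algorithm, ordered so the highest mean carries "a";
  levels share a letter iff their pairwise comparison is non-significant.
* **Two-way ANOVA + LSD.**  Additive model (main effects only — interaction
  is deliberately not fitted), fitted via statsmodels OLS/anova_lm (type II);
  LSD is the textbook unadjusted pairwise t using the residual mean square
  and df.  A single-level factor reduces the model to the one-way case.
  Empty cells are an error naming the cell.

## Problem sizes in tests

The test suite exercises the image chain on 96×96 frames with 3 birds per
group (36 images per study) and the Monte-Carlo calibrations at 1000
replicates of n = 15 studies (screen type-I), 300–400 Tukey replicates, and
n = 2000 birds for planted-correlation recovery — sizes at which the
binomial/Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

* Rayleigh speckle with an optional smoothing kernel is a statistical
  stand-in, not a physical scanner model: no beamforming, time-gain
  compensation, attenuation or tissue layering.  Passing tests demonstrate
  the *analysis chain* is correct and calibrated, not that real muscle
  images satisfy the generator's assumptions.
* Image-level MPH in simulated studies reflects speckle physics (roughly
  0.52·MPI before smoothing) rather than the latent MPH values of the trait
  model; planted correlations involving MPH are therefore verified on the
  trait-table route, while the image round trip is verified for MPI.
* Second-order texture (GLCM, run length), segmentation, despeckling and
  cine loops are out of scope.
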