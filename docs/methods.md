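# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `focidose`.

## Data model

A `ChannelStack` holds named 3D integer intensity volumes in `(z, y, x)`
axis order with a shared `VoxelGeometry`.  The default geometry is a
typical high-NA confocal acquisition: 1024 × 1024 pixels at 140 nm
laterally, 10 optical sections at 581 nm spacing.  Note the anisotropy:
one z-step spans ≈ 4.15 lateral pixels.  All radii and sizes in the
detection code are expressed in voxel-index units, not physical units,
because the protocol's thresholds (8/20-voxel size filters, 6-voxel
background shell) are voxel counts; a physical-distance interpretation
would change their meaning.  Stacks are stored as plain multi-page TIFF
(channel-interleaved or channel-blocked), with z-spacing and free-form
metadata in a JSON `ImageDescription` and lateral pixel size in the
resolution tags.

## Nucleus segmentation

The liver-protocol mask pipeline runs, in order:

1. **Threshold.** Otsu's between-class-variance criterion on the DAPI
   MIP.  The returned level is placed midway between the top of the
   background class and the smallest foreground value, so binarisation
   (`pixels > level`) is unambiguous; a multiplicative `threshold_adjust`
   (default 1.0) reproduces the "user adjustable" knob of interactive
   analysis.
2. **Binary median filter**, radius-2 Euclidean disk (13 pixels, centre
   included).  Edge pixels use the in-bounds neighbourhood; with an even
   neighbourhood the tie (median 0.5) rounds to foreground.  The filter
   is applied to the mask, not the grayscale image.
3. **Watershed** on the Euclidean distance transform.  Seeds are the
   regional maxima of the h-reconstruction of the distance map
   (`watershed_h_px`, default 1.5 px): maxima shallower than h merge
   into their neighbour's plateau.  This keeps a flat ridge — an
   elongated nucleus, an annulus — as one seed while genuinely touching
   round nuclei (saddle depth of several pixels) still split.  Plain
   per-pixel distance maxima over-segment flat ridges, which is why the
   h-criterion replaces a bare minimum-distance rule; seed components
   closer than `seed_min_distance_px` (default 5 px) are merged as a
   second guard.
4. **Fill holes** per label (background components not connected to the
   image border become foreground).
5. **Area filter** (`min_area_px`, default 50 px — removes debris; the
   smallest real nucleus footprint at this resolution is several hundred
   pixels).
6. **Border policy**: nuclei touching the image border are excluded by
   default, because partially imaged nuclei bias per-nucleus counts.
7. Consecutive relabelling and feature measurement (area, centroid,
   perimeter, circularity 4πA/P², elongation = major/minor axis,
   mean intensity, heterochromatin contrast = 0.95-quantile/median
   intensity inside the footprint).

The 2D outlines are extruded unchanged across all z-sections; no
per-slice re-segmentation is attempted.

**Cell classes.** Manual assignment (a verbatim label → class mapping)
is the default and mirrors expert practice.  The automatic rule is a
convenience: elongation ≥ 1.6 → non-hepatocyte; else circularity ≥ 0.8
and area ≥ 1200 px and heterochromatin contrast ≥ 1.18 → hepatocyte;
else unassigned.  The contrast cut-off sits midway between the
populations the default generator produces (speckled hepatocytes ≈ 1.25+,
homogeneous non-hepatocytes ≈ 1.10); on real data it should be
re-estimated from a few labelled nuclei.

Testis mode skips segmentation: the user supplies polygonal ROIs and the
nucleus count per ROI, and the summary statistic is total foci in the
analysed volume divided by the nucleus count.

## 3D focus detection

**Local maxima.** A maximum is a maximal connected set of equal-intensity
voxels (a plateau, possibly of size 1) all of whose outside neighbours
are strictly dimmer; border voxels compare only in-bounds neighbours.
Connectivity is configurable (6/18/26; default 26).  The implementation
is exact — verified against exhaustive enumeration — with a vectorised
fast path for strict (non-plateau) maxima and for plateau screening, so
constant backgrounds (one giant plateau) cost no Python-level loops.

**Background.** For each maximum, the mean (or median) intensity of the
voxels whose index-space Euclidean distance from the plateau centroid is
within ±0.5 voxel of `background_radius_vox` (default 6).  A filled-ball
mode exists as an alternative reading of "at a radius of six voxels".
Near borders the in-bounds shell subset is used; a volume smaller than
the shell is an error.  The per-focus background is used as-is, with no
iterative re-estimation, even when the shell grazes a neighbouring
focus.

**Region growth.** The focus region is the connected component,
containing the maximum, of voxels with intensity ≥
`background + α·(peak − background)`; α (`growth_fraction`) defaults to
0.5 (half-prominence).  Growth can be clipped to a label mask so a focus
never leaks across a nucleus outline.

**Single-maximum rule.** Overlapping regions are grouped; a group whose
region holds several maxima is split along intensity watershed lines
seeded at the maxima (`multi_max_policy="split"`, default) or discarded
(`"reject"`, the stricter reading of "only one local maxima centre").
Each split part keeps only the connectivity component containing its
maximum.

**Size filter.** A region is reported iff it is *strictly larger* than
`min_voxels` — 8 for the liver protocol, 20 for testis ("larger than" is
a strict inequality and is tested as such).

**Noise controls.** Two optional parameters, both 0 (off) by default so
the bare rule above is what you get:

* `min_prominence` — maxima rising less than this above their shell
  background do not seed foci.  On noisy data this is essential, not
  cosmetic: a shot-noise maximum 2–3 noise SDs above background grows a
  half-prominence region whose threshold sits ~1 SD above background,
  and at 26-connectivity voxels above that level percolate into
  volume-spanning clusters.  A cut of 4–5 noise SDs removes these seeds
  while leaving real foci (by construction brighter) untouched.
* `merge_tolerance` — within one coherent region, a maximum whose peak
  rises less than this above the saddle towards a brighter maximum is
  absorbed into it (persistence-based consolidation, processed in
  descending intensity order).  This is the same idea as the noise
  tolerance of interactive maxima finders: noise wiggles on a focus top
  have saddle prominence of ~1–2 noise SDs and would otherwise be split
  into duplicate detections.  Genuinely separate foci keep deep saddles
  and survive.  Physically, two foci whose saddle vanishes are below the
  optical resolution limit and are counted once.

The validation drivers set `min_prominence = 4.5σ` and
`merge_tolerance = 3σ`, with σ the known noise SD of the generator
(shot variance `background·gain` plus read-noise variance).  On real
data σ should be estimated from a signal-free region.

**Assignment.** A focus belongs to the nucleus whose (extruded) label
covers its maximum voxel; every label gets a row in the count table,
zero-count nuclei included — required for zero-fraction statistics.

## Synthetic scenes

The generator emulates the two tissue morphologies end-to-end:

* **Nuclei** are ellipsoids with class-specific parameter ranges
  (voxel units, z semi-axes already anisotropy-adjusted): hepatocytes
  24–30 px minor semi-axis, elongation ≤ 1.15, with 8–14 bright
  heterochromatin speckles; non-hepatocytes 8–12 px, elongation 2–3,
  homogeneous; germ-cell classes in between.  Placement is rejection
  sampling on bounding circles with a 4-px margin; failure after bounded
  retries raises a packing error.
* **Foci** are isotropic Gaussians in index space (σ 1.3–1.8 voxels,
  amplitude 300–520), so voxel-count thresholds are exercised directly;
  centres are drawn uniformly inside the nucleus ellipsoid shrunk by
  `focus_margin` (default 0.15), keeping chromatin-embedded foci clear
  of the nuclear envelope and of the segmented outline.
* **Counts** per nucleus follow a zero-inflated Poisson:
  P(0) = π₀ + (1−π₀)e^{−μ}, otherwise Poisson(μ).  π₀ = 0 recovers a
  plain Poisson; `ZIPCounts.from_zero_fraction` solves π₀ for a target
  zero fraction.  The excess-zero component reflects irradiated-liver
  count histograms, where many nuclei remain focus-free.
* **Noise**: expected intensity / `gain` → Poisson draw → × gain →
  additive Gaussian read noise → rounded to uint16.  Defaults
  (background 80, gain 4, read SD 8; noise SD ≈ 19.6) mimic a
  PMT-detector acquisition with a few tens of photons per background
  pixel.  Both noise sources switch off for exact-oracle tests.

Everything is a deterministic function of one integer seed.

What the generator does **not** model: the optical PSF (foci are
rendered Gaussians, not diffraction images), spectral bleed-through,
autofluorescence, intensity gradients with depth, chromatin texture
beyond discrete speckles, and section-boundary truncation of nuclei.
Passing synthetic tests therefore demonstrates the correctness of the
computational chain, not the biological fidelity of any particular
parameter value on real tissue.

## Statistics

The experimental unit is the animal: per-animal means are computed
first, and group mean ± SD are taken over animal means (the design has
4 animals per group, hence ANOVA df = (2, 9) for three groups).  Pooled
per-nucleus summaries are available (`unit="nucleus"`) but are not the
default, since nuclei within an animal are not independent.  One-way
ANOVA uses the standard F = MS_between/MS_within decomposition; zero
within-group variance with non-zero between-group variance is reported
as F = ∞, p = 0, flagged.  Tukey HSD uses the Tukey–Kramer statistic
q = |x̄ᵢ − x̄ⱼ| / √(MS_w (1/nᵢ + 1/nⱼ)/2) with adjusted p from the
studentized-range distribution (k, df_within).  No further
multiple-testing correction is applied.

## Dosimetry

The chain assumes instantaneous uptake (A(0) = A₀) and a single
mono-exponential elimination per organ: two samples give the closed form
λ_eff = ln(v₁/v₂)/(t₂−t₁); more samples give least squares on
log-values.  Equal values at two times are flagged (λ = 0, infinite
half-life; residence time then exists only for finite horizons).
Residence time per unit A₀ is τ_h = (1 − e^{−λh})/λ (1/λ at infinity),
and the mean absorbed self-dose is D̄ = A₀ · τ · S.  Cross-organ dose is
deliberately out of scope; S factors and organ masses are user-supplied
configuration.  The ¹¹¹In physical half-life used for decay correction
is 67.32 h (library constant).  Gamma-counter volume correction is a
user-supplied (volume → factor) table with linear interpolation.

`dose_per_injected_activity` integrates the dose-rate curve anchored at
a known rate and effective half-life, which reproduces published
dose-coefficient tables without access to S factors or organ masses.

A bundled biokinetic anchor table (`STUDY_TABLE`) carries the published
testis and liver values of a ¹¹¹InCl₃ mouse study (%IA/g at 4/25 h,
effective half-life, dose rates, dose coefficients; 63 MBq injected) as
user-replaceable inputs.  Internal consistency holds well for the testis
row (the two-point fit reproduces the printed 58.7 h within 1.4%; the
anchored integration reproduces 1.65 and 6.5 mGy/MBq within 1%).  The
liver row is *not* self-consistent under this model: its effective
half-life (167.9 h) exceeds the physical half-life — implying the
printed %IA/g values are decay-corrected (biological) rather than
effective — and the infinity coefficient is about half the
mono-exponential extrapolation of the finite-horizon values.  The
package exposes both conventions and documents the discrepancy rather
than silently reproducing one reading; validation anchors on the testis
row.

## Problem sizes of the validation drivers

* Detection benchmark: 200 foci across eight 128 × 128 × 10 fields,
  noise on, peak ≥ 5 noise SDs, pairwise separation ≥ 8 voxels;
  detections match truth greedily within 3 voxels.
* End-to-end recovery: 500 hepatocyte nuclei across 25 stacks of
  512 × 512 × 10 (20 nuclei per stack ≈ 30% areal packing), ZIP counts
  with zero fraction 0.26 at μ = 3.  The recovered mean and zero
  fraction are compared with the configured truth at 99% sampling
  intervals (z = 2.576; normal approximation for the binomial).  μ = 3
  keeps the rate of physically blended focus pairs (closer than the
  ~0.5 µm merge scale) small relative to the interval width; at much
  higher densities per-nucleus counts are limited by optical
  resolvability, exactly as on real tissue.
* Desk-scale tests use 128–384 px stacks; the full 1024 × 1024 geometry
  is supported but not exercised in routine runs.

## Known limitations

* 2D segmentation extruded to 3D: nuclei stacked in z are not separated.
* No sub-voxel focus localisation and no calibration of focus intensity
  to break number.
* The region-growth fraction α is a modelling choice (the size filter,
  background shell and single-maximum rule are specified; the growth
  criterion itself is not), so absolute focus sizes depend on it; it is
  recorded in the provenance sidecar of every run.
* The automatic cell classifier is tuned to the generator's morphology
  ranges and is a convenience, not a validated classifier for real
  tissue.
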