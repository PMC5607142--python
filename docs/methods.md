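# Methods

This note documents the models, numerical choices and limitations behind
`memgp`, in the order the pipeline uses them.

## The phantom generator

The generator produces images with the statistical structure the
analysis modules assume, together with the exact generative truth, so
every estimator can be tested as a recovery problem.

**Geometry.** A specimen is a vesicle membrane — a ring of radius `R`
(nm) with a rectangular (top-hat) radial cross-section of width
`membrane_width_nm` — plus optional sub-resolution discs (endocytic
vesicles, virions, or a filled lumen).  The default membrane width is
8 nm, a lipid bilayer's thickness.  Because 8 nm is one to two orders of
magnitude below optical resolution, the cross-section's shape is
immaterial to every downstream result (a top-hat of width w adds only
w²/12 ≈ 5 nm² to the profile variance against ≥1100 nm² from the PSF);
it is fixed here so the rendering is fully specified.

**Emission.** Each angular arc of the ring (and each disc) is bound to a
"paint": either a fixed fraction `f` of photons landing in the first of
two detection bands (so the true GP of that phase is exactly `2f − 1`),
or a Gaussian emission spectrum (peak, SD) integrated analytically (erf)
over the detection bands or over 9-nm λ windows.  Arc brightness is
expected photons per nm of contour per frame (default 50, giving
membrane peak counts of a few hundred under the STED preset — typical
for a bright membrane dye); disc brightness is a total photon budget.

**Optics and sampling.** The PSF is an isotropic 2-D Gaussian
parameterised by FWHM; presets are 240 nm (confocal) and 80 nm (STED,
inside the 70–90 nm range such systems reach when imaging several µm
deep).  No depletion-physics is simulated.  Rendering happens on a 4×
supersampled grid (5-nm subpixels at the default 20 nm/px) and is
box-binned by summation to the target grid, so pixel values are true
line integrals including the real pixel-integration blur of a detector.
Poisson noise is drawn independently per pixel and page from
`numpy.random.default_rng(seed)`; identical spec + seed reproduces
bit-identical images.

**Presets.** Named presets pin the generative conditions used throughout
the tests and drivers: `fig3-gpmv` (uniform 5-µm vesicle for resolution
profiling), `fig5-nanodomain` (500-nm disordered arc, channel-1
fractions 0.405 domain / 0.540 surround, i.e. GP −0.19 / +0.08),
`fig5-endosome` (150-nm disc at fraction 0.555 → GP 0.11, 500 nm inside
a membrane at 0.660 → GP 0.32), `bleach-20` (20 frames at survival
0.9875), `spectra-shift` (ordered/disordered peaks 570/610 nm, SD
25 nm, twenty 9-nm windows from 513 nm), and `gfp-gpmv` (a 510-nm lumen
emitter inside a 600-nm membrane probe).  ROI circles accompanying arcs
and discs default to 150-nm radius (300 nm for the spectral presets,
where more pixels stabilise window means).

**What the phantoms do not emulate.** Real GPMV/cell images have
structured background, detector offset and read noise, refractive-index
aberrations that make the PSF depth-dependent and anisotropic,
wavelength-dependent depletion (STED resolution differing between
channels), probe partitioning differences between phases, and membrane
undulations.  A per-band transmission factor and a constant background
offset are available as knobs, but passing recovery tests here
demonstrates correctness of the estimators under the stated model, not
robustness to every real-world artefact.

## FWHM profiling

The contour is resampled at arc-length multiples of `spacing_px`
(default 3) from its first vertex, dropping the final partial interval.
Tangents are central differences across neighbouring anchors (wrapping
on closed contours, one-sided at open ends); the profile direction is
the tangent rotated 90°.  Intensities are sampled at 1-px steps over a
40-px window centred on the anchor.

**Interpolation.** Sub-pixel sampling uses cubic B-spline interpolation
(`scipy.ndimage.map_coordinates`, order 3, with a single prefilter per
image).  Bilinear sampling is available (`interp_order=1`) but is not
the default: bilinear interpolation convolves the image with a triangle
kernel whose variance (up to p²/6 per axis) measurably widens profiles
once the PSF SD approaches 2 px — on the noise-free STED-preset phantom
it inflates the recovered FWHM by ≈4.5%, whereas cubic sampling recovers
the 80-nm truth within ≈1.6%, essentially all of which is genuine pixel
integration (p²/12 ≈ 33 nm² of variance at 20-nm pixels).

**Fitting.** Each profile is fit with `offset + A·exp(−(x−c)²/2σ²)` by
Levenberg–Marquardt, initialised at offset = min, A = max − min, c =
argmax, σ = second moment about the argmax.  A fit is rejected (not
averaged) when the optimiser fails, σ ∉ (0.5 px, L/4), |c| > L/4 (a
neighbouring membrane dominating the window), or A < 2× the residual
SD (no contrast).  These rules are this package's own; they are
configurable and deliberately conservative — on clean ridges the fitted
FWHM matches 2√(2 ln 2)σ to <0.1%.

**Aggregation.** Profiles are pooled over images for the headline
mean ± SD; per-image means are also reported since mean-of-image-means
is the other defensible order of averaging (for balanced designs the two
agree to well under a percent).  The resolution ratio divides confocal
by STED mean FWHM with first-order SD propagation.

## GP mapping

`GP = (I₁ − I₂)/(I₁ + I₂)` per pixel, never rescaled.  **Masking:** a
pixel is valid when `I₁ + I₂` reaches `mask_fraction` (default 10%) of
the image's maximum summed intensity; this keeps the membrane, drops
lumen and background where the ratio is noise-dominated, and conditions
the denominator.  Masked pixels are NaN and render black; valid GP is
mapped linearly onto blue (−1) → red (+1).  ROI statistics use the
arithmetic mean of pixel GP (matching "average ± SD" reporting); the
GP-of-summed-intensities variant is provided for comparison.  No
G-factor or spectral-bleed correction is applied by default (an optional
per-channel gain pair exists): the two-band GP is reported as acquired,
and since for independent Poisson channels the pixel GP is conditionally
unbiased given the pixel's total counts, ROI means need no bias
correction at the count levels simulated.  The phantom's optional
per-band transmission factor can emulate the slightly higher absolute GP
values STED mode produces (depletion is more efficient in the red
channel); the analysis never corrects for it, since GP is a relative
index and interdomain differences are the robust readout.

## Spectral analysis

Spectra are per-window ROI means, with window centres at band midpoints;
normalisation divides by the maximum and is idempotent.  Peak positions
default to parabolic refinement — the vertex of a quadratic through the
brightest window and its neighbours — which recovers band-integrated
Gaussian peaks to well under 1 nm on 9-nm windows; `argmax_bin` is kept
for strict window-resolution readouts, and the parabola falls back to it
at the axis edge.  An optional constant background subtraction (default
off) precedes normalisation.  Two-band recombination assigns windows to
bands by centre position; disjoint bands covering the axis partition the
total intensity exactly.  No multi-component unmixing or solvatochromic
lineshape fitting is attempted: phase/probe separation is by band choice
only.

## Photostability

A fixed ROI is applied to every frame (no re-segmentation or drift
correction — the series monitors a static selection), the per-frame mean
is normalised to frame 0, and the loss after N frames is
`1 − I[N−1]`.  The decay fit is a single-parameter least-squares of
`s^k` with `s ∈ (0, 1.1]`, the upper bound tolerating noisy
non-bleaching series; no triplet/dark-state kinetics are modelled.  For
the default series (survival 0.9875, 20 frames) the closed-form loss is
`1 − 0.9875¹⁹ ≈ 21.3%`.

## I/O and conventions

Pixel coordinates are 0-based `(x, y) = (column, row)` at pixel centres.
Images travel as multi-page float32 grayscale TIFF with a JSON metadata
sidecar (axis semantics, pixel size, band edges); round trips are
bit-exact including NaN.  ROIs use a documented JSON schema (polylines
and circles with purpose tags) rather than a binary ROI format, for
testability and diff-ability; proprietary microscope formats are out of
scope.  Circle ROIs select pixels whose centres fall inside the radius;
closed polylines select their polygon interior.  All tabular outputs are
CSV with one header row and `.` decimals, accompanied by a
run-parameters JSON with a parameter hash.

## Problem sizes

The bundled drivers and tests use vesicles of 1–5 µm radius on images of
128–600 px at 20 nm/px, 10 images per modality for resolution studies,
and 20-frame bleaching series — sizes chosen so each study matches the
scale of a typical imaging session while every script completes in
seconds to about a minute on a single core.
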