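# Methods

This note documents the model choices, parameters, numerical conventions
and known limitations of the vesselx pipeline, in the order the stages
run.

## Preprocessing

All processing happens in floating point on the [0, 1] intensity scale;
integer rasters are divided by their dtype maximum on load. A fixed scale
matters because the threshold constant C = 0.039 downstream is only
meaningful on a normalized range.

The green channel is used as the working image: in color fundus
photography it carries the strongest vessel/background contrast and the
least sensor noise of the three channels.

When no dataset FOV mask is supplied, the aperture is estimated by
thresholding at 0.1 of full scale (fundus apertures are near-black
outside the field), keeping the largest connected component and filling
holes. Before any Hessian filtering the FOV is eroded by 5 px and the
image is continued outward with the value of the nearest inside pixel
(`fill="nearest"`). A flat fill with the FOV mean is also available, but
it leaves a residual step wherever the local rim intensity differs from
the global mean, and that step re-creates exactly the rim response the
suppression is meant to remove; the nearest-neighbor continuation is
C⁰-continuous across the rim and eliminates it. Pixels strictly inside
the eroded FOV are never modified.

## Vesselness filter

The filter responds to the eigenvalues λ₁, λ₂ (|λ₁| ≤ |λ₂|) of the
σ²-normalized Hessian. Eigenvalues are computed in closed form
(trace/discriminant); equal-magnitude ties are ordered ascending by
signed value. The Hessian itself is Gaussian smoothing followed by exact
central-difference stencils, all separable convolutions with reflect
padding. This composition reproduces the continuum Hessian exactly on
quadratic images (smoothing maps a quadratic to a quadratic plus a
constant, and second differences of quadratics are exact), which makes
the σ² normalization and the test oracles exact rather than approximate;
an analytic derivative-of-Gaussian kernel differs from it only at
O(discretization).

Polarity: vessels are dark on a bright background in the green channel,
and a dark tube yields positive cross-sectional curvature, i.e. λ₂ > 0,
which is what the response function expects. A `bright-on-dark` option
negates both eigenvalues first.

Scale semantics. The scale grid is expressed as the probed vessel width
s in pixels (default 3 to 16, step 0.5) and each s maps to a derivative
kernel of σ = s/4, so the response of a vessel of width s peaks near
scale s. The alternative reading σ = s is not usable here: with σ up to
16 px every scale far above the widest structure in the image has a
collapsed per-scale maximum, and the cut-off regularization then
amplifies residual curvature (illumination gradients, noise, the smooth
field between neighboring vessels) toward the plateau, flooding the
background of the response map ~30 px around every vessel. With σ = s/4
the grid spans σ 0.75–4 px, which brackets the calibers seen in the
standard public datasets and in the phantoms.

The cut-off τ (default 0.5) controls the regularization of λ₂ against
its per-scale image maximum. Low τ lifts faint, thin vessels toward the
plateau and preserves connectivity; high τ keeps only the strongest
ridges. The per-scale (not global) maximum is used, as the
regularization is defined scale by scale.

The final map is the pointwise supremum over the scale grid, so
enlarging the scale set can never decrease the response anywhere.

## Curvelet enhancement

The wrapping fast discrete curvelet transform is implemented directly:

- **Radial windows.** Meyer-type lowpass ramps Φ_a(r) (1 up to radius a,
  cos(π/2·ν(r/a − 1)) decay to zero at 2a, with ν(t) = t⁴(35 − 84t +
  70t² − 20t³), which satisfies ν(t) + ν(1 − t) = 1). Band j is
  √(Φ_{a_{j+1}}² − Φ_{a_j}²) with dyadic radii a_j = 0.25·2^{j−J}; the
  coarsest band is Φ_{a₂} and the finest √(1 − Φ_{a_J}²), so the squares
  of the J radial bands sum to exactly 1 at every frequency.
- **Angular windows.** Each annulus is split into n_j wedges (16 at the
  second-coarsest level, doubling every second level: 16, 16, 32 for
  J = 5) using cos(π/2·ν(|u|)) of the normalized angular distance u;
  adjacent wedges overlap one spacing and their squares sum to 1 by the
  same ν identity. The finest level is a single isotropic ring by
  default (`finest_mode="wavelets"`, the economical standard choice of
  the wrapping algorithm); full wedges at the finest level are available.
- **Wrapping.** Every wedge's support is a contiguous sector in the
  centered Fourier grid; it is wrapped onto its rectangular bounding
  box and inverse-FFT'd with normalization √(mn/HW). Because no two
  support points coincide modulo the box, wrapping is alias-free, and
  the exact partition of unity makes the frame tight: coefficient energy
  equals image energy and the adjoint is the inverse, both to machine
  precision (measured ~1e-15, asserted < 1e-6). Reconstruction of a real
  image is real by exactness; the vanishing imaginary part is discarded.

Enhancement zeroes the core (coarsest) level and multiplies all finer
coefficients by α = 1.2: the smooth background reconstructs near zero
while curvilinear detail is amplified. The result is min-max rescaled to
[0, 1] over the FOV, because the fixed threshold constant downstream
requires a normalized scale.

The input to this stage is `F·(1 − I)` — the vesselness map gating the
inverted working channel — rather than `F` alone (both wirings are
selectable). The rationale: wherever the filter saturates, `F` is a wide
plateau with no intra-vessel detail, and zeroing the curvelet core
hollows such plateaus out; the product keeps the thin intensity profile
of the vessel inside the vesselness support, which survives core removal
and strictly improves phantom recovery over both the raw channel and the
vesselness-only wiring.

## Mean-C thresholding and cleanup

The local mean is a W×W box filter (reflect padding); a pixel is vessel
iff `img − mean > C` strictly (ties are background), restricted to the
FOV. The decision is invariant to adding a constant to the image and
monotone in C. Defaults W = 13 px and C = 0.039. W must exceed the
widest vessel to be recovered (a structure filling its own window has
zero local contrast); 13 px works both for ~565-px-wide fundus images
and for the 256-px phantoms, so it is kept fixed rather than scaled with
image width — it remains an explicit config value.

Cleanup is a morphological opening with a disk of radius 1 followed by
removal of 8-connected components below 30 px — the smallest settings
that remove 1–2-px speckle. It is anti-extensive and idempotent, and can
be disabled entirely (`cleanup_enabled: false`).

## Evaluation

Confusion counts are taken inside the FOV by default (the convention of
the public benchmarks); whole-frame counting is available. A metric with
a zero denominator is reported as NaN — an explicit undefined marker,
never silently 0 or 1 — and aggregation skips NaNs while recording how
many were skipped per column. Means are unweighted across images.

The package bundles two reference per-image metric tables (DRIVE test
set, 20 images; CHASE_DB1, 14 images) for the baseline curvelet + mean-C
method; aggregating them reproduces their published column averages.
Those published averages are floor-truncated rather than rounded (e.g. a
recomputed mean of 0.66878 printed as 0.6687), so the tests compare
truncated values and additionally require agreement within one unit in
the last printed digit.

## Phantoms

The generator emulates the geometry that matters to this pipeline: dark
curvilinear vessels of varying caliber on a brighter, vignetted circular
field with additive Gaussian noise, plus an exact ground-truth mask.

Defaults (chosen once as the package's standard test conditions):
256×256 canvas; FOV radius 0.47·min(h, w); 3 root vessels entering at
spread-out rim points and running along chords (aimed at a point offset
from the center) so large avascular gaps remain, each bifurcating once
with children tapering to 0.6–0.8 of the parent radius; radii 1.5–5 px;
centerline depth (contrast) 0.3 below a background of 0.8; quadratic
vignette of amplitude 0.2; noise σ = 0.02. Cross-sections are Gaussian
with σ_r = r/√2, so the intensity dip at the annotated mask boundary
(distance r) is still e⁻¹ ≈ 37 % of the centerline depth. Vessel density
inside the FOV is 0.087–0.117 over 20 seeds, within the range typical of
retinal photographs. Identical specs are bit-reproducible.

What the phantoms do not model: optic disc and fovea, lesions and
exudates, central vessel reflexes, heavy-tailed sensor noise, and the
color statistics of real fundus cameras. Passing the phantom suite
demonstrates geometric and contrast behavior of the pipeline, not
clinical performance; results on real datasets must be measured with the
dataset evaluation tools.

On these defaults the full pipeline reaches Dice 0.87–0.91 against truth
over 20 seeds and strictly exceeds mean-C thresholding of the raw
inverted channel on every seed — the enhancement benefit restated at
phantom scale, driven mostly by thick-vessel interiors that defeat a
purely local threshold. Raising τ from 0.5 to 1.0 reduces the number of
recovered vessel pixels, matching the filter's designed τ behavior.

## Numerical conventions and degenerate inputs

- Reflect padding for every convolution (Gaussian, differences, box
  mean), avoiding synthetic edges at the frame.
- Eigenvalue ties (|λ₁| = |λ₂|) ordered ascending by signed value.
- Threshold ties (difference exactly C) are background.
- A constant image produces an exactly empty mask (zero Hessian → zero
  vesselness → zero enhanced contrast).
- Degenerate inputs raise typed errors rather than returning silently:
  empty FOV after thresholding, erosion that consumes the whole FOV,
  σ kernels exceeding the image extent, a box window as large as the
  image, images smaller than the coarsest curvelet support (2^J), and
  all-zero confusion counts.
- The pipeline consumes no randomness; repeated runs are bit-identical.
  All phantom randomness flows from the single spec seed.

## Problem sizes used by the validation suite

Curvelet identities are checked on 64–256 px images, the vesselness
vectorization against a per-pixel reference on 16×16 images with scale
grids whose kernels fit, and the end-to-end recovery on twenty 256×256
phantoms; these sizes exercise every code path (wedge geometry varies
with image size) while keeping the whole suite fast.

## Known limitations

- The method is unsupervised and tuned by four scalars (τ, α, W, C);
  no claim is made that the defaults are optimal for any particular
  camera or dataset. A τ sweep tool makes per-image tuning explicit.
- Very wide vessels (width ≳ W) cannot be recovered by a local mean
  threshold regardless of enhancement.
- The curvelet bounding-box wrapping stores wedges on slightly larger
  grids than a sheared CurveLab-style wrap; coefficients are exact but
  not arranged identically to other FDCT implementations.
- The per-scale maximum in the regularization makes the vesselness map
  depend globally on image content: adding or removing a strong
  structure changes the response of faint ones at the same scale.
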