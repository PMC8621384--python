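# vesselx

Unsupervised retinal blood-vessel segmentation for 2D fundus photographs:
multiscale Hessian (Jerman) vesselness filtering fused with curvelet-domain
coefficient enhancement, binarized by mean-C adaptive thresholding. The
package ships a seeded synthetic-phantom generator with exact ground truth
and a pixel-level evaluation harness, so the whole method is testable
without downloading any retinal database.

It is aimed at medical-image-analysis researchers and engineers who need a
classical (training-free) vessel segmentation baseline, a clean 2D
implementation of the Jerman filter, or a self-contained wrapping-FDCT
curvelet transform with exact tight-frame behavior.

## Method

For a fundus image the green channel `I` is used throughout (best
vessel/background contrast). The pipeline is:

1. **Field of view.** A circular FOV mask is estimated (or loaded); the
   aperture rim is flattened by eroding the FOV and continuing the image
   with nearest-inside values, so second-derivative filters see no rim edge.
2. **Vesselness.** At each scale `s` (probed vessel width, default 3–16 px,
   step 0.5; Gaussian σ = s/4), the σ²-normalized Hessian eigenvalues
   |λ₁| ≤ |λ₂| are computed in closed form. The larger eigenvalue is
   regularized against its per-scale maximum with cut-off τ ∈ (0, 1]
   (default 0.5):

       λρ = λ₂              if λ₂ > τ·maxₓ λ₂
          = τ·maxₓ λ₂       if 0 < λ₂ ≤ τ·maxₓ λ₂
          = 0               otherwise

   and the response is

       ν = 0                                 if λ₂ ≤ 0 or λρ ≤ 0
         = 1                                 if λ₂ ≥ λρ/2 > 0
         = λ₂²(λρ − λ₂)·(3/(λ₂ + λρ))³       otherwise

   The vesselness map `F(x)` is the supremum of ν over scales; it lies in
   [0, 1] and plateaus at 1 inside vessels of matched width.
3. **Curvelet enhancement.** The map `F·(1 − I)` (vesselness gating the
   inverted channel) is decomposed with a wrapping fast discrete curvelet
   transform (5 levels, 16 orientations at the second-coarsest level,
   doubling every second level; Meyer windows; exact tight frame). The
   coarsest (core) level is zeroed, every finer coefficient is multiplied
   by α = 1.2, and the inverse transform plus min-max rescale gives the
   enhanced image: background darkened, curvilinear detail lifted.
4. **Segmentation.** Mean-C thresholding: a pixel is vessel when it exceeds
   its W×W box mean by more than C (defaults W = 13, C = 0.039), restricted
   to the FOV; morphological opening and small-component removal clean up
   speckle (disableable).
5. **Evaluation.** TP/FP/TN/FN inside the FOV give sensitivity,
   specificity, accuracy and precision per image, plus unweighted column
   means in the layout of the standard DRIVE/CHASE_DB1 result tables.

## Worked example

```bash
$ vesselx phantom --out ph --seed 7          # synthetic vessel tree + truth
phantom written to ph
$ vesselx segment ph/image.png --truth ph/truth.png --fov ph/fov.png \
      --out mask.png --report row.csv
se=0.9300 sp=0.9818 acc=0.9761 pr=0.8639
```

The four numbers are pixel ratios against the phantom's exact ground truth
inside the FOV: 93.0 % of true vessel pixels recovered (sensitivity),
98.2 % of background kept clean (specificity), 97.6 % of all pixels
classified correctly (accuracy), and 86.4 % of predicted vessel pixels
true (precision). `mask.png` is the binary segmentation; `row.csv` holds
the same row plus a mean line.

The same from Python:

```python
from vesselx import PhantomSpec, make_vessel_tree, run_pipeline, dice

img, truth = make_vessel_tree(PhantomSpec(seed=7))
result = run_pipeline(img, truth=truth)
print(result.metrics)          # sensitivity/specificity/accuracy/precision
print(dice(result.mask, truth, img.fov))
```

Directory-level evaluation (DRIVE/CHASE_DB1-style layouts pair by stem or
sorted order) and a τ sweep are available via `vesselx evaluate ... --out
report.csv` and `vesselx segment ... --tau-sweep 0.5:1.0:0.1`.

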