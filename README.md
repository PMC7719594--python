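# ventseg

Level set segmentation of weak-boundary structures — brain ventricles in
CT/MR slices being the motivating case — combining **distance-regularized
level set evolution** (DRLSE) with **region-scalable intensity fitting**
(RSF), together with the full evaluation-metric battery and a
coordinate-wise parameter tuner.

## The problem

Ventricular enlargement is a landmark of cerebral atrophy, so measuring
ventricle shape requires separating the CSF-filled cavities from the
surrounding tissue. Purely edge-driven active contours fail here: parts of
the ventricular boundary are *weak* — blurred, low-contrast transitions
with almost no intensity gradient — and an edge-only evolution leaks
straight through them.

## The model

A contour is carried implicitly as the zero level of a function φ
(negative inside), evolved by gradient descent on

```
E(φ) = μ ∫ p(|∇φ|) dx
     + λ ∫ g (I − f₁)² M₁(φ) dx
     + α ∫ g (I − f₂)² M₂(φ) dx
     [ + ν ∫ g δ_ε(φ) |∇φ| dx ]
```

* `p` is the double-well potential with minima at |∇φ| = 0 and 1; its flow
  keeps φ well-behaved without any re-initialization (the DRLSE idea).
* `g = 1 / (1 + |∇(G_σ ∗ I)|²)` is the edge indicator, ≈0 on strong edges.
* `f₁, f₂` are intensity approximations inside/outside the contour, with
  memberships `M₁ = H_ε(−φ)`, `M₂ = 1 − M₁`; the squared residuals
  `(I − f_i)²` replace the classical edge-only length/area data terms, so
  the contour responds to *regional intensity*, not just gradient — this
  is what holds a weak boundary.
* The bracketed edge-weighted curvature term is an optional length penalty
  (weight `curvature_weight`, default λ/2; set 0 for the bare model).

Tuned defaults (selected by the coordinate-wise grid search implemented in
`ventseg.tuning`): α=2, λ=1, ε=2, Δt=1.5, Gaussian edge kernel with σ=2.5
and size 15, μ=0.2/Δt.

## Worked example

```python
from ventseg import (BoundingBox, EvolutionParams, evaluate_masks,
                     make_disk_phantom, run_segmentation)

phantom = make_disk_phantom(shape=(64, 64), radius=18.0)   # dark disk on 120
box = BoundingBox.around_mask(phantom.truth, pad=5)        # rectangular seed
mask, state = run_segmentation(phantom.image, box, EvolutionParams(max_iter=500))
print(state.status, state.iteration, evaluate_masks(mask, phantom.truth).dice)
```

prints `converged 13 1.0`: the contour locks onto the disk boundary in 13
iterations and the recovered mask matches the generating mask pixel for
pixel (Dice 1.0).

The point of the method shows on the ventricle phantom
(`examples/02_weak_boundary_comparison.py`), whose crescents have a 60°
blurred, contrast-halved boundary arc:

```
regional + edges (modified): dice = 0.9937  [converged, 48 iters]
edge-only        (drlse   ): dice = 0.0038  [converged, 252 iters]
```

The edge-only baseline leaks through the weak arc and collapses through
the thin crescents; the regional terms hold the boundary. The other
scripts in `examples/` demonstrate parameter tuning and the metric
battery, one capability per file.

A thin CLI wraps the same pipeline:

```bash
ventseg phantom --kind ventricle --out-prefix out/ph
ventseg segment out/ph_image.png --center-frac 0.8 --truth out/ph_truth.png \
        --out-prefix out/run
ventseg evaluate out/run_mask.png out/ph_truth.png
```

## Layout

| module | contents |
| --- | --- |
| `ventseg.core` | stencil calculus, smoothed Heaviside/Dirac pairs, double-well potential |
| `ventseg.energies` | edge indicator, regional fits, regularizer/curvature flows, the evolution step |
| `ventseg.segment` | bounding-box seeding, evolution loop with stopping logic, skull stripping |
| `ventseg.metrics` | confusion counts, Dice/Jaccard, sensitivity/specificity/accuracy (two definition modes), PSNR, SSIM |
| `ventseg.tuning` | coordinate-wise grid search and tuning tables |
| `ventseg.phantoms` | seeded disk and bilateral-ventricle phantoms with ground truth |
| `ventseg.io` / `ventseg.cli` | PNG/TIFF/DICOM/NIfTI readers, YAML configs, the `ventseg` command |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
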