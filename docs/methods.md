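# Methods

## Model

The segmentation carries a contour as the zero level set of φ (negative
inside) and descends the energy

E(φ) = μ ∫ p(|∇φ|) + λ ∫ g·(I − f₁)²·M₁(φ) + α ∫ g·(I − f₂)²·M₂(φ)
[ + ν ∫ g·δ_ε(φ)·|∇φ| ],

whose explicit-Euler descent step is

φ ← φ + Δt·[ μ·div(d_p(|∇φ|)∇φ) + δ_ε(φ)·g·(λe₁ − αe₂)
             + ν·δ_ε(φ)·div(g∇φ/|∇φ|) ],   e_i = (I − f_i)².

The distance-regularizing first term (double-well potential `p` with
minima at gradient magnitudes 0 and 1) removes the classical need to
periodically re-initialize φ to a signed distance function. The regional
terms are the weak-boundary mechanism: they compare every pixel's
intensity against fitted approximations of the inside (f₁) and outside
(f₂) intensity, weighted by the edge indicator g, so the contour is driven
by regional statistics where the gradient carries no information.

**Memberships and smoothed distributions.** M₁ = H_ε(−φ), M₂ = 1 − M₁ with
the arctan-regularized Heaviside H_ε(x) = ½[1 + (2/π)arctan(x/ε)]; its
derivative, the Lorentzian δ_ε(x) = ε/(π(ε² + x²)), is the default delta
in the flow. The compactly supported sine pair is provided as an option
(`dirac_flow="compact"`); measured on the phantoms it freezes pixels that
one data kick pushes beyond the δ-support, which costs a one-pixel erosion
ring on clean images, so the Lorentzian — under which any mis-assigned
pixel keeps feeling a restoring force — is the default.

**Regional fits.** Three kernels are implemented behind
`regional_fits(..., fits_kernel=...)`:

* `global` (default in the segmenter): f_i is the plain membership-weighted
  mean of the intensities — the scale-free limit of the local kernel.
* `gaussian`: the parent region-scalable form
  f_i = [K_σ∗(M_i·I)]/[K_σ∗M_i] with the same truncated Gaussian as the
  edge indicator (σ=2.5, 15×15). Strictly local fits have two measured
  failure modes under the tuned asymmetric weights: pixels farther than
  the kernel half-width from any intensity structure feel exactly zero
  regional force (frozen islands inside the seed box), and flat noisy
  regions acquire a net drift of order −(α−λ)σ²_noise.
* `edge_weighted_global`: the kernel identified with the edge indicator
  itself, i.e. f_i are global g-weighted means. Rejected as default
  because g is small near edges, so thin structures — whose pixels all lie
  near an edge — are down-weighted out of their own fit.

A region of interest (e.g. a skull-stripped brain mask) may be supplied;
the fits are then computed over the ROI only and φ is clamped to the
outside plateau beyond it. This mirrors the clinical pipeline, where the
brain is isolated before segmentation and the (much brighter) background
would otherwise enter the outside fit as a third intensity class.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| α | outside-region weight | 2 | tuned by the grid search |
| λ | inside-region weight | 1 | tuned |
| ε | Heaviside/Dirac width (px) | 2 | tuned |
| Δt | time step | 1.5 | tuned |
| σ, ksize | Gaussian kernel for g | 2.5, 15 | tuned |
| μ | regularizer weight | 0.2/Δt | conventional; guard Δt·μ < ¼ |
| ν (`curvature_weight`) | length penalty | λ/2 | 0 gives the bare model |
| c0 | initialization plateau | 2 | binary-step seeding ±c0 |
| `force_cap` | regional speed bound | c0/Δt | see Numerics |

Intensities are min–max rescaled to [0, 255] before segmentation: the
tuned weights act on squared intensity residuals, so the scale must be
fixed for them to be meaningful.

## Numerics

* Central differences in the interior, one-sided at borders; every
  spatial-derivative flow first applies a mirrored Neumann extension
  (border lines replaced by their second interior neighbours) so the
  normal derivative vanishes at the image edge.
* Gaussian convolutions are separable, truncated to `ksize` and
  renormalized, with replicate borders.
* **Force cap.** On a [0, 255] image the squared residuals reach ~10⁴–10⁵,
  far beyond what explicit Euler at Δt = 1.5 tolerates: an uncapped data
  term displaces φ by tens of units in a single step. The regional speed
  δ_ε(φ)·g·(λe₁ − αe₂) is therefore clipped to ±c0/Δt — at most one
  plateau height of displacement per step. The cap preserves the sign of
  the force everywhere, hence the contour's equilibrium position, and
  restores the balance between data and regularization; without it the
  clean-disk mask is eroded (compact δ) or noise pixels flip far from the
  contour (Lorentzian δ).
* The fits f₁, f₂ are recomputed from the current φ before each step
  (semi-implicit alternating update).
* Degenerate guards: vanishing fit denominators fall back to global
  membership means; a level set whose memberships vanish everywhere is
  rejected with a diagnostic; non-finite φ after a step aborts with the
  iteration index.

**Stopping rule.** The zero-set area is tracked per iteration; the run
stops when it changes by < 0.1 % over 10 consecutive iterations, with a
`max_iter` fallback (default 1000). Because the binary-step seed needs a
few regularizer-only iterations before the data force engages, stability
only counts once the contour has moved at least once. A φ that ends
single-signed is reported as `contour_vanished` with an empty mask and a
warning, never an exception.

**Known limitation — the LSF does not stay a signed distance function.**
Near the converged boundary the regional force magnitude exceeds the
regularizer rate by orders of magnitude and points away from the contour
on both sides, so the transition zone steepens and |φ| inflates instead of
relaxing to unit slope; with the arctan Heaviside the data energy
decreases monotonically as |φ| grows, so no finite-slope equilibrium
exists. The segmentation (the zero set) is unaffected, but diagnostics
that expect |∇φ| ≈ 1 near the contour hold only for the classical
edge-only regime (`drlse_step`), not for the combined flow at the tuned
weights. `distance_regularizer_flow` itself has the exact fixed point: a
signed distance input yields a numerically zero flow.

## Baseline

`method="drlse"` runs the classical edge-only evolution
μR + λδ·div(g∇φ/|∇φ|) + αgδ with the same parameters. With α > 0 it
shrinks until the edge indicator stops it; on the ventricle phantom it
leaks through the weak arc and collapses through the thin crescents —
the failure mode the regional terms exist to fix — so its Dice is near
zero in the head-to-head comparison.

## Synthetic phantoms

The clinical CT/MR images the method targets are not distributable, so the
study conditions are emulated:

* **Disk phantom** (64×64, radius 18, values 40/120, i.e. contrast 80):
  minimal convergence object; optional Gaussian noise, clipped to [0, 255].
* **Ventricle phantom** (128×128): background 160, brain ellipse 120, two
  mirrored crescents (a tilted ellipse minus a medially shifted bite) at
  120 − contrast, defaults contrast 50, noise SD 5. Along 60° of each
  crescent's laterally facing boundary the step is contrast-halved and
  Gaussian-blurred (σ=3) — the weak-boundary geometry. The ground truth is
  always the unblurred generating mask.

All randomness flows through an explicit seed. What the phantoms do *not*
model: partial-volume effects, bias fields, anatomical texture, skull and
scalp layers, slice-thickness averaging. Passing tests therefore show that
the implementation realizes the model's mechanics (weak-boundary
retention, noise robustness, tuning behavior) at realistic intensity
ratios, not that clinical accuracy figures transfer.

## Parameter tuning

`tune_parameters` is a coordinate-wise grid search: one parameter at a
time, every candidate is run through the full segmentation on each tuning
image, means ± SDs of Dice, Jaccard, sensitivity, specificity and accuracy
are tabulated, the candidate with the highest mean of the selection metric
(default accuracy, ties to the smallest candidate) is fixed, and the sweep
proceeds. Candidates whose runs fail (invalid combinations, divergence,
vanished contour) are recorded as failed and excluded rather than aborting
the sweep. Auto-derived quantities (μ from Δt, the force cap from c0/Δt)
follow their parents between sweeps.

## Metric definition modes

Sensitivity/specificity are reported in two modes: `standard`
(TP/(TP+FN), TN/(TN+FP)) and `as_printed`, which preserves verbatim the
nonstandard published formulas (sensitivity = TP/(TP+FP), i.e. precision;
specificity = TP/(TN+FP)) so published tables can be audited under either
reading. Accuracy is (TP+TN)/total in both. PSNR is reported in dB (an
infinity flag for identical inputs); SSIM uses the standard 11×11 Gaussian
window (σ=1.5) with stabilizers (0.01·peak)² and (0.03·peak)². Two empty
masks count as perfect agreement (Dice = Jaccard = 1).

## Problem sizes

Tests and the acceptance script run on 64×64 (disk) and 128×128
(ventricle) phantoms with iteration budgets of 500–800; at these sizes a
full segmentation takes well under a second, which keeps the whole
verification cycle quick while leaving all mechanisms — weak boundaries,
noise, tuning sweeps — fully exercised.
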