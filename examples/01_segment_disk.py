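"""Segment a simple disk phantom with the combined level-set flow.

Builds a noiseless 64x64 phantom (dark disk, value 40, on a 120
background), seeds a rectangular box around it and evolves the contour
with the tuned parameters.  Prints the Dice overlap against the generating
mask and the number of iterations to convergence — Dice 1.0 means the
recovered region matches the ground truth pixel for pixel.
"""

from ventseg import (
    BoundingBox,
    EvolutionParams,
    evaluate_masks,
    make_disk_phantom,
    run_segmentation,
)

phantom = make_disk_phantom(shape=(64, 64), radius=18.0)
box = BoundingBox.around_mask(phantom.truth, pad=5)
mask, state = run_segmentation(phantom.image, box, EvolutionParams(max_iter=500))
report = evaluate_masks(mask, phantom.truth)

print(f"status      : {state.status} after {state.iteration} iterations")
print(f"dice        : {report.dice:.4f}")
print(f"jaccard     : {report.jaccard:.4f}")
print(f"accuracy    : {report.accuracy:.4f}")
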