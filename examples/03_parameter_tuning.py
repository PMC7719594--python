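"""Coordinate-wise grid search for the Heaviside width epsilon.

Five noisy disk phantoms with known ground truth form the tuning set; each
candidate epsilon is run through the full segmentation on every phantom
and the candidate with the highest mean accuracy is fixed.  The table
mirrors the usual tuning report: per candidate, mean +/- SD of each
similarity measure over the tuning set.
"""

from ventseg import (
    BoundingBox,
    EvolutionParams,
    ParameterGrid,
    make_disk_phantom,
    tune_parameters,
)

dataset = []
for seed in range(5):
    ph = make_disk_phantom(noise_sigma=18.0, seed=seed)
    dataset.append((ph.image, ph.truth, BoundingBox.around_mask(ph.truth, pad=5)))

grid = ParameterGrid(entries=[("eps", [0.5, 1.0, 1.5, 2.0, 2.5])], metric="accuracy")
tuned, table = tune_parameters(dataset, grid, EvolutionParams(max_iter=150))

cols = ["candidate", "dice_mean", "dice_sd", "accuracy_mean", "accuracy_sd"]
print(table.summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nselected epsilon: {tuned.eps}")
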