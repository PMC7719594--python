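"""The full evaluation battery between a mask and its ground truth.

Compares a deliberately imperfect mask (the truth eroded by one pixel)
against the generating mask, in both definition modes: `standard` uses the
conventional sensitivity TP/(TP+FN) and specificity TN/(TN+FP);
`as_printed` preserves the nonstandard published formulas (sensitivity
TP/(TP+FP), i.e. precision, and specificity TP/(TN+FP)) for auditing
published numbers.  PSNR is reported in dB (infinite for identical masks);
SSIM is the mean local structural similarity.
"""

from scipy.ndimage import binary_erosion

from ventseg import evaluate_masks, make_ventricle_phantom

truth = make_ventricle_phantom(noise_sigma=0.0).truth
mask = binary_erosion(truth).astype(truth.dtype)

for mode in ("standard", "as_printed"):
    r = evaluate_masks(mask, truth, mode=mode)
    print(f"[{mode}]")
    print(f"  dice={r.dice:.4f} jaccard={r.jaccard:.4f}")
    print(f"  sensitivity={r.sensitivity:.4f} specificity={r.specificity:.4f} "
          f"accuracy={r.accuracy:.4f}")
    print(f"  psnr={r.psnr_db:.2f} dB  ssim={r.ssim:.4f}")
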