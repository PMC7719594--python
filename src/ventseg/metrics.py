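"""Segmentation evaluation measures.

Pixelwise confusion counts and the derived overlap/rate measures (Dice,
Jaccard, sensitivity, specificity, accuracy), plus the image-fidelity
measures PSNR and SSIM between a segmentation mask and its ground truth.

Two definition modes are provided for the rate measures.  ``standard`` is
the conventional one (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)).
``as_printed`` preserves, verbatim, the nonstandard formulas the source
tables use (sensitivity = TP/(TP+FP), i.e. precision, and specificity =
TP/(TN+FP)) so published numbers can be audited against either reading.
Accuracy = (TP+TN)/total in both modes.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .core import as_field

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "dice",
    "jaccard",
    "sens_spec_acc",
    "psnr",
    "ssim",
    "evaluate_masks",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(a, name: str) -> np.ndarray:
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return a.astype(bool)


def confusion(mask, truth) -> ConfusionCounts:
    """Pixelwise confusion counts with foreground = 1."""
    m = _as_binary(mask, "mask")
    t = _as_binary(truth, "truth")
    if m.shape != t.shape:
        raise ValueError(f"mask {m.shape} and truth {t.shape} shapes differ")
    return ConfusionCounts(
        tp=int((m & t).sum()),
        tn=int((~m & ~t).sum()),
        fp=int((m & ~t).sum()),
        fn=int((~m & t).sum()),
    )


def dice(c: ConfusionCounts) -> float:
    """Dice overlap 2 TP / (2 TP + FP + FN); two empty masks agree perfectly (1)."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard overlap TP / (TP + FP + FN); two empty masks agree perfectly (1)."""
    denom = c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def sens_spec_acc(c: ConfusionCounts, mode: str = "standard") -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) under the chosen definition mode.

    A zero denominator yields NaN (undefined) rather than an error.
    """

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    if mode == "standard":
        sens = ratio(c.tp, c.tp + c.fn)
        spec = ratio(c.tn, c.tn + c.fp)
    elif mode == "as_printed":
        sens = ratio(c.tp, c.tp + c.fp)
        spec = ratio(c.tp, c.tn + c.fp)
    else:
        raise ValueError(f"mode must be 'standard' or 'as_printed', got {mode!r}")
    acc = ratio(c.tp + c.tn, c.total)
    return sens, spec, acc


def psnr(a, b, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10 log10(peak^2 / MSE), in dB.

    Identical inputs (MSE = 0) return ``math.inf``.
    """
    a = as_field(a, "first image")
    b = as_field(b, "second image")
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def ssim(a, b, peak: float = 1.0) -> float:
    """Mean local structural similarity (11x11 Gaussian window, sigma 1.5,
    stabilizers C1 = (0.01 peak)^2, C2 = (0.03 peak)^2)."""
    a = as_field(a, "first image")
    b = as_field(b, "second image")
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError(f"images must be at least 11x11 for SSIM, got {a.shape}")
    return float(
        structural_similarity(
            a,
            b,
            data_range=peak,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
        )
    )


@dataclass
class MetricReport:
    """Flat per-image record of all evaluation measures."""

    dice: float
    jaccard: float
    sensitivity: float
    specificity: float
    accuracy: float
    psnr_db: float
    ssim: float
    definition_mode: str = "standard"

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_masks(mask, truth, mode: str = "standard") -> MetricReport:
    """Full metric battery between a binary mask and its ground truth.

    PSNR and SSIM treat the masks as images with peak value 1.
    """
    c = confusion(mask, truth)
    sens, spec, acc = sens_spec_acc(c, mode)
    m = np.asarray(mask, dtype=float)
    t = np.asarray(truth, dtype=float)
    return MetricReport(
        dice=dice(c),
        jaccard=jaccard(c),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        psnr_db=psnr(m, t, peak=1.0),
        ssim=ssim(m, t, peak=1.0),
        definition_mode=mode,
    )
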