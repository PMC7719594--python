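"""Synthetic phantoms emulating windowed head CT/MR slices.

The clinical images the method targets are not distributable, so every
other module is exercised on phantoms that reproduce their salient
features: dark CSF-filled lateral-ventricle-like structures inside a
brighter brain on a still brighter background, boundary segments that are
either sharp steps or weak (locally blurred and contrast-reduced), and
additive Gaussian noise.  Each phantom carries the exact generating mask
as ground truth and a metadata record of every generation parameter.

All randomness flows through the explicit ``seed`` argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["Phantom", "make_disk_phantom", "make_ventricle_phantom"]

BACKGROUND_VALUE = 160.0
BRAIN_VALUE = 120.0


@dataclass
class Phantom:
    """A synthetic image, its generating ground-truth mask, and metadata."""

    image: np.ndarray
    truth: np.ndarray
    meta: dict = field(default_factory=dict)


def _add_noise(image: np.ndarray, noise_sigma: float, seed: int) -> np.ndarray:
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, image.shape)
    return np.clip(image, 0.0, 255.0)


def make_disk_phantom(
    shape: tuple[int, int] = (64, 64),
    radius: float = 18.0,
    inside_val: float = 40.0,
    outside_val: float = 120.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Phantom:
    """Centered disk on a uniform background: the minimal convergence object."""
    h, w = shape
    if radius + 5 > min(h, w) / 2:
        raise ValueError(
            f"radius {radius} does not fit in shape {shape} with a 5-pixel margin"
        )
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - (h - 1) / 2.0, cc - (w - 1) / 2.0)
    truth = (dist < radius).astype(np.uint8)
    image = np.where(truth == 1, float(inside_val), float(outside_val))
    image = _add_noise(image, noise_sigma, seed)
    meta = dict(
        kind="disk",
        shape=(int(h), int(w)),
        radius=float(radius),
        inside_val=float(inside_val),
        outside_val=float(outside_val),
        contrast=float(abs(outside_val - inside_val)),
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )
    return Phantom(image=image, truth=truth, meta=meta)


def _ellipse_mask(shape, center, semiaxes, angle_deg=0.0):
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    t = np.deg2rad(angle_deg)
    # rotate into the ellipse frame: u along the row semiaxis, v along the column one
    u = dy * np.cos(t) + dx * np.sin(t)
    v = -dy * np.sin(t) + dx * np.cos(t)
    return (u / semiaxes[0]) ** 2 + (v / semiaxes[1]) ** 2 <= 1.0


def make_ventricle_phantom(
    shape: tuple[int, int] = (128, 128),
    contrast: float = 50.0,
    weak_arc_deg: float = 60.0,
    blur_sigma: float = 3.0,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> Phantom:
    """Bilateral ventricle-like phantom with mixed sharp/weak boundaries.

    Geometry: background 160, brain ellipse 120, two mirrored crescent
    (comma-like) dark regions of value ``120 - contrast``.  Along
    ``weak_arc_deg`` of each crescent's laterally facing boundary the step
    is halved in contrast and Gaussian-blurred with ``blur_sigma`` — the
    weak-boundary failure mode that defeats purely edge-driven evolution.
    The ground truth is always the unblurred generating mask.
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError(f"shape must be at least 64x64, got {shape}")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if contrast <= 6.0 * noise_sigma:
        warnings.warn(
            f"contrast {contrast} <= 6*noise_sigma = {6 * noise_sigma}: "
            "structure statistically invisible",
            stacklevel=2,
        )
    brain = _ellipse_mask(shape, ((h - 1) / 2.0, (w - 1) / 2.0), (0.44 * h, 0.42 * w))
    truth = np.zeros(shape, dtype=bool)
    weak = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        center = (0.47 * h, 0.5 * w + side * 0.15 * w)
        body = _ellipse_mask(shape, center, (0.21 * h, 0.075 * w), angle_deg=side * 20.0)
        bite_center = (0.47 * h, 0.5 * w + side * 0.10 * w)
        bite = _ellipse_mask(shape, bite_center, (0.15 * h, 0.05 * w), angle_deg=side * 20.0)
        vent = body & ~bite
        truth |= vent
        if weak_arc_deg > 0:
            rr, cc = np.mgrid[0:h, 0:w]
            # angle about the ventricle centre, measured from its lateral direction
            ang = np.rad2deg(np.arctan2(rr - center[0], side * (cc - center[1])))
            dist = np.hypot(rr - center[0], cc - center[1])
            weak |= (np.abs(ang) <= weak_arc_deg / 2.0) & (dist <= 0.30 * h)
    truth &= brain
    image = np.full(shape, BACKGROUND_VALUE)
    image[brain] = BRAIN_VALUE
    image[truth] = BRAIN_VALUE - contrast
    if weak_arc_deg > 0 and weak.any():
        weakened = image.copy()
        weakened[truth & weak] = BRAIN_VALUE - contrast / 2.0
        blurred = gaussian_filter(weakened, blur_sigma, mode="nearest")
        image = np.where(weak, blurred, image)
    image = _add_noise(image, noise_sigma, seed)
    meta = dict(
        kind="ventricle",
        shape=(int(h), int(w)),
        contrast=float(contrast),
        weak_arc_deg=float(weak_arc_deg),
        blur_sigma=float(blur_sigma),
        noise_sigma=float(noise_sigma),
        seed=int(seed),
    )
    return Phantom(image=image, truth=truth.astype(np.uint8), meta=meta)
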