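"""Grid calculus and smoothed distributional functions for level-set evolution.

Scalar fields are plain 2-D ``float64`` numpy arrays on a unit-spaced pixel
grid; by convention the first axis is the row (``y``) and the second the
column (``x``).  Derivatives use central differences in the interior and
one-sided differences at the borders; the flow operators in
:mod:`ventseg.energies` apply a mirrored Neumann extension
(:func:`neumann_extend`) before differentiating so the normal derivative
vanishes at the image edge.

Two smoothed Heaviside/Dirac pairs are provided:

* the arctan/Lorentzian pair (:func:`smoothed_heaviside`,
  :func:`smoothed_dirac`), supported on all of the real line — required for
  the region-membership functions, which must stay strictly positive away
  from the contour for the regional intensity fits to be well defined;
* the compactly supported sine pair (:func:`compact_heaviside`,
  :func:`compact_dirac`), the classical choice that confines the data flow
  to a band of width ``2*eps`` around the zero level set.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "VectorField",
    "gradient",
    "divergence",
    "neumann_extend",
    "smoothed_heaviside",
    "smoothed_dirac",
    "compact_heaviside",
    "compact_dirac",
    "double_well_dp",
    "double_well_potential",
]


def as_field(f, name: str = "field") -> np.ndarray:
    """Coerce *f* to a valid 2-D scalar field, rejecting bad input.

    A valid field is at least 3x3 (interior points exist for the stencils)
    and contains only finite values.
    """
    f = np.asarray(f, dtype=float)
    if f.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got {f.ndim}-D")
    if f.shape[0] < 3 or f.shape[1] < 3:
        raise ValueError(f"{name} must be at least 3x3, got {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError(f"non-finite values in {name}")
    return f


class VectorField(NamedTuple):
    """A 2-D vector field: x (column-direction) and y (row-direction) parts."""

    x: np.ndarray
    y: np.ndarray


def gradient(f, name: str = "field") -> VectorField:
    """Gradient of a scalar field: central differences, one-sided at borders."""
    f = as_field(f, name)
    gy, gx = np.gradient(f)
    return VectorField(x=gx, y=gy)


def divergence(v: VectorField) -> np.ndarray:
    """Divergence d(vx)/dx + d(vy)/dy with the same stencils as :func:`gradient`."""
    vx = np.asarray(v[0], dtype=float)
    vy = np.asarray(v[1], dtype=float)
    if vx.shape != vy.shape:
        raise ValueError(
            f"vector components have mismatched shapes {vx.shape} vs {vy.shape}"
        )
    return np.gradient(vx, axis=1) + np.gradient(vy, axis=0)


def neumann_extend(f) -> np.ndarray:
    """Mirror border rows/columns onto their second interior neighbours.

    After the extension the central difference across each border pixel is
    (approximately) zero in the normal direction, i.e. a reflecting Neumann
    boundary condition.
    """
    f = as_field(f)
    g = f.copy()
    g[0, :] = g[2, :]
    g[-1, :] = g[-3, :]
    g[:, 0] = g[:, 2]
    g[:, -1] = g[:, -3]
    return g


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return eps


def smoothed_heaviside(x, eps: float):
    """Arctan-regularized Heaviside H_eps(x) = (1 + (2/pi) atan(x/eps)) / 2."""
    eps = _check_eps(eps)
    scalar = np.isscalar(x)
    out = 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(x, dtype=float) / eps))
    return float(out) if scalar else out


def smoothed_dirac(x, eps: float):
    """Lorentzian delta d/dx H_eps = eps / (pi (eps^2 + x^2))."""
    eps = _check_eps(eps)
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    out = (eps / np.pi) / (eps * eps + x * x)
    return float(out) if scalar else out


def compact_heaviside(x, eps: float):
    """Sine-regularized Heaviside, identically 0 / 1 outside |x| <= eps."""
    eps = _check_eps(eps)
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    inner = 0.5 * (1.0 + x / eps + np.sin(np.pi * x / eps) / np.pi)
    out = np.where(x < -eps, 0.0, np.where(x > eps, 1.0, inner))
    return float(out) if scalar else out


def compact_dirac(x, eps: float):
    """Raised-cosine delta supported on |x| <= eps (classical DRLSE choice)."""
    eps = _check_eps(eps)
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    out = np.where(
        np.abs(x) <= eps, (1.0 + np.cos(np.pi * x / eps)) / (2.0 * eps), 0.0
    )
    return float(out) if scalar else out


def double_well_dp(s):
    """d_p(s) = p'(s)/s for the double-well potential with minima at s=0, s=1.

    p(s) = (1/(2 pi)^2)(1 - cos 2 pi s) for s <= 1 and (s - 1)^2 / 2 for
    s >= 1.  The removable singularity at s = 0 resolves to the limit 1
    (np.sinc handles it exactly); the two branches agree at s = 1.
    """
    scalar = np.isscalar(s)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("double_well_dp requires s >= 0")
    out = np.where(s <= 1.0, np.sinc(2.0 * np.minimum(s, 1.0)), (s - 1.0) / np.maximum(s, 1.0))
    return float(out) if scalar else out


def double_well_potential(s):
    """The double-well penalty p(s) itself (used for energy monitoring)."""
    scalar = np.isscalar(s)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("double_well_potential requires s >= 0")
    low = (1.0 - np.cos(2.0 * np.pi * s)) / (2.0 * np.pi) ** 2
    high = 0.5 * (s - 1.0) ** 2
    out = np.where(s <= 1.0, low, high)
    return float(out) if scalar else out
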