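"""File readers/writers and run configuration.

Supported inputs: 8/16-bit PNG/TIFF, single-slice DICOM, and axial slices
of NIfTI volumes (a slice index is required for 3-D sources).  Every
source is returned as a float64 field; 16-bit integer and floating-point
sources are min-max rescaled to [0, 255] so the tuned energy weights are
meaningful regardless of the acquisition scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .core import as_field
from .energies import DEFAULT_FITS_KERNEL, EvolutionParams

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "overlay_contour",
    "RunConfig",
]


def _rescale_255(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi > lo:
        return (a - lo) * (255.0 / (hi - lo))
    return np.zeros_like(a)


def read_image(path, slice_index: int | None = None) -> np.ndarray:
    """Read a 2-D grayscale image as a float field.

    8-bit sources keep their native [0, 255] values; 16-bit and float
    sources (including DICOM after slope/intercept) are min-max rescaled to
    [0, 255].  RGB images are rejected: convert to grayscale first.
    ``slice_index`` selects the axial plane of a NIfTI volume.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffixes = [s.lower() for s in path.suffixes]
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim == 3:
            if slice_index is None:
                raise ValueError(
                    f"NIfTI volume {path} is 3-D: a slice index is required"
                )
            if not 0 <= slice_index < vol.shape[2]:
                raise ValueError(
                    f"slice index {slice_index} out of range for volume {vol.shape}"
                )
            vol = vol[:, :, slice_index]
        elif vol.ndim != 2:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim} in {path}")
        return as_field(_rescale_255(vol), "NIfTI slice")
    if suffixes and suffixes[-1] == ".dcm":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(float)
        if arr.ndim != 2:
            raise ValueError(f"DICOM {path} is not a single slice")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return as_field(_rescale_255(arr * slope + intercept), "DICOM slice")
    if suffixes and suffixes[-1] in (".png", ".tif", ".tiff"):
        arr = iio.imread(path)
        if arr.ndim == 3:
            raise ValueError(
                f"{path} is RGB; convert to grayscale before segmentation"
            )
        arr = np.asarray(arr)
        if arr.dtype == np.uint8:
            return as_field(arr.astype(float), "image")
        return as_field(_rescale_255(arr), "image")
    raise ValueError(
        f"unsupported image format {path.suffix!r} for {path} "
        "(expected png/tif/tiff, dcm, nii/nii.gz)"
    )


def write_image(path, image) -> None:
    """Write a [0, 255] field as an 8-bit grayscale PNG/TIFF."""
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).round().astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_mask(path, mask) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255)."""
    mask = np.asarray(mask)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    """Read a binary mask PNG written by :func:`write_mask`."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        raise ValueError(f"mask {path} must be grayscale")
    return (np.asarray(arr) > 127).astype(np.uint8)


def overlay_contour(image, mask) -> np.ndarray:
    """RGB overlay of the mask's boundary, drawn in red, over the image."""
    from skimage.segmentation import find_boundaries

    img = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    rgb = np.stack([img, img, img], axis=-1)
    edge = find_boundaries(np.asarray(mask).astype(bool), mode="inner")
    rgb[edge] = (255, 0, 0)
    return rgb


@dataclass
class RunConfig:
    """Fully resolved run configuration; round-trips through YAML."""

    params: EvolutionParams = field(default_factory=EvolutionParams)
    method: str = "modified"
    fits_kernel: str = DEFAULT_FITS_KERNEL
    definition_mode: str = "standard"
    box: tuple[int, int, int, int] | None = None
    box_fraction: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d = {k: v for k, v in d.items() if not k.startswith("_")}
        return dict(
            params=d,
            method=self.method,
            fits_kernel=self.fits_kernel,
            definition_mode=self.definition_mode,
            box=list(self.box) if self.box is not None else None,
            box_fraction=self.box_fraction,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            params=EvolutionParams(**d.get("params", {})),
            method=d.get("method", "modified"),
            fits_kernel=d.get("fits_kernel", "gaussian"),
            definition_mode=d.get("definition_mode", "standard"),
            box=tuple(d["box"]) if d.get("box") else None,
            box_fraction=d.get("box_fraction"),
        )


def write_report(path, report_dict: dict) -> None:
    """Write a metric report (or any flat record) as JSON, inf-safe."""

    def clean(v):
        if isinstance(v, float) and not np.isfinite(v):
            return "inf" if v > 0 else "-inf"
        return v

    Path(path).write_text(
        json.dumps({k: clean(v) for k, v in report_dict.items()}, indent=2)
    )
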