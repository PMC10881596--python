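"""Domain containers for CT slices and masks, plus file I/O.

Densities are Hounsfield units (HU): water ~ 0, subcutaneous fat strongly
negative (~ -100). Images and masks are 2D, row-major, 0-based, and always
paired by shape. A :class:`GrayscaleMask` stores the image restricted to a
binary support; zero is reserved for "outside support", and all statistics
must use the stored support mask rather than a zero test, because edema
densities straddle 0 HU.

Supported on disk: NIfTI (.nii/.nii.gz) and 16-bit PNG with a JSON sidecar
carrying the HU intercept and the physical spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
from PIL import Image as PILImage

__all__ = [
    "DensityImage",
    "BinaryMask",
    "GrayscaleMask",
    "SliceStack",
    "apply_mask",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class DensityImage:
    """A 2D CT slice of HU values with physical pixel geometry.

    Parameters
    ----------
    values
        2D array of densities in HU (stored as float64).
    pixel_spacing
        (row, col) spacing in mm; strictly positive.
    slice_thickness
        Slice thickness in mm; strictly positive.
    slice_index
        Ordinal position of the slice within its scan.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0
    slice_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("DensityImage requires a non-empty 2D grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("DensityImage values must be finite")
        spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0 or float(self.slice_thickness) <= 0:
            raise ValueError("pixel spacing and slice thickness must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pixel_spacing", spacing)
        object.__setattr__(self, "slice_thickness", float(self.slice_thickness))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class BinaryMask:
    """A 2D {0,1} mask, shape-paired with its image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("BinaryMask requires a non-empty 2D grid")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("BinaryMask values must be 0 or 1")
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


@dataclass(frozen=True)
class GrayscaleMask:
    """HU values restricted to a binary support; exactly zero outside it."""

    values: np.ndarray
    support: BinaryMask

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.support.shape:
            raise ValueError("GrayscaleMask values and support shapes differ")
        if np.any(values[~self.support.as_bool()] != 0):
            raise ValueError("GrayscaleMask must be zero outside its support")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def masked_values(self) -> np.ndarray:
        """In-support densities as a flat array (never use a zero test)."""
        return self.values[self.support.as_bool()]


@dataclass(frozen=True)
class SliceStack:
    """Ordered stack of slices (DensityImage or BinaryMask) from one scan.

    Shapes must agree across slices; DensityImage stacks must additionally
    share spacing/thickness and have strictly increasing slice_index.
    """

    slices: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if not slices:
            raise ValueError("SliceStack must contain at least one slice")
        shape = slices[0].shape
        if any(s.shape != shape for s in slices):
            raise ValueError("SliceStack slices must share one shape")
        if isinstance(slices[0], DensityImage):
            sp = slices[0].pixel_spacing
            th = slices[0].slice_thickness
            for s in slices:
                if s.pixel_spacing != sp or s.slice_thickness != th:
                    raise ValueError("SliceStack slices must share spacing")
            idx = [s.slice_index for s in slices]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError("slice_index must be strictly increasing")
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator:
        return iter(self.slices)

    def __getitem__(self, i):
        return self.slices[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


def apply_mask(image: DensityImage, mask: BinaryMask) -> GrayscaleMask:
    """Multiply an image by a binary mask, yielding a grayscale mask.

    The output equals the image where the mask is 1 and is zero elsewhere;
    the mask is retained as the support.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    return GrayscaleMask(values=image.values * mask.values, support=mask)


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_image(path, fmt: str | None = None) -> DensityImage:
    """Read a 2D CT slice from NIfTI or 16-bit PNG + JSON sidecar.

    NIfTI: 2D or (rows, cols, 1) payloads accepted; spacing from header zooms,
    thickness from the third zoom when present (else 1 mm). PNG16: stored
    values are de-offset to HU by the sidecar's ``intercept``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "nifti" if _is_nifti(path) else "png16"
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError(f"non-2D payload in {path} (shape {data.shape})")
        zooms = img.header.get_zooms()
        spacing = (float(zooms[0]), float(zooms[1]))
        thickness = float(zooms[2]) if len(zooms) >= 3 and zooms[2] > 0 else 1.0
        return DensityImage(values=np.asarray(data, dtype=np.float64),
                            pixel_spacing=spacing, slice_thickness=thickness)
    if fmt == "png16":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"missing spacing metadata sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        try:
            intercept = float(meta["intercept"])
            spacing = tuple(float(v) for v in meta["spacing_mm"])
            thickness = float(meta["thickness_mm"])
        except KeyError as exc:
            raise ValueError(f"sidecar {sidecar} missing key {exc}") from exc
        raw = np.asarray(PILImage.open(path), dtype=np.float64)
        if raw.ndim != 2:
            raise ValueError(f"non-2D payload in {path}")
        return DensityImage(values=raw + intercept, pixel_spacing=spacing,
                            slice_thickness=thickness)
    raise ValueError(f"unknown format {fmt!r}")


def write_image(image: DensityImage, path, fmt: str | None = None,
                intercept: float = -1024.0) -> None:
    """Write a slice as NIfTI (float, spacing in zooms) or PNG16 + sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = "nifti" if _is_nifti(path) else "png16"
    if fmt == "nifti":
        affine = np.diag([image.pixel_spacing[0], image.pixel_spacing[1],
                          image.slice_thickness, 1.0])
        data = image.values[:, :, None].astype(np.float64)
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    if fmt == "png16":
        shifted = image.values - intercept
        if shifted.min() < 0 or shifted.max() > 65535:
            raise ValueError("HU values out of range for 16-bit PNG at this intercept")
        PILImage.fromarray(np.round(shifted).astype(np.uint16)).save(path)
        _sidecar_path(path).write_text(json.dumps({
            "intercept": intercept,
            "spacing_mm": list(image.pixel_spacing),
            "thickness_mm": image.slice_thickness,
        }))
        return
    raise ValueError(f"unknown format {fmt!r}")


def write_mask(mask: BinaryMask, path, fmt: str | None = None) -> None:
    """Write a binary mask as uint8 NIfTI or 8-bit PNG; round-trip exact."""
    path = Path(path)
    if fmt is None:
        fmt = "nifti" if _is_nifti(path) else "png"
    if fmt == "nifti":
        data = mask.values[:, :, None].astype(np.uint8)
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
        return
    if fmt == "png":
        PILImage.fromarray(mask.values, mode="L").save(path)
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_mask(path, fmt: str | None = None) -> BinaryMask:
    """Read a binary mask written by :func:`write_mask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "nifti" if _is_nifti(path) else "png"
    if fmt == "nifti":
        data = np.asanyarray(nib.load(str(path)).dataobj)
        if data.ndim == 3 and data.shape[2] == 1:
            data = data[:, :, 0]
        if data.ndim != 2:
            raise ValueError(f"non-2D payload in {path}")
    elif fmt == "png":
        data = np.asarray(PILImage.open(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return BinaryMask(values=(np.asarray(data) > 0).astype(np.uint8))
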