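"""Core containers and NIfTI I/O.

All stages operate on axis-aligned grids in a canonical (RAS-like)
orientation: array axis 0 ≈ left-right, axis 1 ≈ anterior-posterior and
axis 2 the craniocaudal axis with the index increasing toward the lung
apex.  Oblique acquisitions are reoriented to the closest canonical frame
on load; genuinely oblique affines (shear between voxel and world axes)
are rejected rather than silently mishandled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

#: array axis that runs caudal → cranial in the canonical frame
CRANIOCAUDAL_AXIS = 2


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(spacing))
    if len(s) == 1:
        s = s * 3
    if len(s) != 3 or any(v <= 0 or not np.isfinite(v) for v in s):
        raise ValueError(f"spacing must be 3 positive finite numbers, got {spacing!r}")
    return s


@dataclass
class ImageVolume:
    """A 3-D scalar grid with per-axis voxel spacing (mm) and world origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.data.shape}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def same_grid(self, other: "ImageVolume", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(np.asarray(data), self.spacing, self.origin)

    # physical coordinates of every voxel centre, one array per axis (mm)
    def grid_coords(self) -> list[np.ndarray]:
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return list(np.meshgrid(*axes, indexing="ij"))


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on the baseline grid.

    The transform T(x) = x + u(x) maps baseline (fixed) world coordinates
    to follow-up (moving) world coordinates; warping the follow-up image
    through the field recovers the baseline anatomy (pull-back sampling).
    """

    data: np.ndarray  # (nx, ny, nz, 3), mm, component i along array axis i
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"expected (nx,ny,nz,3) field, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)
        fov = np.linalg.norm(np.array(self.data.shape[:3]) * np.array(self.spacing))
        if np.abs(self.data).max() > fov:
            raise ValueError("displacement magnitude exceeds the field-of-view diagonal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @classmethod
    def zeros(cls, shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        return cls(np.zeros(tuple(shape) + (3,)), spacing, origin)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=-1)


@dataclass
class JacobianMap:
    """Voxel-wise log of the Jacobian determinant of T(x) = x + u(x).

    Sign semantics: 0 = locally unchanged volume, < 0 = shrinkage,
    > 0 = expansion.  ``n_clamped`` records voxels whose determinant was
    not positive and was clamped at ``epsilon`` before the log.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    epsilon: float = 1e-6
    n_clamped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D map, got {self.data.shape}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self):
        return self.data.shape

    @property
    def clamped_fraction(self) -> float:
        return self.n_clamped / self.data.size

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.data, self.spacing, self.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_nifti(img) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.as_closest_canonical(img)
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    # reject oblique affines: off-diagonal terms must be negligible
    if np.abs(lin - np.diag(np.diag(lin))).max() > 1e-3 * spacing.max():
        raise ValueError(
            "oblique affine not supported; reorient/resample the volume first:\n"
            f"{aff}"
        )
    data = np.asanyarray(img.dataobj)
    return data, tuple(spacing), tuple(aff[:3, 3])


def load_volume(path) -> ImageVolume:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def save_volume(vol: ImageVolume, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def load_field(path) -> DisplacementField:
    data, spacing, origin = _grid_from_nifti(nib.load(str(path)))
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected a 4-D vector NIfTI with 3 components, got {data.shape}")
    return DisplacementField(np.asarray(data, dtype=np.float64), spacing[:3], origin)


def save_field(field: DisplacementField, path) -> None:
    aff = np.diag(list(field.spacing) + [1.0])
    aff[:3, 3] = field.origin
    img = nib.Nifti1Image(np.asarray(field.data, dtype=np.float32), aff)
    nib.save(img, str(path))


def load_mask_volume(path) -> ImageVolume:
    vol = load_volume(path)
    return vol.with_data(vol.data > 0.5)


def save_mask(mask: np.ndarray, like: ImageVolume, path) -> None:
    save_volume(like.with_data(np.asarray(mask, dtype=np.uint8)), path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# SimpleITK bridging (array axis 0 <-> sitk x axis)


def to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(np.float64)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    return img


def from_sitk(img: sitk.Image) -> ImageVolume:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(np.asarray(data, dtype=np.float64), img.GetSpacing(), img.GetOrigin())


def field_to_sitk(field: DisplacementField) -> sitk.Image:
    arr = np.ascontiguousarray(field.data.transpose(2, 1, 0, 3).astype(np.float64))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(field.spacing))
    img.SetOrigin(tuple(field.origin))
    return img


def field_from_sitk(img: sitk.Image) -> DisplacementField:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3) with components (x, y, z)
    data = arr.transpose(2, 1, 0, 3)
    return DisplacementField(data, img.GetSpacing(), img.GetOrigin())
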