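"""Preprocessing: isotropic resampling and lung-mask handling.

Scan pairs are resampled to a common 1 mm isotropic grid before
registration so that displacement fields, Jacobian maps and masks all
live on one canonical grid.  Lung masks may be supplied (the realistic
path — segmentation quality is upstream of this package) or derived from
intensity by a classical threshold-plus-morphology rule that is adequate
for phantom-style data.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.ndimage import zoom

from .core import ImageVolume, load_mask_volume


class SegmentationError(ValueError):
    pass


def resample_isotropic(
    vol: ImageVolume, target_mm: float = 1.0, mode: str = "linear"
) -> ImageVolume:
    """Resample onto an isotropic ``target_mm`` grid preserving world extent.

    ``mode='linear'`` for intensities, ``'nearest'`` for masks/labels.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be > 0")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if np.allclose(vol.spacing, target_mm, rtol=0, atol=1e-9):
        return ImageVolume(vol.data.copy(), (target_mm,) * 3, vol.origin)
    factors = np.asarray(vol.spacing) / target_mm
    order = 1 if mode == "linear" else 0
    data = zoom(
        np.asarray(vol.data, dtype=float),
        zoom=factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    return ImageVolume(data, (target_mm,) * 3, vol.origin)


def segment_lungs_threshold(
    vol: ImageVolume,
    air_threshold: float = -500.0,
    min_component_ml: float = 2.0,
    max_components: int = 2,
) -> ImageVolume:
    """Lung mask from intensity: low-attenuation components inside the body.

    Voxels below ``air_threshold`` that are not connected to the volume
    border (outside-body air) form lung candidates; the largest components
    above ``min_component_ml`` are kept and their interior holes filled.
    Suitable for phantom-like data; clinical scans should provide masks.
    """
    data = np.asarray(vol.data, dtype=float)
    low = data < air_threshold
    if not low.any():
        raise SegmentationError(
            f"no voxels below air_threshold={air_threshold}; is the intensity "
            "scale HU-like?"
        )

    # air connected to the border is outside the body
    labels, _ = ndimage.label(low)
    border_labels = set(np.unique(labels[0, :, :])) | set(np.unique(labels[-1, :, :]))
    border_labels |= set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :]))
    border_labels |= set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
    border_labels.discard(0)
    inside = low & ~np.isin(labels, sorted(border_labels))

    labels, n = ndimage.label(inside)
    if n == 0:
        raise SegmentationError(
            f"no low-intensity region enclosed by the body at threshold "
            f"{air_threshold}; empty lung mask"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    min_vox = min_component_ml * 1000.0 / vol.voxel_volume_mm3
    keep = np.argsort(sizes)[::-1][:max_components]
    keep = [k + 1 for k in keep if sizes[k] >= min_vox]
    if not keep:
        raise SegmentationError(
            f"largest enclosed air component is below min_component_ml="
            f"{min_component_ml}; empty lung mask at threshold {air_threshold}"
        )
    mask = np.isin(labels, keep)
    mask = ndimage.binary_fill_holes(mask)
    return vol.with_data(mask)


def load_mask(path, companion: ImageVolume, target_mm: float | None = None) -> ImageVolume:
    """Load a mask and check it shares the companion volume's grid.

    If ``target_mm`` is given, the mask is first resampled (nearest) to
    that spacing, mirroring the companion's preprocessing.
    """
    mask = load_mask_volume(path)
    if target_mm is not None:
        mask = resample_isotropic(mask, target_mm, mode="nearest")
        mask = mask.with_data(mask.data > 0.5)
    if mask.shape != companion.shape or not np.allclose(
        mask.spacing, companion.spacing, atol=1e-4
    ):
        raise ValueError(
            "mask grid does not match the companion volume: "
            f"mask {mask.shape} @ {mask.spacing} vs "
            f"volume {companion.shape} @ {companion.spacing}"
        )
    if not mask.data.any():
        raise SegmentationError(f"mask loaded from {path} is empty")
    return mask
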