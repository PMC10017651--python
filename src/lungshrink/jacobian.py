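"""Voxel-wise Jacobian-determinant analysis of displacement fields.

The deformation T(x) = x + u(x) aligns the follow-up scan to the baseline;
its Jacobian determinant det(I + du/dx) measures the local volume-change
ratio at each voxel, and the natural log of it (log-Jacobian) is the
quantity summarized per patient: 0 = unchanged, < 0 = shrinkage,
> 0 = expansion.

Derivatives are taken in world units (mm) using the per-axis voxel
spacing: central differences at interior voxels, one-sided at the volume
faces.  Non-positive determinants (folding, occasionally produced by real
registrations) are clamped at a small epsilon before the log, and the
clamp count is carried on the map so it stays visible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion

from .core import CRANIOCAUDAL_AXIS, DisplacementField, ImageVolume, JacobianMap


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(I + du/dx) per voxel, derivatives in mm."""
    u = field.data
    sp = field.spacing
    # J[i][j] = d u_i / d x_j
    J = [[np.gradient(u[..., i], sp[j], axis=j) for j in range(3)] for i in range(3)]
    for i in range(3):
        J[i][i] = J[i][i] + 1.0
    det = (
        J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
        - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
        + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
    )
    return det


def log_jacobian(
    det: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    epsilon: float = 1e-6,
) -> JacobianMap:
    """ln(max(det, epsilon)); clamped voxels are counted, not dropped."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    det = np.asarray(det, dtype=np.float64)
    clamped = det < epsilon
    data = np.log(np.where(clamped, epsilon, det))
    return JacobianMap(
        data, spacing, origin, epsilon=epsilon, n_clamped=int(clamped.sum())
    )


def logjac_of_field(field: DisplacementField, epsilon: float = 1e-6) -> JacobianMap:
    """Convenience: determinant + log in one step."""
    return log_jacobian(jacobian_determinant(field), field.spacing, field.origin, epsilon)


def eroded_mask(mask: np.ndarray, erosion_voxels: int = 1) -> np.ndarray:
    mask = np.asarray(mask) > 0.5
    if erosion_voxels > 0:
        mask = binary_erosion(mask, iterations=erosion_voxels)
    return mask


def mean_logjac(
    jac: JacobianMap, mask: np.ndarray | ImageVolume, erosion_voxels: int = 1
) -> float:
    """Masked mean log-Jacobian after eroding the mask boundary.

    A 1-voxel erosion (default) discards boundary voxels whose finite
    differences straddle the mask edge, where derivative estimates from a
    registration are least reliable.
    """
    if isinstance(mask, ImageVolume):
        mask = mask.data
    m = eroded_mask(mask, erosion_voxels)
    if not m.any():
        raise ValueError(
            f"mask is empty after erosion by {erosion_voxels} voxel(s); "
            "use a smaller erosion"
        )
    return float(jac.data[m].mean())


def regional_means(
    jac: JacobianMap,
    mask: np.ndarray | ImageVolume,
    axis: int | None = CRANIOCAUDAL_AXIS,
    erosion_voxels: int = 1,
) -> tuple[float, float, float]:
    """(basal, middle, apical) masked means over equal-extent craniocaudal
    thirds of the mask's bounding range.

    ``axis`` is the craniocaudal array axis with the index increasing
    toward the apex (the canonical orientation); pass it explicitly when
    the volume's orientation metadata is not canonical.
    """
    if axis is None:
        raise ValueError(
            "craniocaudal axis is ambiguous for this volume; pass axis= explicitly"
        )
    if isinstance(mask, ImageVolume):
        mask = mask.data
    m = eroded_mask(mask, erosion_voxels)
    if not m.any():
        raise ValueError("mask is empty after erosion")
    idx = np.where(m.any(axis=tuple(i for i in range(3) if i != axis)))[0]
    lo, hi = idx.min(), idx.max() + 1
    edges = np.linspace(lo, hi, 4)
    means = []
    pos = np.arange(m.shape[axis])
    for k in range(3):
        in_band = (pos >= edges[k]) & (pos < edges[k + 1] if k < 2 else pos <= edges[3])
        sel = np.zeros_like(m)
        sl = [slice(None)] * 3
        sl[axis] = in_band
        sel[tuple(sl)] = True
        band = m & sel
        means.append(float(jac.data[band].mean()) if band.any() else float("nan"))
    basal, middle, apical = means
    return basal, middle, apical


@dataclass
class PatientSummary:
    """Per-patient scalar summary row of the Jacobian analysis."""

    patient_id: str
    mean_logjac: float
    basal_mean: float
    middle_mean: float
    apical_mean: float
    clamped_fraction: float
    lung_volume_ml: float
    interval_months: float | None = None
    functional_group: str | None = None
    morphology_group: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_patient(
    patient_id: str,
    jac: JacobianMap,
    mask: np.ndarray | ImageVolume,
    erosion_voxels: int = 1,
    interval_months: float | None = None,
    functional_group: str | None = None,
    morphology_group: str | None = None,
) -> PatientSummary:
    if isinstance(mask, ImageVolume):
        voxvol = mask.voxel_volume_mm3
        mdata = mask.data
    else:
        voxvol = float(np.prod(jac.spacing))
        mdata = mask
    basal, middle, apical = regional_means(jac, mdata, erosion_voxels=erosion_voxels)
    return PatientSummary(
        patient_id=patient_id,
        mean_logjac=mean_logjac(jac, mdata, erosion_voxels),
        basal_mean=basal,
        middle_mean=middle,
        apical_mean=apical,
        clamped_fraction=jac.clamped_fraction,
        lung_volume_ml=float((np.asarray(mdata) > 0.5).sum() * voxvol / 1000.0),
        interval_months=interval_months,
        functional_group=functional_group,
        morphology_group=morphology_group,
    )
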