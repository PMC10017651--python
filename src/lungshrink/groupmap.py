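"""Common-space averaging and rendering of per-patient Jacobian maps.

Each patient's baseline scan is registered to a template (by default the
first patient's baseline, configurable), and the same transform
resamples the patient's log-Jacobian map into template space — values
are transported unchanged (linear interpolation, no Jacobian
reweighting), matching a plain group average.  Voxels a patient's map
does not reach are missing (NaN), not zero, and a per-voxel contributing
count accompanies every group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from scipy.ndimage import map_coordinates

from .core import DisplacementField, ImageVolume, JacobianMap
from .registration import RegistrationConfig, register_affine, register_deformable


@dataclass
class GroupMap:
    """Voxel-wise mean log-Jacobian of a patient group in template space."""

    data: np.ndarray  # NaN where no patient contributes
    count: np.ndarray  # contributing patients per voxel
    spacing: tuple
    label: str = ""
    n: int = 0

    def masked_mean(self, mask: np.ndarray | None = None) -> float:
        valid = self.count > 0
        if mask is not None:
            valid &= np.asarray(mask) > 0.5
        return float(self.data[valid].mean())


def to_common_space(
    jac: JacobianMap,
    patient_baseline: ImageVolume,
    template: ImageVolume,
    config: RegistrationConfig | None = None,
    deformable: bool = False,
) -> JacobianMap:
    """Resample a patient's map into template space via the transform that
    registers the patient baseline to the template."""
    if patient_baseline is template or (
        patient_baseline.same_grid(template)
        and np.array_equal(patient_baseline.data, template.data)
    ):
        return JacobianMap(
            jac.data.copy(), template.spacing, template.origin,
            epsilon=jac.epsilon, n_clamped=jac.n_clamped,
        )

    config = config or RegistrationConfig()
    if deformable:
        field = register_deformable(template, patient_baseline, config=config)
    else:
        affine = register_affine(template, patient_baseline, config)
        grid = ImageVolume(np.zeros(template.shape), template.spacing, template.origin)
        X, Y, Z = grid.grid_coords()
        P = np.stack([X, Y, Z], axis=-1)
        field = DisplacementField(
            affine.apply_points(P) - P, template.spacing, template.origin
        )
    # pull-back resample with NaN marking voxels outside the patient's map
    idx = np.meshgrid(*[np.arange(n) for n in template.shape], indexing="ij")
    coords = [
        (template.origin[i] + idx[i] * template.spacing[i] + field.data[..., i]
         - jac.origin[i]) / jac.spacing[i]
        for i in range(3)
    ]
    data = map_coordinates(jac.data, coords, order=1, mode="constant", cval=np.nan)
    return JacobianMap(
        data,
        template.spacing,
        template.origin,
        epsilon=jac.epsilon,
        n_clamped=jac.n_clamped,
    )


def average_maps(maps: list[JacobianMap], label: str = "") -> GroupMap:
    """Voxel-wise mean over contributing (non-NaN) maps on a shared grid."""
    if not maps:
        raise ValueError("need at least one map to average")
    shape = maps[0].shape
    spacing = maps[0].spacing
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("maps must share the template grid")
    stack = np.stack([m.data for m in maps])
    valid = np.isfinite(stack)
    count = valid.sum(axis=0)
    # sort contributions before summing so the mean is bit-for-bit
    # independent of patient order
    total = np.sort(np.where(valid, stack, 0.0), axis=0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return GroupMap(mean, count, spacing, label=label, n=len(maps))


def render_sagittal(
    groupmap: GroupMap,
    path,
    slice_fraction: float = 0.5,
    color_limits: tuple[float, float] = (-0.3, 0.3),
    title: str | None = None,
) -> None:
    """Render one sagittal slice with a diverging scale centred at 0
    (blue = shrinkage, red = expansion) and a colour bar."""
    if not (0.0 <= slice_fraction <= 1.0):
        raise ValueError("slice_fraction must lie in [0, 1]")
    i = int(round(slice_fraction * (groupmap.data.shape[0] - 1)))
    sl = groupmap.data[i, :, :]
    # display with the craniocaudal axis vertical, apex up
    img = sl.T[::-1, :]
    lo, hi = color_limits
    vmax = max(abs(lo), abs(hi))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad(color="0.85")
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.ma.masked_invalid(img), cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or (groupmap.label and f"{groupmap.label} (n={groupmap.n})") or "")
    fig.colorbar(im, ax=ax, label="log Jacobian")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
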