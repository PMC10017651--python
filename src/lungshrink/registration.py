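"""Affine + deformable registration of follow-up to baseline scans.

The engine is a symmetric-forces, Gaussian-regularized demons scheme run
over a multi-resolution pyramid, preceded by a dense affine stage; it is
a deliberately simple, deterministic diffeomorphic-style registration
whose output — a dense displacement field u(x) in mm on the baseline
grid, pull-back convention — feeds the Jacobian analysis.  Fields from
external registration tools can be imported instead
(:func:`import_displacement_field`), so the downstream analysis is not
tied to this engine.

By default the returned field is the *composite* transform
T(x) = A(x + d(x)) (affine ∘ deformable), so a global volume change
captured by the affine stage is included in the Jacobian; set
``jacobian_source='deformable'`` to analyse the deformable residual only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Literal

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .core import (
    DisplacementField,
    ImageVolume,
    field_from_sitk,
    from_sitk,
    load_field,
    to_sitk,
)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Knobs of the affine + demons engine (all distances in mm)."""

    levels: int = 3
    iterations: tuple = (100, 60, 30)
    update_sigma_mm: float = 1.0  # fluid-like smoothing of each update
    total_sigma_mm: float = 1.5  # diffusion-like smoothing of the field
    metric: Literal["mse", "correlation"] = "mse"  # affine-stage similarity
    symmetric: bool = True
    do_affine: bool = True
    affine_iterations: int = 200
    jacobian_source: Literal["composite", "deformable"] = "composite"
    convergence_tol: float = 1e-6
    fill_value: float | None = None  # None -> min of the moving image

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.iterations) < self.levels:
            raise ValueError("need one iteration count per level")
        if self.update_sigma_mm < 0 or self.total_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")


@dataclass
class AffineResult:
    """12-parameter affine T(x) = M (x - c) + c + t (world mm)."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray
    final_metric: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-9:
            raise RegistrationError("affine registration produced a singular transform")

    @classmethod
    def identity(cls) -> "AffineResult":
        return cls(np.eye(3), np.zeros(3), np.zeros(3))

    @classmethod
    def from_sitk(cls, tx: sitk.AffineTransform, **kw) -> "AffineResult":
        return cls(
            np.array(tx.GetMatrix()).reshape(3, 3),
            np.array(tx.GetTranslation()),
            np.array(tx.GetCenter()),
            **kw,
        )

    def as_sitk(self) -> sitk.AffineTransform:
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(tuple(self.matrix.ravel()))
        tx.SetTranslation(tuple(self.translation))
        tx.SetCenter(tuple(self.center))
        return tx

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return (pts - self.center) @ self.matrix.T + self.center + self.translation

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))


@dataclass
class RegistrationInfo:
    affine: AffineResult | None
    level_metrics: list  # masked full-resolution MSE after each demons level
    initial_metric: float
    final_metric: float
    levels_reverted: list


# ---------------------------------------------------------------------------
# affine stage


def register_affine(
    fixed: ImageVolume, moving: ImageVolume, config: RegistrationConfig | None = None
) -> AffineResult:
    """Dense, deterministic affine alignment of moving to fixed."""
    config = config or RegistrationConfig()
    f_img, m_img = to_sitk(fixed), to_sitk(moving)

    tx = sitk.AffineTransform(3)
    center = np.asarray(fixed.origin) + 0.5 * np.asarray(fixed.shape) * np.asarray(
        fixed.spacing
    )
    tx.SetCenter(tuple(center))

    reg = sitk.ImageRegistrationMethod()
    if config.metric == "correlation":
        reg.SetMetricAsCorrelation()
    else:
        reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense, deterministic
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=config.affine_iterations,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=config.convergence_tol,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [4, 2, 1][-min(3, config.levels):]
    sigmas = [2.0, 1.0, 0.0][-min(3, config.levels):]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(tx, inPlace=True)

    metric_trace: list[float] = []
    reg.AddCommand(
        sitk.sitkIterationEvent, lambda: metric_trace.append(reg.GetMetricValue())
    )
    reg.Execute(f_img, m_img)

    converged = True
    if reg.GetOptimizerStopConditionDescription().startswith("RegularStepGradientDescent"):
        pass  # normal stop; description carries the reason either way
    if len(metric_trace) >= config.affine_iterations * len(shrink):
        converged = False
        warnings.warn(
            "affine registration hit the iteration cap; returning best-so-far",
            RuntimeWarning,
        )
    return AffineResult.from_sitk(
        tx, final_metric=float(reg.GetMetricValue()), converged=converged
    )


def apply_affine(
    moving: ImageVolume,
    affine: AffineResult,
    reference: ImageVolume,
    mode: str = "linear",
    fill: float | None = None,
) -> ImageVolume:
    """Resample moving through the affine onto the reference grid."""
    fill = float(np.min(moving.data)) if fill is None else float(fill)
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    out = sitk.Resample(
        to_sitk(moving), to_sitk(reference), affine.as_sitk(), interp, fill
    )
    return from_sitk(out)


# ---------------------------------------------------------------------------
# deformable stage


def _downsample(img: sitk.Image, shrink: int) -> sitk.Image:
    if shrink == 1:
        return img
    smoothed = sitk.SmoothingRecursiveGaussian(img, 0.5 * shrink * min(img.GetSpacing()))
    return sitk.Shrink(smoothed, [shrink] * 3)


def _masked_mse(fixed: np.ndarray, warped: np.ndarray, mask: np.ndarray | None) -> float:
    d = (fixed - warped) ** 2
    return float(d[mask].mean() if mask is not None else d.mean())


def register_deformable(
    fixed: ImageVolume,
    moving: ImageVolume,
    mask: np.ndarray | ImageVolume | None = None,
    config: RegistrationConfig | None = None,
    full_output: bool = False,
):
    """Affine + multiscale demons; returns the displacement field (mm,
    baseline grid, pull-back convention).

    With ``full_output=True`` also returns a :class:`RegistrationInfo`
    with the affine stage and the per-level masked-MSE log.  A pyramid
    level whose full-resolution masked MSE is worse than the previous
    level's is reverted, so the logged metric is non-increasing.
    """
    config = config or RegistrationConfig()
    if isinstance(mask, ImageVolume):
        mask = np.asarray(mask.data) > 0.5
    elif mask is not None:
        mask = np.asarray(mask) > 0.5

    affine = None
    moving_work = moving
    if config.do_affine:
        affine = register_affine(fixed, moving, config)
        moving_work = apply_affine(moving, affine, fixed, fill=config.fill_value)

    f_img = to_sitk(fixed)
    m_img = to_sitk(moving_work)

    demons = (
        sitk.FastSymmetricForcesDemonsRegistrationFilter()
        if config.symmetric
        else sitk.DemonsRegistrationFilter()
    )
    demons.SetSmoothDisplacementField(config.total_sigma_mm > 0)
    if config.total_sigma_mm > 0:
        demons.SetStandardDeviations(config.total_sigma_mm)
    demons.SetSmoothUpdateField(config.update_sigma_mm > 0)
    if config.update_sigma_mm > 0:
        demons.SetUpdateFieldStandardDeviations(config.update_sigma_mm)

    shrinks = [2 ** (config.levels - 1 - k) for k in range(config.levels)]
    init = _masked_mse(fixed.data, moving_work.data, mask)
    best_mse = init
    best_df = None
    level_metrics: list[float] = []
    reverted: list[int] = []
    df = None
    for lvl, shrink in enumerate(shrinks):
        f_l = _downsample(f_img, shrink)
        m_l = _downsample(m_img, shrink)
        if df is None:
            df = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64)
            df.CopyInformation(f_l)
        else:
            df = sitk.Resample(df, f_l, sitk.Transform(), sitk.sitkLinear)
        demons.SetNumberOfIterations(int(config.iterations[lvl]))
        df = demons.Execute(f_l, m_l, df)
        metric = demons.GetMetric()
        if not np.isfinite(metric):
            raise RegistrationError(
                f"demons metric diverged at level {lvl} (shrink {shrink}): {metric}"
            )
        # evaluate at full resolution for an honest, comparable log
        df_full = (
            df if shrink == 1 else sitk.Resample(df, f_img, sitk.Transform(), sitk.sitkLinear)
        )
        d_np = field_from_sitk(df_full)
        warped = warp_image(moving_work, d_np, fill=config.fill_value).data
        mse = _masked_mse(fixed.data, warped, mask)
        if mse <= best_mse:
            best_mse, best_df = mse, df
        else:
            reverted.append(lvl)
            df = best_df if best_df is not None else df
        level_metrics.append(best_mse)

    if best_df is None:  # no level improved on the affine alignment
        deform = DisplacementField.zeros(fixed.shape, fixed.spacing, fixed.origin)
    else:
        df_full = sitk.Resample(best_df, f_img, sitk.Transform(), sitk.sitkLinear)
        deform = field_from_sitk(df_full)

    if affine is not None and config.jacobian_source == "composite":
        out = compose_affine_deformable(affine, deform)
    else:
        out = deform

    if full_output:
        info = RegistrationInfo(
            affine=affine,
            level_metrics=level_metrics,
            initial_metric=init,
            final_metric=best_mse,
            levels_reverted=reverted,
        )
        return out, info
    return out


def compose_affine_deformable(
    affine: AffineResult, deform: DisplacementField
) -> DisplacementField:
    """Dense field of T(x) = A(x + d(x)): u(x) = A(x + d(x)) - x."""
    grid = ImageVolume(np.zeros(deform.shape), deform.spacing, deform.origin)
    X, Y, Z = grid.grid_coords()
    P = np.stack([X, Y, Z], axis=-1) + deform.data
    Q = affine.apply_points(P)
    U = Q - np.stack([X, Y, Z], axis=-1)
    return DisplacementField(U, deform.spacing, deform.origin)


# ---------------------------------------------------------------------------
# warping and field import


def warp_image(
    moving: ImageVolume,
    field: DisplacementField,
    mode: str = "linear",
    fill: float | None = None,
) -> ImageVolume:
    """Pull-back warp: output(x) = moving(x + u(x)) by interpolation."""
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    fill = float(np.min(moving.data)) if fill is None else float(fill)
    sp_f = np.asarray(field.spacing)
    sp_m = np.asarray(moving.spacing)
    idx = np.meshgrid(*[np.arange(n) for n in field.shape], indexing="ij")
    coords = [
        (np.asarray(field.origin[i]) + idx[i] * sp_f[i] + field.data[..., i]
         - moving.origin[i]) / sp_m[i]
        for i in range(3)
    ]
    out = map_coordinates(
        np.asarray(moving.data, dtype=float),
        coords,
        order=1 if mode == "linear" else 0,
        mode="constant",
        cval=fill,
    )
    return ImageVolume(out, field.spacing, field.origin)


def import_displacement_field(
    path, expected_grid: ImageVolume, units: Literal["mm", "voxel"] = "mm"
) -> DisplacementField:
    """Load an externally computed field (4-D NIfTI, vector in last dim).

    The field must live on the baseline grid in the pull-back convention
    (u maps baseline to follow-up coordinates).  ``units='voxel'`` fields
    are converted to mm with the header spacing.
    """
    f = load_field(path)
    if f.shape != expected_grid.shape:
        raise ValueError(
            f"field grid {f.shape} does not match the expected baseline grid "
            f"{expected_grid.shape}"
        )
    if not np.allclose(f.spacing, expected_grid.spacing, atol=1e-3):
        raise ValueError(
            f"field spacing {f.spacing} does not match the baseline spacing "
            f"{expected_grid.spacing}"
        )
    if units == "voxel":
        warnings.warn("converting voxel-unit field to mm using header spacing")
        f = DisplacementField(
            f.data * np.asarray(f.spacing)[None, None, None, :], f.spacing, f.origin
        )
    return f


def roundtrip_residual(
    forward: DisplacementField, inverse_warp, mask: np.ndarray | None = None
) -> float:
    """Mean |T_inv(T(x)) - x| in mm, a convention sanity metric.

    ``inverse_warp`` maps points (X, Y, Z arrays) back to baseline space
    (e.g. a phantom's analytic inverse).
    """
    grid = ImageVolume(np.zeros(forward.shape), forward.spacing, forward.origin)
    X, Y, Z = grid.grid_coords()
    Xf = X + forward.data[..., 0]
    Yf = Y + forward.data[..., 1]
    Zf = Z + forward.data[..., 2]
    Xb, Yb, Zb = inverse_warp(Xf, Yf, Zf)
    res = np.sqrt((Xb - X) ** 2 + (Yb - Y) ** 2 + (Zb - Z) ** 2)
    return float(res[mask].mean() if mask is not None else res.mean())
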