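"""Synthetic longitudinal chest-CT phantoms with analytically known deformation.

The generator emulates the structure of a fibrosis follow-up cohort:
paired baseline/follow-up volumes whose true deformation field is known in
closed form (hence exact ground-truth log-Jacobian maps), embedded vessel
trees of known topology, and pulmonary-function records whose decline is
rank-coupled to the true volume loss.  Every downstream stage —
resampling, registration, Jacobian analysis, vessel metrics, cohort
statistics — is validated against these ground truths.

Warp family
-----------
The deforming scenarios use an axial contraction toward a centre c with a
craniocaudally varying amplitude,

    u(x) = -alpha(z) * (x - c),      alpha(z) = A * t(z)**g,

where t(z) = (z_top - z) / L runs from 0 at the top of the grid to 1 at
the bottom, A is the peak fractional linear contraction and g >= 0 the
basal-gradient exponent (g = 0: uniform isotropic contraction by factor
s = 1 - A).  The Jacobian matrix of T(x) = x + u(x) is upper triangular,
so its determinant is available in closed form:

    det = (1 - alpha)^2 * (1 - alpha - alpha'(z) * (z - c_z)).

Shrinkage (A > 0) gives det < 1 and log-Jacobian < 0, strongest at the
lung base; expansion (A < 0) gives the opposite sign.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import (
    CRANIOCAUDAL_AXIS,
    DisplacementField,
    ImageVolume,
    JacobianMap,
    save_field,
    save_mask,
    save_volume,
)

HU_AIR = -1000.0
HU_LUNG = -800.0
HU_BODY = 40.0
HU_VESSEL = -300.0

Scenario = Literal["deteriorate", "stable", "improve"]


class FoldingWarpError(ValueError):
    """Raised when a requested warp folds (det <= threshold) inside the mask."""


# ---------------------------------------------------------------------------
# analytic warps


class Warp:
    """Base class: a parametric transform T(x) = x + u(x) with closed-form
    displacement and log-Jacobian."""

    def displacement(self, X, Y, Z):
        raise NotImplementedError

    def logjac(self, X, Y, Z):
        return np.log(self.jacobian_det(X, Y, Z))

    def jacobian_det(self, X, Y, Z):
        raise NotImplementedError

    def inverse_points(self, X, Y, Z):
        """Map follow-up coordinates back to baseline coordinates T^-1(y)."""
        raise NotImplementedError


class IdentityWarp(Warp):
    def displacement(self, X, Y, Z):
        zeros = np.zeros_like(X)
        return zeros, zeros.copy(), zeros.copy()

    def jacobian_det(self, X, Y, Z):
        return np.ones_like(X)

    def inverse_points(self, X, Y, Z):
        return X, Y, Z


@dataclass
class AffineWarp(Warp):
    """T(x) = c + A (x - c); u = (A - I)(x - c)."""

    matrix: np.ndarray  # 3x3
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine warp matrix is singular")

    def displacement(self, X, Y, Z):
        c = self.center
        d = self.matrix - np.eye(3)
        dx = d[0, 0] * (X - c[0]) + d[0, 1] * (Y - c[1]) + d[0, 2] * (Z - c[2])
        dy = d[1, 0] * (X - c[0]) + d[1, 1] * (Y - c[1]) + d[1, 2] * (Z - c[2])
        dz = d[2, 0] * (X - c[0]) + d[2, 1] * (Y - c[1]) + d[2, 2] * (Z - c[2])
        return dx, dy, dz

    def jacobian_det(self, X, Y, Z):
        return np.full_like(np.asarray(X, dtype=float), np.linalg.det(self.matrix))

    def inverse_points(self, X, Y, Z):
        c = np.asarray(self.center)
        inv = np.linalg.inv(self.matrix)
        P = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=-1)
        Q = P @ inv.T
        return Q[..., 0] + c[0], Q[..., 1] + c[1], Q[..., 2] + c[2]


@dataclass
class AxialContractionWarp(Warp):
    """Contraction toward ``center`` whose amplitude grows toward the base.

    The craniocaudal weight is w(z) = ((z_top - z) / (z_top - z_base))**g,
    normalized to 1 at ``z_base`` (the lung base) and decaying toward
    ``z_top``, which sits *above* the imaged grid so the weight and its
    derivative stay smooth and finite everywhere, including fractional
    exponents.  amplitude > 0 shrinks, < 0 expands; gradient = 0 is
    spatially uniform.
    """

    center: tuple[float, float, float]
    amplitude: float
    gradient: float = 0.0
    z_top: float = 1.3  # reference height of zero weight, above the grid
    z_base: float = 0.0  # world z where the weight is 1
    z_max: float | None = None  # top of the imaged region (defaults to z_top)

    def _t(self, Z):
        scale = self.z_top - self.z_base
        return np.clip((self.z_top - np.asarray(Z, dtype=float)) / scale, 1e-9, None)

    def _alpha(self, Z):
        return self.amplitude * self._t(Z) ** self.gradient

    def _alpha_prime(self, Z):
        if self.gradient == 0:
            return np.zeros_like(np.asarray(Z, dtype=float))
        t = self._t(Z)
        return (
            -self.amplitude
            * self.gradient
            * t ** (self.gradient - 1.0)
            / (self.z_top - self.z_base)
        )

    def displacement(self, X, Y, Z):
        a = self._alpha(Z)
        c = self.center
        return -a * (X - c[0]), -a * (Y - c[1]), -a * (Z - c[2])

    def jacobian_det(self, X, Y, Z):
        a = self._alpha(Z)
        ap = self._alpha_prime(Z)
        return (1.0 - a) ** 2 * (1.0 - a - ap * (np.asarray(Z, dtype=float) - self.center[2]))

    def inverse_points(self, X, Y, Z):
        cz = self.center[2]
        # table over the imaged region plus a margin, staying clear of
        # z_top where fractional-exponent weights lose smoothness
        hi = self.z_max if self.z_max is not None else self.z_top
        span = hi - self.z_base
        zg = np.linspace(
            self.z_base - 0.3 * span, min(hi + 0.2 * span, self.z_top - 1e-6), 4096
        )
        phi = cz + (1.0 - self._alpha(zg)) * (zg - cz)
        if np.any(np.diff(phi) <= 0):
            raise FoldingWarpError("axial warp is not invertible along z")
        z_back = np.interp(Z, phi, zg)
        a = self._alpha(z_back)
        scale = 1.0 - a
        return (
            self.center[0] + (X - self.center[0]) / scale,
            self.center[1] + (Y - self.center[1]) / scale,
            z_back,
        )


@dataclass
class RadialWarp(Warp):
    """Gaussian-envelope radial push toward/away from a centre.

    u(x) = -a * exp(-r^2 / (2 sigma^2)) * (x - c).  For u = f(r^2)(x - c)
    the Jacobian is f I + 2 f' (x-c)(x-c)^T + I with determinant
    (1 + f)^2 (1 + f + 2 f' r^2) by the matrix determinant lemma.
    """

    center: tuple[float, float, float]
    amplitude: float
    sigma: float

    def _f(self, r2):
        return -self.amplitude * np.exp(-r2 / (2.0 * self.sigma**2))

    def displacement(self, X, Y, Z):
        c = self.center
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        f = self._f(r2)
        return f * (X - c[0]), f * (Y - c[1]), f * (Z - c[2])

    def jacobian_det(self, X, Y, Z):
        c = self.center
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        f = self._f(r2)
        fp = -f / (2.0 * self.sigma**2)  # d f / d(r^2)
        return (1.0 + f) ** 2 * (1.0 + f + 2.0 * fp * r2)


def analytic_logjac(warp: Warp, grid: ImageVolume) -> JacobianMap:
    """Closed-form log-Jacobian of a parametric warp evaluated on a grid."""
    X, Y, Z = grid.grid_coords()
    det = warp.jacobian_det(X, Y, Z)
    if np.any(det <= 0):
        raise FoldingWarpError(
            f"warp parameters are non-invertible: min det = {det.min():.4g}"
        )
    return JacobianMap(np.log(det), grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# phantom anatomy


@dataclass
class LungGeometry:
    """Two ellipsoidal lungs inside an ellipsoidal body, all in mm."""

    body_center: tuple[float, float, float]
    body_half_axes: tuple[float, float, float]
    lung_centers: tuple[tuple[float, float, float], tuple[float, float, float]]
    lung_half_axes: tuple[float, float, float]

    @classmethod
    def default_for(cls, grid_shape, spacing_mm) -> "LungGeometry":
        extent = np.array(grid_shape) * np.array(spacing_mm)
        # half-voxel offset keeps ellipsoid equators off lattice planes,
        # where inclusive rasterization would bias the mask volume
        c = extent / 2.0 + 0.5 * np.array(spacing_mm)
        body = (0.44 * extent[0], 0.38 * extent[1], 0.47 * extent[2])
        lung_half = (0.155 * extent[0], 0.24 * extent[1], 0.34 * extent[2])
        lungs = (
            (c[0] - 0.21 * extent[0], c[1], c[2] + 0.03 * extent[2]),
            (c[0] + 0.21 * extent[0], c[1], c[2] + 0.03 * extent[2]),
        )
        return cls(tuple(c), body, lungs, lung_half)


def _ellipsoid(X, Y, Z, center, half_axes) -> np.ndarray:
    return (
        ((X - center[0]) / half_axes[0]) ** 2
        + ((Y - center[1]) / half_axes[1]) ** 2
        + ((Z - center[2]) / half_axes[2]) ** 2
    ) <= 1.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic longitudinal scan pair."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_geometry: LungGeometry | None = None
    shrink_amplitude: float = 0.05  # peak fractional linear contraction
    basal_gradient: float = 0.0  # 0 = spatially uniform
    noise_sd: float = 8.0  # HU, additive
    seed: int = 0
    scenario: Scenario = "deteriorate"
    texture_sd: float = 60.0  # HU, parenchymal texture contrast
    vessel_depth: int = 3  # 0 disables embedded vessel trees

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >= 16 voxels, got {self.grid_shape}")
        self.spacing_mm = tuple(float(s) for s in np.broadcast_to(self.spacing_mm, (3,)))
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not (0.0 <= self.shrink_amplitude < 0.5):
            raise ValueError("shrink_amplitude must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.basal_gradient < 0:
            raise ValueError("basal_gradient must be >= 0")
        if self.scenario not in ("deteriorate", "stable", "improve"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.lung_geometry is None:
            self.lung_geometry = LungGeometry.default_for(self.grid_shape, self.spacing_mm)


@dataclass
class GroundTruth:
    """Everything the generator knows exactly about one phantom pair."""

    displacement: DisplacementField
    logjac_true: JacobianMap
    lung_volume_change_ml: float
    vessel_branch_count_true: int
    warp: Warp
    vessel_mask: np.ndarray | None = None
    followup_lung_mask: np.ndarray | None = None


def make_warp(spec: PhantomSpec) -> Warp:
    if spec.scenario == "stable":
        return IdentityWarp()
    sign = 1.0 if spec.scenario == "deteriorate" else -1.0
    extent = np.array(spec.grid_shape) * np.array(spec.spacing_mm)
    geom = spec.lung_geometry
    center = tuple(np.mean(np.asarray(geom.lung_centers), axis=0))
    return AxialContractionWarp(
        center=center,
        amplitude=sign * spec.shrink_amplitude,
        gradient=spec.basal_gradient,
        z_top=1.3 * float(extent[2]),
        z_base=0.0,
        z_max=float(extent[2]),
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, GroundTruth]:
    """Generate a (baseline, follow-up, lung mask, ground truth) quadruple.

    The follow-up volume is the baseline anatomy observed through the
    analytic warp (pull-back resampling of the inverse transform), plus
    independent additive noise on each time point.
    """
    rng = np.random.default_rng(spec.seed)
    grid = ImageVolume(np.zeros(spec.grid_shape), spec.spacing_mm)
    X, Y, Z = grid.grid_coords()
    geom = spec.lung_geometry

    body = _ellipsoid(X, Y, Z, geom.body_center, geom.body_half_axes)
    lung = np.zeros(spec.grid_shape, dtype=bool)
    for c in geom.lung_centers:
        lung |= _ellipsoid(X, Y, Z, c, geom.lung_half_axes)
    lung &= body

    baseline = np.full(spec.grid_shape, HU_AIR)
    baseline[body] = HU_BODY
    baseline[lung] = HU_LUNG

    # fixed parenchymal texture so registration has features to lock onto
    if spec.texture_sd > 0:
        tex = gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=2.5)
        tex *= spec.texture_sd / max(tex.std(), 1e-9)
        baseline[lung] += tex[lung]

    vessel_mask = None
    branch_truth = 0
    if spec.vessel_depth >= 1:
        vessel_mask = np.zeros(spec.grid_shape, dtype=bool)
        for c in geom.lung_centers:
            tree, n_seg, _ = generate_vessel_tree(
                seed=int(rng.integers(2**31)),
                depth=spec.vessel_depth,
                spacing_mm=spec.spacing_mm,
                grid_shape=spec.grid_shape,
                root_mm=(c[0], c[1], c[2] + 0.75 * geom.lung_half_axes[2]),
                direction=(0.0, 0.0, -1.0),
                segment_length_mm=0.55 * geom.lung_half_axes[2],
                radius_mm=2.2 * max(spec.spacing_mm),
            )
            vessel_mask |= tree
            branch_truth += n_seg
        vessel_mask &= lung
        baseline[vessel_mask] = HU_VESSEL

    warp = make_warp(spec)
    ux, uy, uz = warp.displacement(X, Y, Z)
    field = DisplacementField(np.stack([ux, uy, uz], axis=-1), spec.spacing_mm)

    det = warp.jacobian_det(X, Y, Z)
    if np.any(det[lung] <= 0.05):
        raise FoldingWarpError(
            "warp folds inside the lung mask "
            f"(min det = {det[lung].min():.4f} <= 0.05); reduce shrink_amplitude"
        )
    if np.any(det <= 0.01):
        raise FoldingWarpError(f"warp folds inside the grid (min det = {det.min():.4f})")
    logjac = JacobianMap(np.log(det), spec.spacing_mm)

    if isinstance(warp, IdentityWarp):
        followup = baseline.copy()
        followup_lung = lung.copy()
    else:
        Xb, Yb, Zb = warp.inverse_points(X, Y, Z)
        coords = np.stack(
            [Xb / spec.spacing_mm[0], Yb / spec.spacing_mm[1], Zb / spec.spacing_mm[2]]
        )
        followup = map_coordinates(baseline, coords, order=1, mode="constant", cval=HU_AIR)
        # follow-up mask from the analytic geometry at the pulled-back points
        # (re-rasterizing the voxelized baseline mask would alias against it)
        f_body = _ellipsoid(Xb, Yb, Zb, geom.body_center, geom.body_half_axes)
        followup_lung = np.zeros(spec.grid_shape, dtype=bool)
        for c in geom.lung_centers:
            followup_lung |= _ellipsoid(Xb, Yb, Zb, c, geom.lung_half_axes)
        followup_lung &= f_body

    if spec.noise_sd > 0:
        baseline = baseline + spec.noise_sd * rng.standard_normal(spec.grid_shape)
        followup = followup + spec.noise_sd * rng.standard_normal(spec.grid_shape)

    voxvol = float(np.prod(spec.spacing_mm))
    dvol_ml = float(np.sum(det[lung] - 1.0) * voxvol / 1000.0)

    truth = GroundTruth(
        displacement=field,
        logjac_true=logjac,
        lung_volume_change_ml=dvol_ml,
        vessel_branch_count_true=branch_truth,
        warp=warp,
        vessel_mask=vessel_mask,
        followup_lung_mask=followup_lung,
    )
    base_vol = ImageVolume(baseline, spec.spacing_mm)
    follow_vol = ImageVolume(np.asarray(followup, dtype=float), spec.spacing_mm)
    mask_vol = ImageVolume(lung, spec.spacing_mm)
    return base_vol, follow_vol, mask_vol, truth


# ---------------------------------------------------------------------------
# vessel trees


def generate_vessel_tree(
    seed: int = 0,
    depth: int = 3,
    spacing_mm: Sequence[float] = (1.0, 1.0, 1.0),
    grid_shape: tuple[int, int, int] | None = None,
    root_mm: tuple[float, float, float] | None = None,
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0),
    segment_length_mm: float = 18.0,
    radius_mm: float = 2.0,
    branch_angle_deg: float = 38.0,
    length_decay: float = 0.75,
    radius_decay: float = 0.8,
) -> tuple[np.ndarray, int, float]:
    """Rasterize a symmetric bifurcating tube tree of ``depth`` generations.

    Returns (binary mask, true segment count, analytic volume in mL).  A
    depth-1 tree is a single straight tube; a symmetric tree of depth d
    has 2**d - 1 segments.  The analytic volume sums the cylinder volumes
    pi r^2 L of all segments (joint overlap is ignored, which is within
    the voxelization tolerance for the default geometry).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    if grid_shape is None:
        n = int(np.ceil((depth + 1) * segment_length_mm / spacing.min())) + 16
        grid_shape = (n, n, n)
    if root_mm is None:
        ext = np.array(grid_shape) * spacing
        root_mm = (ext[0] / 2, ext[1] / 2, ext[2] - 4 * spacing[2])

    rng = np.random.default_rng(seed)
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []

    def grow(p0, direc, length, radius, level):
        direc = direc / np.linalg.norm(direc)
        p1 = p0 + direc * length
        segments.append((p0, p1, radius))
        if level + 1 >= depth:
            return
        # split in a plane whose normal alternates with the generation
        axis = np.array([1.0, 0.0, 0.0]) if level % 2 == 0 else np.array([0.0, 1.0, 0.0])
        if abs(np.dot(axis, direc)) > 0.9:
            axis = np.array([0.0, 0.0, 1.0])
        side = np.cross(direc, axis)
        side /= np.linalg.norm(side)
        ang = np.deg2rad(branch_angle_deg)
        for s in (+1.0, -1.0):
            child = np.cos(ang) * direc + s * np.sin(ang) * side
            grow(p1, child, length * length_decay, radius * radius_decay, level + 1)

    grow(np.asarray(root_mm, dtype=float), np.asarray(direction, dtype=float),
         segment_length_mm, radius_mm, 0)

    mask = np.zeros(grid_shape, dtype=bool)
    for p0, p1, radius in segments:
        _rasterize_capsule(mask, spacing, p0, p1, radius)

    volume_ml = sum(np.pi * r**2 * np.linalg.norm(p1 - p0) for p0, p1, r in segments) / 1000.0
    return mask, len(segments), float(volume_ml)


def _rasterize_capsule(mask, spacing, p0, p1, radius):
    """Mark voxels inside the flat-ended cylinder around segment p0-p1
    (world mm), so the segment's volume is pi r^2 L up to voxelization."""
    lo = np.minimum(p0, p1) - radius - spacing
    hi = np.maximum(p0, p1) + radius + spacing
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, mask.shape)
    if np.any(i0 >= i1):
        return
    axes = [spacing[k] * np.arange(i0[k], i1[k]) for k in range(3)]
    Xs, Ys, Zs = np.meshgrid(*axes, indexing="ij")
    P = np.stack([Xs, Ys, Zs], axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    t = ((P - p0) @ d) / max(L2, 1e-12)
    closest = p0 + np.clip(t, 0.0, 1.0)[..., None] * d
    dist2 = np.sum((P - closest) ** 2, axis=-1)
    sub = mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    sub |= (dist2 <= radius**2) & (t >= 0.0) & (t <= 1.0)


# ---------------------------------------------------------------------------
# synthetic pulmonary-function cohorts


def coupling_for_spearman(rho: float) -> float:
    """Gaussian-copula correlation that yields a target Spearman rho."""
    return float(2.0 * np.sin(np.pi * rho / 6.0))


def generate_pft_cohort(
    n: int = 69,
    seed: int = 0,
    coupling: float = 0.5,
    fvc_change_scale: float = 8.0,
    dlco_change_scale: float = 10.0,
) -> pd.DataFrame:
    """Simulate a cohort of percent-predicted lung-function records whose
    FVC%/VC% declines are rank-coupled to each patient's true mean
    log-Jacobian.

    ``coupling`` is the correlation of the underlying Gaussian copula
    (1 = perfectly monotone link, 0 = independent); the implied Spearman
    correlation is 6/pi * asin(coupling/2).  DLco% decline is drawn
    independently.  Baseline distributions roughly follow an IPF clinic
    population (median FVC% near 89, DLco% near 51).
    """
    if n < 8:
        raise ValueError("n must be >= 8")
    if not (0.0 <= abs(coupling) <= 1.0):
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)

    z_shrink = rng.standard_normal(n)
    eps_f = rng.standard_normal(n)
    eps_v = rng.standard_normal(n)
    mix_f = coupling * z_shrink + np.sqrt(1.0 - coupling**2) * eps_f
    mix_v = coupling * z_shrink + np.sqrt(1.0 - coupling**2) * eps_v

    # monotone map from the latent severity to a mean log-Jacobian with a
    # stable cluster near 0 and a negative deteriorating tail
    mean_logjac = -0.12 * np.exp(-0.9 * z_shrink) + 0.02 * z_shrink + 0.08

    d_fvc = -4.6 + fvc_change_scale * mix_f
    d_vc = -3.5 + fvc_change_scale * mix_v
    d_tlc = -3.3 + 6.0 * rng.standard_normal(n)
    d_dlco = -4.5 + dlco_change_scale * rng.standard_normal(n)

    fvc0 = np.clip(88.8 + 18.0 * rng.standard_normal(n), 25.0, 140.0)
    vc0 = np.clip(85.6 + 17.0 * rng.standard_normal(n), 25.0, 140.0)
    tlc0 = np.clip(71.3 + 13.0 * rng.standard_normal(n), 25.0, 130.0)
    dlco0 = np.clip(51.4 + 18.0 * rng.standard_normal(n), 10.0, 120.0)

    interval = np.exp(np.log(13.1) + 0.6 * rng.standard_normal(n))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "vc_pct_base": vc0,
            "vc_pct_follow": np.clip(vc0 + d_vc, 5.0, None),
            "fvc_pct_base": fvc0,
            "fvc_pct_follow": np.clip(fvc0 + d_fvc, 5.0, None),
            "tlc_pct_base": tlc0,
            "tlc_pct_follow": np.clip(tlc0 + d_tlc, 5.0, None),
            "dlco_pct_base": dlco0,
            "dlco_pct_follow": np.clip(dlco0 + d_dlco, 2.0, None),
            "interval_months": interval,
            "true_mean_logjac": mean_logjac,
        }
    )


# ---------------------------------------------------------------------------
# cohort writer


def write_phantom_cohort(
    outdir,
    n_per_group: dict[str, int] | None = None,
    seed: int = 0,
    grid_shape=(48, 48, 48),
    spacing_mm=(1.0, 1.0, 1.0),
    noise_sd: float = 8.0,
    basal_gradient: float = 1.5,
    write_truth_fields: bool = True,
) -> Path:
    """Write a phantom cohort to disk (NIfTI + PFT CSV + JSON manifest).

    Returns the manifest path.  Each patient entry records its scenario,
    file paths and ground-truth values, so the full pipeline can run on it
    with either imported truth fields or de-novo registration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if n_per_group is None:
        n_per_group = {"deteriorate": 3, "stable": 3, "improve": 2}

    rng = np.random.default_rng(seed)
    patients = []
    pft_rows = []
    morph_label = {"deteriorate": "worsen", "stable": "stable", "improve": "improve"}

    idx = 0
    for scenario, count in n_per_group.items():
        for _ in range(count):
            pid = f"PH{idx:03d}"
            if scenario == "stable":
                amp, grad = 0.0, 0.0
            else:
                amp = float(rng.uniform(0.03, 0.08))
                grad = basal_gradient
            spec = PhantomSpec(
                grid_shape=grid_shape,
                spacing_mm=spacing_mm,
                shrink_amplitude=amp,
                basal_gradient=grad,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
                scenario=scenario,
            )
            base, follow, mask, truth = generate_phantom(spec)
            pdir = outdir / pid
            pdir.mkdir(exist_ok=True)
            save_volume(base, pdir / "baseline.nii.gz")
            save_volume(follow, pdir / "followup.nii.gz")
            save_mask(mask.data, base, pdir / "lung_mask.nii.gz")
            entry = {
                "id": pid,
                "baseline": str(pdir / "baseline.nii.gz"),
                "followup": str(pdir / "followup.nii.gz"),
                "lung_mask": str(pdir / "lung_mask.nii.gz"),
                "morphology": morph_label[scenario],
                "scenario": scenario,
                "true_mean_logjac": float(truth.logjac_true.data[mask.data].mean()),
                "true_lung_volume_change_ml": truth.lung_volume_change_ml,
            }
            if truth.vessel_mask is not None:
                save_mask(truth.vessel_mask, base, pdir / "vessels_baseline.nii.gz")
                entry["vessel_mask_baseline"] = str(pdir / "vessels_baseline.nii.gz")
                entry["true_branch_count"] = truth.vessel_branch_count_true
            if write_truth_fields:
                save_field(truth.displacement, pdir / "field.nii.gz")
                entry["field"] = str(pdir / "field.nii.gz")
            patients.append(entry)

            # lung-function record consistent with the scenario
            mean_lj = entry["true_mean_logjac"]
            d_fvc = 250.0 * mean_lj + rng.normal(0, 2.0)
            d_dlco = 280.0 * mean_lj + rng.normal(0, 3.0)
            fvc0 = float(np.clip(rng.normal(88.8, 15.0), 30, 130))
            dlco0 = float(np.clip(rng.normal(51.4, 15.0), 15, 110))
            pft_rows.append(
                {
                    "patient_id": pid,
                    "vc_pct_base": fvc0 - 3.0,
                    "vc_pct_follow": fvc0 - 3.0 + d_fvc,
                    "fvc_pct_base": fvc0,
                    "fvc_pct_follow": max(fvc0 + d_fvc, 5.0),
                    "tlc_pct_base": float(np.clip(rng.normal(71.3, 12.0), 30, 120)),
                    "tlc_pct_follow": float(np.clip(rng.normal(68.0, 12.0), 25, 120)),
                    "dlco_pct_base": dlco0,
                    "dlco_pct_follow": max(dlco0 + d_dlco, 2.0),
                    "interval_months": float(np.exp(np.log(13.1) + 0.5 * rng.standard_normal())),
                }
            )
            idx += 1

    pft_path = outdir / "pft.csv"
    pd.DataFrame(pft_rows).to_csv(pft_path, index=False)
    manifest = {
        "seed": seed,
        "grid_shape": list(grid_shape),
        "spacing_mm": list(np.broadcast_to(spacing_mm, (3,)).astype(float)),
        "pft_csv": str(pft_path),
        "patients": patients,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
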