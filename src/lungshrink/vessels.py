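"""Vessel-mask metrics: volume, skeletonization and branch counting.

Operates on binary vessel masks (all-vessel, artery or vein — whatever
segmentation is supplied upstream).  The mask is reduced to a
one-voxel-wide, topology-preserving medial skeleton; skeleton voxels are
classified by their 26-neighbourhood degree (endpoint = 1, regular = 2,
branch point >= 3), and a *branch* is a maximal chain of degree-<=2
voxels running between terminals (endpoints or branch-point clusters).
An isolated loop counts as one branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

_STRUCT26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class VesselMetrics:
    vessel_volume_ml: float
    branch_count: int
    branch_point_count: int
    endpoint_count: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def skeletonize_mask(vessel_mask: np.ndarray) -> np.ndarray:
    """1-voxel-wide medial skeleton; an empty mask gives an empty skeleton."""
    vessel_mask = np.asarray(vessel_mask) > 0.5
    if not vessel_mask.any():
        return np.zeros_like(vessel_mask)
    return skeletonize(vessel_mask).astype(bool)


def _neighbor_degree(skel: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(skel.astype(np.uint8), _STRUCT26, mode="constant")
    return np.where(skel, counts - 1, 0)


def count_branches(skeleton: np.ndarray, min_branch_voxels: int = 0) -> VesselMetrics:
    """Topological metrics of a skeleton (volume field left at 0).

    ``min_branch_voxels`` optionally prunes endpoint-terminated chains
    shorter than that many voxels (skeletonization spurs) before counting.
    """
    skel = np.asarray(skeleton) > 0.5
    if not skel.any():
        return VesselMetrics(0.0, 0, 0, 0)
    if min_branch_voxels > 0:
        skel = prune_spurs(skel, min_branch_voxels)

    deg = _neighbor_degree(skel)
    endpoints = deg == 1
    junction = deg >= 3

    # adjacent junction voxels act as a single branch point
    _, n_junction_clusters = ndimage.label(junction, structure=_STRUCT26)
    chains = skel & ~junction
    _, n_chains = ndimage.label(chains, structure=_STRUCT26)

    return VesselMetrics(
        vessel_volume_ml=0.0,
        branch_count=int(n_chains),
        branch_point_count=int(n_junction_clusters),
        endpoint_count=int(endpoints.sum()),
    )


def prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove endpoint-terminated chains shorter than ``min_len`` voxels."""
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        deg = _neighbor_degree(skel)
        junction = deg >= 3
        chains = skel & ~junction
        labels, n = ndimage.label(chains, structure=_STRUCT26)
        for lab in range(1, n + 1):
            comp = labels == lab
            size = int(comp.sum())
            if size >= min_len:
                continue
            # a spur touches at least one endpoint and at least one junction
            if (deg[comp] == 1).any() and ndimage.binary_dilation(
                comp, structure=_STRUCT26
            )[junction].any():
                skel[comp] = False
                changed = True
    return skel


def vessel_volume(vessel_mask: np.ndarray, spacing_mm) -> float:
    """Mask volume in mL (voxel count x voxel volume)."""
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    n = int((np.asarray(vessel_mask) > 0.5).sum())
    return float(n * np.prod(spacing) / 1000.0)


def vessel_metrics(
    vessel_mask: np.ndarray, spacing_mm, min_branch_voxels: int = 0
) -> VesselMetrics:
    """Volume + skeleton topology metrics in one call."""
    skel = skeletonize_mask(vessel_mask)
    m = count_branches(skel, min_branch_voxels)
    m.vessel_volume_ml = vessel_volume(vessel_mask, spacing_mm)
    return m


@dataclass
class VesselDeltas:
    vessel_volume_ml: float
    branch_count: int
    branch_point_count: int
    endpoint_count: int


def vessel_deltas(baseline: VesselMetrics, followup: VesselMetrics) -> VesselDeltas:
    """Signed follow-up minus baseline changes."""
    return VesselDeltas(
        vessel_volume_ml=followup.vessel_volume_ml - baseline.vessel_volume_ml,
        branch_count=followup.branch_count - baseline.branch_count,
        branch_point_count=followup.branch_point_count - baseline.branch_point_count,
        endpoint_count=followup.endpoint_count - baseline.endpoint_count,
    )
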