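"""ROI masks: spheres at MNI mm coordinates on a voxel grid, and unions.

The a priori regions of the decoding analysis that are not taken from an
anatomical atlas are geometric spheres in MNI space (RAS+ mm): the ventral
striatum (12 mm radius at x = +/-12, y = 10, z = -6), the ventromedial
prefrontal cortex (8 mm at (0, 46, -7)), and the small substantia nigra /
ventral tegmental area spheres (3 mm) whose union with the VS forms the
mesolimbic composite ROI.  A voxel belongs to a sphere iff the Euclidean
distance from its centre (mapped through the grid affine) to the sphere
centre is <= the radius (inclusive boundary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from nibabel.affines import apply_affine

__all__ = [
    "SphereSpec",
    "sphere_mask",
    "union_masks",
    "default_roi_specs",
    "build_sphere_rois",
    "default_affine",
]


@dataclass(frozen=True)
class SphereSpec:
    """A sphere in scanner mm space (RAS+)."""

    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius_mm) or self.radius_mm < 0:
            raise ValueError("radius_mm must be finite and >= 0")
        if not np.all(np.isfinite(self.center_mm)):
            raise ValueError("center_mm must be finite")


def default_affine(shape: tuple[int, int, int], voxel_mm: float = 2.0) -> np.ndarray:
    """A centred isotropic RAS+ affine for a synthetic grid."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def sphere_mask(
    spec: SphereSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Binary mask of voxels whose centre lies within the sphere.

    Raises if the sphere covers no voxel (entirely off-grid).
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    vox = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = apply_affine(affine, vox)
    d2 = np.sum((mm - np.asarray(spec.center_mm)) ** 2, axis=1)
    mask = (d2 <= spec.radius_mm**2 + 1e-9).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"sphere at {spec.center_mm} (r = {spec.radius_mm} mm) contains no voxel "
            "of the grid"
        )
    return mask


def union_masks(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise logical OR of binary masks on identical grids."""
    if not masks:
        raise ValueError("no masks to union")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError(f"grid mismatch: {m.shape} vs {out.shape}")
        out = out | m
    return out


def default_roi_specs() -> dict[str, list[SphereSpec]]:
    """Published sphere definitions of the non-atlas ROIs (MNI mm).

    ``mesolimbic`` is the union of the SN, VTA and VS sphere sets.
    """
    vs = [
        SphereSpec((-12.0, 10.0, -6.0), 12.0),
        SphereSpec((12.0, 10.0, -6.0), 12.0),
    ]
    sn = [
        SphereSpec((-10.1, -18.9, -11.6), 3.0),
        SphereSpec((11.3, -18.7, -11.7), 3.0),
    ]
    vta = [
        SphereSpec((-2.7, -15.9, -13.9), 3.0),
        SphereSpec((4.1, -15.9, -13.9), 3.0),
    ]
    return {
        "VS": vs,
        "vmPFC": [SphereSpec((0.0, 46.0, -7.0), 8.0)],
        "SN": sn,
        "VTA": vta,
        "mesolimbic": sn + vta + vs,
    }


def build_sphere_rois(
    affine: np.ndarray, shape: tuple[int, int, int]
) -> dict[str, np.ndarray]:
    """Materialise every default sphere ROI as a binary mask on the grid."""
    return {
        name: union_masks([sphere_mask(s, affine, shape) for s in specs])
        for name, specs in default_roi_specs().items()
    }
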