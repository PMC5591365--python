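"""Geometric feature extraction from co-registered binary masks.

The five raw measurements feeding the complexity score:

* distance from enhancing tumour to the ventricles (mm),
* corpus callosum involvement (boolean overlap),
* bilaterality (tumour voxels on both sides of the midsagittal plane),
* eloquent-region involvement (boolean overlap),
* maximal tumour diameter (3D Feret diameter, mm),
* extension of peritumoural oedema beyond the enhancing margin (mm).

All distances are Euclidean between voxel centres, honouring anisotropic
spacing via an exact distance transform; sub-voxel surface offsets are not
modelled, so every length carries a discretisation error of at most one
voxel space diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .masks import MaskVolume, Plane, RegionAtlas

__all__ = [
    "TumorFeatures",
    "min_surface_distance",
    "feret_diameter",
    "oedema_extension",
    "involvement",
    "crosses_midline",
    "extract_features",
]

FEATURE_COLUMNS = (
    "ventricle_distance_mm",
    "corpus_callosum_involved",
    "bilateral",
    "eloquent_involved",
    "max_diameter_mm",
    "oedema_extension_mm",
)


@dataclass(frozen=True)
class TumorFeatures:
    """The five raw measurements of one tumour, before thresholding."""

    ventricle_distance_mm: float
    corpus_callosum_involved: bool
    bilateral: bool
    eloquent_involved: bool
    max_diameter_mm: float
    oedema_extension_mm: float

    def __post_init__(self) -> None:
        for name in ("ventricle_distance_mm", "max_diameter_mm", "oedema_extension_mm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    def as_dict(self) -> dict:
        return {
            "ventricle_distance_mm": self.ventricle_distance_mm,
            "corpus_callosum_involved": self.corpus_callosum_involved,
            "bilateral": self.bilateral,
            "eloquent_involved": self.eloquent_involved,
            "max_diameter_mm": self.max_diameter_mm,
            "oedema_extension_mm": self.oedema_extension_mm,
        }


def _require_nonempty(mask: MaskVolume, name: str) -> None:
    if mask.is_empty:
        raise ValueError(f"mask '{name}' is empty")


def min_surface_distance(a: MaskVolume, b: MaskVolume, names=("a", "b")) -> float:
    """Minimum voxel-centre distance in mm from mask ``a`` to mask ``b``.

    Zero when the masks overlap. Both masks must be nonempty and on the
    same grid. Exact for voxel centres: uses the Euclidean distance
    transform of ``b`` sampled at the voxels of ``a``.
    """
    a.require_same_grid(b, names)
    _require_nonempty(a, names[0])
    _require_nonempty(b, names[1])
    if (a.data & b.data).any():
        return 0.0
    dist_to_b = distance_transform_edt(~b.data, sampling=b.spacing)
    return float(dist_to_b[a.data].min())


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Exact maximum pairwise distance over a point set (mm coordinates)."""
    n = len(points)
    if n == 1:
        return 0.0
    if n > 2000:
        # the diameter is attained on the convex hull; fall back to the
        # full pairwise scan for degenerate (flat/collinear) point sets
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass
    return float(pdist(points).max())


def feret_diameter(a: MaskVolume, mode: str = "3d") -> float:
    """Maximal diameter of a mask in mm.

    ``mode='3d'`` (default): maximum Euclidean distance between any two
    voxel centres of the mask. ``mode='axial'``: maximum in-plane diameter
    over axial (constant-k) slices, mirroring a slice-wise radiological
    read. Exact in either mode.
    """
    _require_nonempty(a, "mask")
    if mode == "3d":
        return _max_pairwise_distance(a.world_coordinates())
    if mode == "axial":
        idx = np.argwhere(a.data)
        R, t = a.affine[:3, :3], a.affine[:3, 3]
        best = 0.0
        for k in np.unique(idx[:, 2]):
            pts = idx[idx[:, 2] == k] @ R.T + t
            best = max(best, _max_pairwise_distance(pts))
        return best
    raise ValueError(f"unknown diameter mode {mode!r}; use '3d' or 'axial'")


def oedema_extension(tumour: MaskVolume, oedema: MaskVolume) -> float:
    """Maximum distance in mm from any oedema voxel to the nearest tumour voxel.

    Zero when the oedema mask is empty or entirely inside the tumour.
    """
    tumour.require_same_grid(oedema, ("tumour", "oedema"))
    _require_nonempty(tumour, "tumour")
    if oedema.is_empty:
        return 0.0
    dist_to_tumour = distance_transform_edt(~tumour.data, sampling=tumour.spacing)
    return float(dist_to_tumour[oedema.data].max())


def involvement(tumour: MaskVolume, region: MaskVolume, min_voxels: int = 1) -> bool:
    """True iff tumour and region share at least ``min_voxels`` voxels."""
    tumour.require_same_grid(region, ("tumour", "region"))
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    return int((tumour.data & region.data).sum()) >= min_voxels


def crosses_midline(tumour: MaskVolume, midline: Plane) -> bool:
    """True iff the tumour has voxel centres strictly on both sides of the plane.

    Centres exactly on the plane count for neither side.
    """
    _require_nonempty(tumour, "tumour")
    d = midline.signed_distance(tumour.world_coordinates())
    return bool((d > 0).any() and (d < 0).any())


def extract_features(
    tumour: MaskVolume,
    oedema: MaskVolume,
    atlas: RegionAtlas,
    *,
    involvement_min_voxels: int = 1,
    diameter_mode: str = "3d",
) -> TumorFeatures:
    """Measure all five grading features of one subject.

    Deterministic: identical inputs give bit-identical outputs.
    """
    _require_nonempty(tumour, "tumour")
    atlas.require_same_grid_as(tumour)
    return TumorFeatures(
        ventricle_distance_mm=min_surface_distance(
            tumour, atlas.ventricles, ("tumour", "ventricles")
        ),
        corpus_callosum_involved=involvement(
            tumour, atlas.corpus_callosum, involvement_min_voxels
        ),
        bilateral=crosses_midline(tumour, atlas.midline),
        eloquent_involved=involvement(tumour, atlas.eloquent, involvement_min_voxels),
        max_diameter_mm=feret_diameter(tumour, mode=diameter_mode),
        oedema_extension_mm=oedema_extension(tumour, oedema),
    )
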