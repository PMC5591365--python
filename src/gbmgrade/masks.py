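"""Binary mask volumes on a physical voxel grid.

All geometric measurements in this package operate on co-registered 3D
binary masks (tumour, oedema, ventricles, corpus callosum, eloquent
regions). A :class:`MaskVolume` couples the voxel lattice with a 4x4
affine mapping voxel indices to scanner millimetre coordinates
(RAS convention: +x right, +y anterior, +z superior). Distances are
measured between voxel centres; the affine's direction columns must be
orthogonal so that index offsets scaled by the voxel spacing give true
Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["MaskVolume", "Plane", "RegionAtlas", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two masks do not share shape and affine."""


def _as_affine(spacing, origin) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    if origin is not None:
        affine[:3, 3] = np.asarray(origin, dtype=float)
    return affine


@dataclass(frozen=True)
class MaskVolume:
    """A 3D binary mask with physical spacing and orientation.

    Parameters
    ----------
    data
        3D array; values must be exactly 0 or 1 (stored as bool).
    affine
        4x4 voxel-index -> scanner-mm map. Voxel (i, j, k)'s *centre*
        sits at ``affine @ (i, j, k, 1)``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    "mask voxels must be exactly 0 or 1; "
                    f"found values {vals[~np.isin(vals, (0, 1))][:5]}"
                )
            arr = arr.astype(bool)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        R = aff[:3, :3]
        lengths = np.linalg.norm(R, axis=0)
        if not (lengths > 0).all() or not np.isfinite(lengths).all():
            raise ValueError("voxel spacing must be positive and finite")
        # orthogonal direction columns: required for spacing-based distances
        gram = R.T @ R
        off = gram - np.diag(np.diag(gram))
        if np.abs(off).max() > 1e-6 * lengths.max() ** 2:
            raise ValueError("affine direction columns must be orthogonal")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "affine", aff)

    # -- constructors -------------------------------------------------

    @classmethod
    def from_array(cls, data, spacing=(1.0, 1.0, 1.0), origin=None) -> "MaskVolume":
        """Build a mask from an array, axis-aligned spacing and origin (mm)."""
        return cls(np.asarray(data), _as_affine(spacing, origin))

    @classmethod
    def from_nifti(cls, path, binarize_threshold: float | None = None) -> "MaskVolume":
        """Load a NIfTI-1 volume as a binary mask.

        Non-binary volumes are rejected unless ``binarize_threshold`` is
        given, in which case voxels strictly above the threshold become 1.
        """
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if binarize_threshold is not None:
            arr = arr > binarize_threshold
        else:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(
                    f"{path}: volume is not binary; pass a binarize threshold"
                )
        return cls(arr.astype(bool), img.affine)

    def to_nifti(self, path) -> None:
        """Write the mask as uint8 NIfTI-1 (.nii or .nii.gz by extension)."""
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        nib.save(img, str(Path(path)))

    # -- grid properties ----------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size along each axis in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of one voxel's space diagonal — the discretisation bound."""
        return float(np.linalg.norm(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def same_grid(self, other: "MaskVolume", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_grid(self, other: "MaskVolume", names=("a", "b")) -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"masks '{names[0]}' and '{names[1]}' are not on the same grid: "
                f"shapes {self.shape} vs {other.shape}, "
                f"affines differ by {np.abs(self.affine - other.affine).max():.3g}"
            )

    def world_coordinates(self) -> np.ndarray:
        """Scanner-mm coordinates of the centres of all foreground voxels, (n, 3)."""
        idx = np.argwhere(self.data)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class Plane:
    """A plane in scanner mm coordinates, given by a point and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0 or not np.isfinite(norm):
            raise ValueError("plane normal must be nonzero and finite")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    @classmethod
    def midsagittal(cls) -> "Plane":
        """Default midline: the x = 0 plane of the RAS scanner frame."""
        return cls(np.zeros(3), np.array([1.0, 0.0, 0.0]))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass(frozen=True)
class RegionAtlas:
    """Anatomical reference masks for one subject, plus the midsagittal plane.

    ``eloquent`` is the union of motor/sensory cortex, language cortex,
    insula and basal ganglia.
    """

    ventricles: MaskVolume
    corpus_callosum: MaskVolume
    eloquent: MaskVolume
    midline: Plane = field(default_factory=Plane.midsagittal)

    def __post_init__(self) -> None:
        ref = self.ventricles
        for name in ("corpus_callosum", "eloquent"):
            ref.require_same_grid(getattr(self, name), ("ventricles", name))

    def require_same_grid_as(self, mask: MaskVolume, name: str = "tumour") -> None:
        mask.require_same_grid(self.ventricles, (name, "atlas"))
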