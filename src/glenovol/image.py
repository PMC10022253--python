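"""Voxel-grid containers for CT-arthrography volumes and segmentation masks.

All geometry is expressed in the LPS (left-posterior-superior) patient-space
convention used by DICOM.  A voxel with integer index ``(i, j, k)`` has its
center at ``origin + direction @ (spacing * (i, j, k))`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError

__all__ = ["VolumeImage", "SegmentationMask"]

_ORTHO_TOL = 1e-6


def _check_geometry(voxels: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                    direction: np.ndarray) -> None:
    if voxels.ndim != 3 or min(voxels.shape) < 1:
        raise GeometryError(f"voxel grid must be 3-D with >=1 voxel per axis, got shape {voxels.shape}")
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise GeometryError(f"spacing must be three positive lengths (mm), got {spacing}")
    if origin.shape != (3,):
        raise GeometryError(f"origin must be a 3-vector (mm), got shape {origin.shape}")
    if direction.shape != (3, 3):
        raise GeometryError("direction must be a 3x3 matrix")
    if not np.allclose(direction @ direction.T, np.eye(3), atol=_ORTHO_TOL):
        raise GeometryError("direction matrix is not orthonormal")
    if abs(abs(float(np.linalg.det(direction))) - 1.0) > _ORTHO_TOL:
        raise GeometryError("direction matrix determinant is not +/-1")


@dataclass
class VolumeImage:
    """A 3-D scalar image on a regular grid in LPS patient space.

    Parameters
    ----------
    voxels
        Scalar array indexed ``[i, j, k]`` (fastest-varying image axis first,
        matching the ITK index convention).
    spacing
        Per-axis voxel edge length in mm; all entries positive.
    origin
        Physical position (mm, LPS) of the center of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal axis-cosine matrix mapping index axes to LPS axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.ndim == 0:
            self.spacing = np.full(3, float(self.spacing))
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        _check_geometry(self.voxels, self.spacing, self.origin, self.direction)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices, shape (..., 3), to LPS mm."""
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (ijk * self.spacing) @ self.direction.T

    def physical_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map LPS-mm points, shape (..., 3), to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - self.origin) @ self.direction) / self.spacing

    def contains_point(self, xyz: np.ndarray) -> bool:
        """True when the nearest voxel to ``xyz`` lies inside the grid."""
        idx = np.rint(self.physical_to_index(xyz)).astype(int)
        return bool(np.all(idx >= 0) and np.all(idx < np.array(self.shape)))

    def same_geometry(self, other: "VolumeImage", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.direction, other.direction, atol=tol))


@dataclass
class SegmentationMask(VolumeImage):
    """Binary label map (1 = intra-articular contrast) sharing VolumeImage geometry."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise GeometryError(f"mask labels must be 0/1, found values {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def n_labeled(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def labeled_indices(self) -> np.ndarray:
        """Integer indices of labeled voxels, shape (n, 3)."""
        return np.argwhere(self.voxels > 0)

    def labeled_centers_mm(self) -> np.ndarray:
        """Physical centers (mm, LPS) of labeled voxels, shape (n, 3)."""
        return self.index_to_physical(self.labeled_indices())
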