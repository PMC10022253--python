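"""Scapular landmarks and the scapular anatomical coordinate frame.

The frame follows the arthrographic convention: the plane through the three
scapular landmarks (angulus inferior, trigonum scapulae, glenoid center) is
the scapular *coronal* plane; the *axial* plane is perpendicular to it and
carries the superior direction along the scapula's medial border; the
*sagittal* plane is orthogonal to both.  The glenoid center is the common
origin, and also the center of the clock face used for quadrant partitioning.

Axes (unit vectors, LPS patient space):

``a_axis``  anterior  — normal of the scapular plane, signed so its LPS-y
            component is negative (anterior);
``s_axis``  superior  — angulus-inferior -> trigonum-scapulae direction
            orthogonalized against ``a_axis``, signed so its z component is
            positive (superior);
``l_axis``  lateral   — ``a_axis x s_axis`` (right-handed triad).

For left shoulders the stored triad is unchanged (still right-handed) but the
*lateral coordinate* returned by :meth:`ScapularFrame.to_coords` is negated so
that positive ``l`` means "lateral" on both sides.  Quadrant labels depend only
on the (a, s) coordinates and are therefore side-symmetric by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GeometryError, OrientationWarning

__all__ = ["ScapularLandmarks", "ScapularFrame", "build_frame", "ras_to_lps", "lps_to_ras"]

#: landmarks within this triangle area (mm^2) of collinear are rejected
MIN_TRIANGLE_AREA_MM2 = 1.0

#: |z| of the superior axis below this triggers an implausible-pose warning
MIN_SUPERIOR_Z = 0.1


def ras_to_lps(points: np.ndarray) -> np.ndarray:
    """Convert RAS coordinates to LPS (negate x and y). Involution."""
    points = np.asarray(points, dtype=float)
    return points * np.array([-1.0, -1.0, 1.0])


# the conversion is its own inverse
lps_to_ras = ras_to_lps


@dataclass
class ScapularLandmarks:
    """The three scapular fiducials, in mm LPS patient space."""

    angulus_inferior: np.ndarray
    trigonum_scapulae: np.ndarray
    glenoid_center: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.angulus_inferior = np.asarray(self.angulus_inferior, dtype=float)
        self.trigonum_scapulae = np.asarray(self.trigonum_scapulae, dtype=float)
        self.glenoid_center = np.asarray(self.glenoid_center, dtype=float)
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")
        for p in (self.angulus_inferior, self.trigonum_scapulae, self.glenoid_center):
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise GeometryError("each landmark must be a finite 3-vector (mm)")
        if self.triangle_area_mm2 <= MIN_TRIANGLE_AREA_MM2:
            raise GeometryError(
                "landmarks are collinear or nearly so "
                f"(triangle area {self.triangle_area_mm2:.3g} mm^2 <= {MIN_TRIANGLE_AREA_MM2} mm^2)")

    @property
    def triangle_area_mm2(self) -> float:
        u = self.trigonum_scapulae - self.angulus_inferior
        v = self.glenoid_center - self.angulus_inferior
        return 0.5 * float(np.linalg.norm(np.cross(u, v)))

    def as_array(self) -> np.ndarray:
        return np.stack([self.angulus_inferior, self.trigonum_scapulae, self.glenoid_center])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ScapularLandmarks":
        """Apply a rigid transform ``x -> R x + t`` to all three points."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return ScapularLandmarks(R @ self.angulus_inferior + t,
                                 R @ self.trigonum_scapulae + t,
                                 R @ self.glenoid_center + t, side=self.side)


@dataclass
class ScapularFrame:
    """Orthonormal scapular coordinate frame with origin at the glenoid center."""

    origin: np.ndarray
    a_axis: np.ndarray
    s_axis: np.ndarray
    l_axis: np.ndarray
    side: str = "right"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.a_axis = np.asarray(self.a_axis, dtype=float)
        self.s_axis = np.asarray(self.s_axis, dtype=float)
        self.l_axis = np.asarray(self.l_axis, dtype=float)
        M = np.stack([self.a_axis, self.s_axis, self.l_axis])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal to 1e-9")
        if not np.isclose(float(np.linalg.det(M)), 1.0, atol=1e-9):
            raise GeometryError("frame axes are not right-handed (det != +1)")
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def rotation(self) -> np.ndarray:
        """Rows are (a, s, l); maps LPS offsets to frame coordinates."""
        return np.stack([self.a_axis, self.s_axis, self.l_axis])

    def to_coords(self, points: np.ndarray) -> np.ndarray:
        """Frame coordinates (a, s, l) in mm for LPS points of shape (..., 3).

        On left shoulders the lateral coordinate is mirrored so that positive
        ``l`` is lateral on both sides; ``a`` and ``s`` are unchanged.
        """
        points = np.asarray(points, dtype=float)
        out = (points - self.origin) @ self.rotation.T
        if self.side == "left":
            out = out * np.array([1.0, 1.0, -1.0])
        return out

    def from_coords(self, coords: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_coords`; recovers LPS points."""
        coords = np.asarray(coords, dtype=float)
        if self.side == "left":
            coords = coords * np.array([1.0, 1.0, -1.0])
        return coords @ self.rotation + self.origin

    def to_json(self, path: str | Path) -> None:
        data = {"origin": self.origin.tolist(), "a_axis": self.a_axis.tolist(),
                "s_axis": self.s_axis.tolist(), "l_axis": self.l_axis.tolist(),
                "side": self.side, "convention": "LPS"}
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScapularFrame":
        data = json.loads(Path(path).read_text())
        return cls(np.array(data["origin"]), np.array(data["a_axis"]),
                   np.array(data["s_axis"]), np.array(data["l_axis"]),
                   side=data.get("side", "right"))


def build_frame(landmarks: ScapularLandmarks) -> ScapularFrame:
    """Construct the scapular frame from the three fiducials.

    The plane through the landmarks is the scapular (coronal) plane; its unit
    normal, signed anteriorly (negative LPS-y), is the anterior axis.  The
    superior axis is the angulus-inferior -> trigonum-scapulae direction
    (the medial border, in-plane by construction) orthogonalized against the
    normal and signed superiorly.  The lateral axis completes the triad.

    Raises
    ------
    GeometryError
        If the landmarks are collinear (triangle area <= 1 mm^2).

    Warns
    -----
    OrientationWarning
        If the superior axis is nearly horizontal (|z| < 0.1), an implausible
        scapula pose; the frame is still returned.
    """
    ai = landmarks.angulus_inferior
    ts = landmarks.trigonum_scapulae
    gc = landmarks.glenoid_center

    normal = np.cross(ts - ai, gc - ai)
    norm = np.linalg.norm(normal)
    if norm <= 2.0 * MIN_TRIANGLE_AREA_MM2:  # area = norm / 2
        raise GeometryError("landmarks are collinear; scapular plane is undefined")
    a_axis = normal / norm
    if a_axis[1] > 0:  # anterior is -y in LPS
        a_axis = -a_axis

    s_axis = ts - ai
    s_axis = s_axis - (s_axis @ a_axis) * a_axis
    s_norm = np.linalg.norm(s_axis)
    if s_norm < 1e-12:
        raise GeometryError("medial-border direction is parallel to the plane normal")
    s_axis = s_axis / s_norm
    if s_axis[2] < 0:  # superior is +z in LPS
        s_axis = -s_axis
    if abs(s_axis[2]) < MIN_SUPERIOR_Z:
        warnings.warn(
            "superior axis is nearly horizontal (|z| < 0.1): implausible scapula pose",
            OrientationWarning, stacklevel=2)

    l_axis = np.cross(a_axis, s_axis)
    return ScapularFrame(origin=gc.copy(), a_axis=a_axis, s_axis=s_axis,
                         l_axis=l_axis, side=landmarks.side)
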