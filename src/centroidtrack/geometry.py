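"""Cartesian coordinate frames and rigid-transform algebra.

The clinical frame is derived upstream from the patient's natural head
position: X is sagittal (+ anterior), Y vertical (+ superior), Z
transversal (+ toward the patient's right).  Those positive directions are
a convention of this package and are echoed into every report, since the
sign of a displacement is only interpretable relative to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FrameError
from .mesh import TriangleMesh

AXIS_CONVENTION = {"x": "sagittal (+anterior)", "y": "vertical (+superior)",
                   "z": "transversal (+patient right)"}

_ORTHO_TOL = 1e-9          # invariant tolerance after construction
_REORTHO_LIMIT = 1e-6      # inputs worse than this are rejected


def _orthonormality_deviation(matrix: np.ndarray) -> float:
    return float(np.abs(matrix.T @ matrix - np.eye(3)).max())


def _project_to_rotation(matrix: np.ndarray) -> np.ndarray:
    """Nearest rotation matrix (Frobenius) via SVD, det forced to +1."""
    u, _, vt = np.linalg.svd(matrix)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        u[:, -1] *= -1
        rot = u @ vt
    return rot


@dataclass
class CartesianFrame:
    """Origin plus right-handed orthonormal axis triple (mm)."""

    origin: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray
    axis_z: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        axes = np.column_stack([
            np.asarray(self.axis_x, dtype=np.float64).reshape(3),
            np.asarray(self.axis_y, dtype=np.float64).reshape(3),
            np.asarray(self.axis_z, dtype=np.float64).reshape(3)])
        dev = _orthonormality_deviation(axes)
        if dev > _REORTHO_LIMIT:
            raise FrameError(
                f"frame axes not orthonormal (deviation {dev:.3g} > "
                f"{_REORTHO_LIMIT:g}); refusing to guess an axis system")
        if np.linalg.det(axes) < 0:
            raise FrameError("frame axes are left-handed (x cross y != z)")
        if dev > _ORTHO_TOL:
            axes = _project_to_rotation(axes)
        self.axis_x, self.axis_y, self.axis_z = axes.T

    @classmethod
    def identity(cls) -> "CartesianFrame":
        return cls(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.column_stack([self.axis_x, self.axis_y, self.axis_z])

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(),
                "axis_x": self.axis_x.tolist(),
                "axis_y": self.axis_y.tolist(),
                "axis_z": self.axis_z.tolist(),
                "units": "mm",
                "convention": AXIS_CONVENTION}


def load_frame(path) -> CartesianFrame:
    """Load a frame from its JSON file.

    Schema: ``{"origin": [x,y,z], "axis_x": [...], "axis_y": [...],
    "axis_z": [...], "units": "mm"}``.  Axes within 1e-6 of orthonormal are
    re-orthonormalized; anything worse is rejected.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FrameError(f"cannot parse frame file {path}: {exc}") from exc
    missing = {"origin", "axis_x", "axis_y", "axis_z"} - set(payload)
    if missing:
        raise FrameError(f"frame file {path} missing keys: {sorted(missing)}")
    units = payload.get("units", "mm")
    if units != "mm":
        raise FrameError(f"frame file {path}: unsupported units {units!r}")
    return CartesianFrame(payload["origin"], payload["axis_x"],
                          payload["axis_y"], payload["axis_z"])


def save_frame(frame: CartesianFrame, path) -> None:
    Path(path).write_text(json.dumps(frame.to_dict(), indent=2))


def to_frame_coords(point, frame: CartesianFrame) -> np.ndarray:
    """Express world point(s) in the frame: ((p - origin) . axis_i)."""
    p = np.asarray(point, dtype=np.float64)
    return (p - frame.origin) @ frame.rotation


def from_frame_coords(point, frame: CartesianFrame) -> np.ndarray:
    """Inverse of :func:`to_frame_coords`."""
    p = np.asarray(point, dtype=np.float64)
    return p @ frame.rotation.T + frame.origin


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation,
                                      dtype=np.float64).reshape(3)
        dev = _orthonormality_deviation(self.rotation)
        if dev > _REORTHO_LIMIT:
            raise FrameError(f"rotation not orthonormal (deviation {dev:.3g})")
        if np.linalg.det(self.rotation) < 0:
            raise FrameError("rotation has determinant -1 (reflection)")
        if dev > 1e-12:
            self.rotation = _project_to_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}


def compose(t1: RigidTransform, t2: RigidTransform) -> RigidTransform:
    """Transform applying ``t1`` first, then ``t2``."""
    rotation = t2.rotation @ t1.rotation
    translation = t2.rotation @ t1.translation + t2.translation
    return RigidTransform(rotation, translation)  # re-orthonormalized inside


def apply_rigid(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Rigidly move a mesh; topology is untouched."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy(),
                        mesh.name)
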