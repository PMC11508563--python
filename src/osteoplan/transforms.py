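"""Rigid transforms, mirror planes and anatomical coordinate frames.

All lengths are millimetres. Angles are degrees at every public API
boundary and radians only inside numerical kernels.

The package-wide coordinate convention is a right-handed, patient-like
frame for a RIGHT leg:

* ``x``: anterior (-) to posterior (+)
* ``y``: lateral (-) to medial (+)
* ``z``: caudal (-) to cranial (+)

For a left leg the lateral/medial reading of ``y`` flips; this is carried
by :class:`AnatomicalFrame.side` so reports can annotate directions
correctly without changing the numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "Plane", "AnatomicalFrame"]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``v -> R @ v + t`` in mm.

    ``rotation`` must be orthonormal with determinant +1 (checked to
    1e-9 at construction).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (improper reflection)")
        # re-orthonormalise tiny drift so compositions stay exact
        if err > _ORTHO_TOL:
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def about_point(cls, rotation: np.ndarray, center: np.ndarray,
                    translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation about ``center`` followed by an optional translation."""
        R = np.asarray(rotation, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(R, c - R @ c + t)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self after other``: ``(self @ other)(v) == self(other(v))``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))


@dataclass(frozen=True)
class Plane:
    """Oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        n = n / norm
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.point) @ self.normal

    def reflect(self, points: np.ndarray) -> np.ndarray:
        d = self.signed_distance(points)
        return np.asarray(points, float) - 2.0 * d[:, None] * self.normal

    @property
    def reflection_matrix(self) -> np.ndarray:
        """4x4 affine reflection across the plane."""
        n = self.normal
        H = np.eye(3) - 2.0 * np.outer(n, n)
        m = np.eye(4)
        m[:3, :3] = H
        m[:3, 3] = 2.0 * (self.point @ n) * n
        return m


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed anatomical frame (axes orthonormal, ``x cross y = z``).

    Defaults encode the package convention for a right proximal tibia
    with the origin at the centre of the tibial plateau.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    x_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    y_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    z_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    side: str = "right"

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        x, y, z = _unit(self.x_axis), _unit(self.y_axis), _unit(self.z_axis)
        B = np.column_stack([x, y, z])
        if np.abs(B.T @ B - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.norm(np.cross(x, y) - z) > 1e-9:
            raise ValueError("frame must be right-handed (x cross y = z)")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "x_axis", x)
        object.__setattr__(self, "y_axis", y)
        object.__setattr__(self, "z_axis", z)

    @property
    def basis(self) -> np.ndarray:
        """3x3 matrix whose columns are the frame axes."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def mid_sagittal_plane(self) -> Plane:
        """Default mirroring plane: through the origin, normal to y."""
        return Plane(self.origin, self.y_axis)

    def to_frame_coords(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.basis
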