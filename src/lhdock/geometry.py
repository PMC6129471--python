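"""Rigid-body transforms for docking poses.

A pose is a proper rigid transform ``x -> R(q) @ x + t`` acting on a solute's
reference coordinates.  Rotations are stored as unit quaternions in
``(w, x, y, z)`` order so that poses serialize compactly and compose without
drift (the quaternion is renormalized after every composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "quat_to_matrix",
    "quat_multiply",
    "quat_from_axis_angle",
    "quat_from_rotvec",
    "random_quaternion",
]

_UNIT_TOL = 1e-9


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``(w, x, y, z)``."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a * b`` (both ``(w, x, y, z)``)."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    half = 0.5 * angle
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = np.sin(half) * axis / n
    return q


def quat_from_rotvec(phi: np.ndarray) -> np.ndarray:
    """Quaternion of a rotation vector (axis * angle); exact for small angles."""
    phi = np.asarray(phi, dtype=float)
    angle = np.linalg.norm(phi)
    q = np.empty(4)
    if angle < 1e-12:
        q[0] = 1.0
        q[1:] = 0.5 * phi  # first-order; renormalized by the caller
    else:
        q[0] = np.cos(0.5 * angle)
        q[1:] = np.sin(0.5 * angle) * phi / angle
    return q / np.linalg.norm(q)


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    return np.array(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ]
    )


@dataclass
class RigidTransform:
    """Unit-quaternion rotation plus translation, in Å."""

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.quaternion = np.asarray(self.quaternion, dtype=float).copy()
        self.translation = np.asarray(self.translation, dtype=float).copy()
        if self.quaternion.shape != (4,) or self.translation.shape != (3,):
            raise ValueError("quaternion must be length 4, translation length 3")
        n = np.linalg.norm(self.quaternion)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n:.3g} is not 1")
        self.quaternion /= n

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        q = quat_multiply(self.quaternion, other.quaternion)
        q /= np.linalg.norm(q)
        t = self.apply(other.translation)
        return RigidTransform(q, t)

    def inverse(self) -> "RigidTransform":
        q = self.quaternion * np.array([1.0, -1.0, -1.0, -1.0])
        return RigidTransform(q, -(quat_to_matrix(q) @ self.translation))

    def copy(self) -> "RigidTransform":
        return RigidTransform(self.quaternion.copy(), self.translation.copy())

    def __eq__(self, other: object) -> bool:  # poses equal up to quaternion sign
        if not isinstance(other, RigidTransform):
            return NotImplemented
        qa, qb = self.quaternion, other.quaternion
        return bool(
            np.allclose(self.translation, other.translation)
            and (np.allclose(qa, qb) or np.allclose(qa, -qb))
        )
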