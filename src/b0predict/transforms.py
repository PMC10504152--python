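"""Rigid-body 6-DOF transforms in the scanner frame.

Convention: a transform first rotates about the scanner axes through the
world origin (the grid centre) with intrinsic rotations applied in the order
R = R_x · R_y · R_z (angles in degrees), then translates (mm):

    r_new = R · r + t

External 6-DOF estimates (e.g. from a rigid registration tool) must be
converted to this convention before use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform"]


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid motion: rotations (deg) about scanner x, y, z and
    translations (mm)."""

    rotations_deg: tuple = (0.0, 0.0, 0.0)
    translations_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        rot = tuple(float(v) for v in self.rotations_deg)
        tra = tuple(float(v) for v in self.translations_mm)
        if len(rot) != 3 or len(tra) != 3:
            raise ValueError("need three rotations and three translations")
        if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tra))):
            raise ValueError("transform parameters must be finite")
        object.__setattr__(self, "rotations_deg", rot)
        object.__setattr__(self, "translations_mm", tra)

    # ---------------------------------------------------------------- matrix
    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = np.deg2rad(self.rotations_deg)
        return _rot_x(ax) @ _rot_y(ay) @ _rot_z(az)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate map r → R r + t."""
        m = np.eye(4)
        m[:3, :3] = self.rotation_matrix()
        m[:3, 3] = self.translations_mm
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return all(v == 0.0 for v in self.rotations_deg + self.translations_mm)

    def inverse_matrix(self) -> np.ndarray:
        R = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = R.T
        m[:3, 3] = -R.T @ np.asarray(self.translations_mm)
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of world points (mm)."""
        R = self.rotation_matrix()
        return points @ R.T + np.asarray(self.translations_mm)

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        R = self.rotation_matrix()
        return (points - np.asarray(self.translations_mm)) @ R
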