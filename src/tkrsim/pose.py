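"""Rigid transforms (rotation + translation) of body frames in the world frame.

Lengths are millimetres throughout.  Rotations are stored as 3x3 matrices;
construction helpers accept axis-angle in degrees because all user-facing
angles in this package are degrees.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Pose:
    """Pose of a body frame in the world frame: ``p_world = R @ p_body + t``."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float).reshape(3, 3))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    @staticmethod
    def identity() -> "Pose":
        return Pose()

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, point=None) -> "Pose":
        """Rotation about ``axis`` through ``point`` (default: world origin)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        if point is None:
            return Pose(R, np.zeros(3))
        p = np.asarray(point, dtype=float)
        return Pose(R, p - R @ p)

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Pose(self.R @ other.R, self.R @ other.t + self.t)

    def __matmul__(self, other: "Pose") -> "Pose":
        return self.compose(other)

    def inverse(self) -> "Pose":
        Rt = self.R.T
        return Pose(Rt, -Rt @ self.t)

    def apply(self, points) -> np.ndarray:
        """Transform points (..., 3) from body to world frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def apply_vector(self, vectors) -> np.ndarray:
        """Rotate free vectors (..., 3) from body to world frame."""
        return np.asarray(vectors, dtype=float) @ self.R.T

    def almost_equal(self, other: "Pose", tol: float = 1e-9) -> bool:
        return (np.abs(self.R - other.R).max() < tol
                and np.abs(self.t - other.t).max() < tol)
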