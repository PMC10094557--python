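"""Pose of one placed model copy: rotation about the model centroid
followed by a fractional translation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .model import AtomicModel
from .rotation import euler_to_matrix

__all__ = ["Pose", "apply_pose"]


@dataclass
class Pose:
    euler: np.ndarray    # z-y-z Euler angles, degrees
    tfrac: np.ndarray    # fractional translation in [0, 1)

    def __post_init__(self) -> None:
        self.euler = np.mod(np.asarray(self.euler, float), 360.0)
        self.tfrac = np.mod(np.asarray(self.tfrac, float), 1.0)

    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.euler)

    def copy(self) -> "Pose":
        return Pose(self.euler.copy(), self.tfrac.copy())


def apply_pose(model_centered: AtomicModel, pose: Pose, cell: UnitCell) -> AtomicModel:
    """Place a centroid-centered model: x_frac = frac(W x_orth) + t."""
    out = model_centered.copy()
    rotated = out.xyz @ pose.matrix().T
    out.xyz = (cell.fractionalize(rotated) + pose.tfrac) @ cell.orth.T
    return out
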