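"""Unit cells and resolution geometry.

Fractional coordinates are used internally throughout the package;
orthogonal angstrom coordinates appear only at I/O boundaries and inside
the molecular-transform machinery.  Orthogonalization follows the standard
convention with **a** along x and **b** in the x-y plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["UnitCell", "d_spacing"]


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell edge {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell angles give a non-positive volume")

    @cached_property
    def volume(self) -> float:
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return float(self.a * self.b * self.c * np.sqrt(arg))

    @cached_property
    def orth(self) -> np.ndarray:
        """Fractional -> orthogonal (angstrom) matrix, a along x."""
        ca, cb = np.cos(np.radians(self.alpha)), np.cos(np.radians(self.beta))
        cg, sg = np.cos(np.radians(self.gamma)), np.sin(np.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @cached_property
    def frac(self) -> np.ndarray:
        """Orthogonal -> fractional matrix (inverse of :attr:`orth`)."""
        return np.linalg.inv(self.orth)

    @cached_property
    def recip(self) -> np.ndarray:
        """Reciprocal basis B: columns are a*, b*, c* so that q = B @ hkl (1/angstrom)."""
        return self.frac.T.copy()

    def orthogonalize(self, x_frac: np.ndarray) -> np.ndarray:
        return np.asarray(x_frac, float) @ self.orth.T

    def fractionalize(self, r_orth: np.ndarray) -> np.ndarray:
        return np.asarray(r_orth, float) @ self.frac.T

    def recip_vectors(self, hkl: np.ndarray) -> np.ndarray:
        """Cartesian reciprocal vectors (rows) for an (n, 3) array of indices."""
        return np.atleast_2d(np.asarray(hkl, float)) @ self.recip.T

    def d_values(self, hkl: np.ndarray) -> np.ndarray:
        q = self.recip_vectors(np.atleast_2d(hkl))
        norms = np.linalg.norm(q, axis=-1)
        if np.any(norms == 0):
            raise ValueError("d-spacing undefined for the (0,0,0) index")
        return 1.0 / norms

    # convenient key for caching / equality at file boundaries
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def d_spacing(cell: UnitCell, hkl) -> float:
    """Resolution d (angstrom) of one reflection ``hkl``."""
    h = np.asarray(hkl, float)
    if h.shape != (3,):
        raise ValueError("hkl must be a triple")
    if not np.any(h):
        raise ValueError("d-spacing undefined for the (0,0,0) index")
    return float(cell.d_values(h)[0])
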