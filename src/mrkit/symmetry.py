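"""Space-group symmetry: operators, point groups, allowed origin shifts.

Backed by gemmi's space-group tables.  An operator is stored as an integer
3x3 rotation acting on fractional coordinates plus a fractional translation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property, lru_cache
from itertools import product

import gemmi
import numpy as np

__all__ = ["SpaceGroup"]

# candidate components for discrete allowed-origin shifts; covers the
# common macromolecular settings (halves, thirds, quarters, sixths)
_SHIFT_FRACTIONS = (0.0, 1 / 2, 1 / 3, 2 / 3, 1 / 4, 3 / 4, 1 / 6, 5 / 6)


@dataclass(frozen=True)
class SpaceGroup:
    """Space group identified by its Hermann-Mauguin symbol."""

    symbol: str

    @cached_property
    def _gemmi(self) -> gemmi.SpaceGroup:
        sg = gemmi.find_spacegroup_by_name(self.symbol)
        if sg is None:
            raise ValueError(f"unknown space group symbol: {self.symbol!r}")
        return sg

    @cached_property
    def hm(self) -> str:
        return self._gemmi.hm

    @cached_property
    def operators(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """All (rotation, translation) pairs, centering included."""
        den = float(gemmi.Op.DEN)
        ops = []
        for op in self._gemmi.operations():
            rot = np.array(op.rot, float) / den
            tran = np.array(op.tran, float) / den
            ops.append((rot.astype(int) if np.allclose(rot, np.round(rot)) else rot, tran % 1.0))
        return ops

    @property
    def m(self) -> int:
        return len(self.operators)

    @cached_property
    def rotations(self) -> np.ndarray:
        """(m, 3, 3) stack of fractional rotation matrices."""
        return np.stack([r for r, _ in self.operators]).astype(float)

    @cached_property
    def translations(self) -> np.ndarray:
        return np.stack([t for _, t in self.operators])

    @cached_property
    def crystal_system(self) -> str:
        return self._gemmi.crystal_system_str()

    @cached_property
    def proper_rotations(self) -> np.ndarray:
        """Unique proper (det=+1) point rotations, fractional basis."""
        seen: dict[bytes, np.ndarray] = {}
        for r, _ in self.operators:
            r = np.asarray(r, float)
            if np.linalg.det(r) > 0:
                seen.setdefault(np.round(r, 6).tobytes(), r)
        return np.stack(list(seen.values()))

    @cached_property
    def laue_rotations(self) -> np.ndarray:
        """Unique point rotations of the Laue group (inversion added)."""
        seen: dict[bytes, np.ndarray] = {}
        for r, _ in self.operators:
            for s in (np.asarray(r, float), -np.asarray(r, float)):
                seen.setdefault(np.round(s, 6).tobytes(), s)
        return np.stack(list(seen.values()))

    @cached_property
    def polar_axes(self) -> np.ndarray:
        """Boolean mask of fractional axes along which the origin is free."""
        # axis i is polar iff R e_i == e_i for every operator rotation R
        mask = np.array(
            [all(np.allclose(np.asarray(r, float)[:, i], np.eye(3)[:, i]) for r, _ in self.operators) for i in range(3)]
        )
        return mask

    @cached_property
    def origin_shifts(self) -> np.ndarray:
        """Discrete allowed origin shifts (k, 3), polar components set to 0.

        A shift d is allowed when (R - I) d is a lattice vector for every
        operator: moving the origin by d then leaves the operator set (and
        all structure-factor amplitudes) unchanged.
        """
        polar = self.polar_axes
        axes_choices = [(0.0,) if polar[i] else _SHIFT_FRACTIONS for i in range(3)]
        rots = [np.asarray(r, float) for r, _ in self.operators]
        shifts = []
        for d in product(*axes_choices):
            dv = np.array(d)
            ok = all(np.allclose((r @ dv - dv) % 1.0, np.round((r @ dv - dv) % 1.0)) for r in rots)
            if ok:
                shifts.append(dv)
        return np.array(shifts)

    def epsilon_factors(self, hkl: np.ndarray) -> np.ndarray:
        """Expected intensity multiplicity (epsilon) per reflection."""
        ops = self._gemmi.operations()
        hkl = np.atleast_2d(np.asarray(hkl, int))
        return np.array([ops.epsilon_factor_without_centering(list(map(int, h))) for h in hkl], float)

    def is_absent(self, hkl) -> bool:
        return self._gemmi.operations().is_systematically_absent(list(int(x) for x in hkl))

    def asu_reduce(self, hkl: np.ndarray) -> np.ndarray:
        """Map indices to one reciprocal-asymmetric-unit representative each."""
        asu = gemmi.ReciprocalAsu(self._gemmi)
        ops = self._gemmi.operations()
        out = np.empty_like(np.atleast_2d(hkl))
        for i, h in enumerate(np.atleast_2d(hkl)):
            out[i], _ = asu.to_asu([int(h[0]), int(h[1]), int(h[2])], ops)
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpaceGroup({self.hm!r})"


@lru_cache(maxsize=32)
def spacegroup(symbol: str) -> SpaceGroup:
    return SpaceGroup(symbol)
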