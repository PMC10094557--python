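"""Structure-factor calculation with single-Gaussian scattering factors.

The scoring functions of molecular replacement rank Pearson correlations,
which are invariant to the absolute scattering scale, so each element is
represented by its electron count modulated by one Gaussian falloff:

    f(s) = Z * exp(-b_el * s^2 / 4),      s = 1/d

with a common width ``b_el`` (angstrom^2) chosen to mimic the decay of the
tabulated form factors of light elements over the 1.5-10 angstrom range.
Hydrogen is excluded from all sums by default.
"""

from __future__ import annotations

import numpy as np

from .cell import UnitCell
from .model import AtomicModel
from .symmetry import SpaceGroup

__all__ = ["scattering_factor", "calc_structure_factors", "symmetry_coefficients"]

# electron counts of the elements encountered in biomolecular models
ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "CO": 27,
    "NI": 28, "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

GAUSSIAN_WIDTH = 12.0  # b_el, angstrom^2


def _electrons(elements) -> np.ndarray:
    z = np.empty(len(elements), float)
    for i, el in enumerate(elements):
        key = str(el).strip().upper()
        if key not in ELECTRONS:
            raise ValueError(f"no scattering factor for element {el!r}")
        z[i] = ELECTRONS[key]
    return z


def scattering_factor(element: str, s: np.ndarray | float) -> np.ndarray:
    """f(s) for one element; ``s`` is 1/d in 1/angstrom."""
    z = _electrons([element])[0]
    s = np.asarray(s, float)
    return z * np.exp(-GAUSSIAN_WIDTH * s * s / 4.0)


def _per_atom_weights(model: AtomicModel, s2: np.ndarray, skip_h: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (atom mask, (n_hkl, n_atoms) weight matrix f*occ*DW)."""
    mask = np.ones(model.n_atoms, bool)
    if skip_h:
        mask &= np.array([str(e).strip().upper() != "H" for e in model.element])
    z = _electrons(model.element[mask])
    occ = model.occ[mask]
    b = model.b_iso[mask]
    # (n_hkl, n_atoms): element Gaussian plus the atomic Debye-Waller factor
    w = (z * occ)[None, :] * np.exp(-(GAUSSIAN_WIDTH + b)[None, :] * s2[:, None] / 4.0)
    return mask, w


def calc_structure_factors(
    model: AtomicModel,
    cell: UnitCell,
    sg: SpaceGroup,
    hkl: np.ndarray,
    skip_h: bool = True,
) -> np.ndarray:
    """Complex F(hkl) summed over all symmetry copies of ``model``.

    F(h) = sum_s sum_j f_j(s) occ_j exp(-B_j s^2/4) exp(2 pi i h.(R_s x_j + t_s))
    """
    hkl = np.atleast_2d(np.asarray(hkl, float))
    s2 = 1.0 / cell.d_values(hkl) ** 2
    mask, w = _per_atom_weights(model, s2, skip_h)
    x = cell.fractionalize(model.xyz[mask])  # (n_atoms, 3)
    f = np.zeros(len(hkl), complex)
    for rot, tran in sg.operators:
        h_rot = hkl @ np.asarray(rot, float)          # rows: R^T h
        phase = np.exp(2j * np.pi * (h_rot @ x.T + (hkl @ tran)[:, None]))
        f += (w * phase).sum(axis=1)
    return f


def symmetry_coefficients(
    x_frac: np.ndarray,
    weights: np.ndarray,
    sg: SpaceGroup,
    hkl: np.ndarray,
    hkl_tran_phase: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-operator complex coefficients C_s(h) for a copy placed at t = 0.

    The structure factor of symmetry copy s for the model shifted by a
    fractional translation t is  C_s(h) * exp(2 pi i (R_s^T h) . t), so the
    coefficients let the translation search move the copy without resumming
    over atoms.  ``weights`` is the (n_hkl, n_atoms) f*occ*DW matrix.

    Returns (C of shape (m, n_hkl), h_rot of shape (m, n_hkl, 3) int).
    """
    hkl = np.atleast_2d(np.asarray(hkl, float))
    m = sg.m
    coeff = np.empty((m, len(hkl)), complex)
    h_rot_all = np.empty((m, len(hkl), 3))
    for s, (rot, tran) in enumerate(sg.operators):
        h_rot = hkl @ np.asarray(rot, float)
        phase = np.exp(2j * np.pi * (h_rot @ x_frac.T))
        coeff[s] = (weights * phase).sum(axis=1)
        if hkl_tran_phase:
            coeff[s] *= np.exp(2j * np.pi * (hkl @ tran))
        h_rot_all[s] = h_rot
    return coeff, h_rot_all


def atom_weights(model: AtomicModel, cell: UnitCell, hkl: np.ndarray, skip_h: bool = True):
    """Convenience: fractional coordinates and weight matrix for ``symmetry_coefficients``."""
    hkl = np.atleast_2d(np.asarray(hkl, float))
    s2 = 1.0 / cell.d_values(hkl) ** 2
    mask, w = _per_atom_weights(model, s2, skip_h)
    return cell.fractionalize(model.xyz[mask]), w
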