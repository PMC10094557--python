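"""Agreement scores: crystallographic R factor and model accuracy (MA).

MA is the fraction of non-H reference atoms that have a model atom (of any
element) within 0.6 angstrom, maximized over the space group's symmetry
operators and allowed origin shifts -- a molecular-replacement solution is
only defined up to that ambiguity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .cell import UnitCell
from .model import AtomicModel
from .symmetry import SpaceGroup

__all__ = ["r_factor", "scale_factor", "evaluate_model_accuracy"]


def scale_factor(fobs: np.ndarray, fcalc: np.ndarray, method: str = "sum") -> float:
    """Deterministic closed-form scale k for |Fo| ~ k |Fc|.

    ``sum`` matches the amplitude sums (k = sum|Fo| / sum|Fc|), the
    convention under which two unrelated acentric structures give the
    classic R ~ 0.59; ``lsq`` minimizes sum (|Fo| - k |Fc|)^2.
    """
    if method == "sum":
        fc = float(np.sum(fcalc))
        return float(np.sum(fobs) / fc) if fc > 0 else 0.0
    if method == "lsq":
        fc2 = float(np.sum(fcalc * fcalc))
        return float(np.sum(fobs * fcalc) / fc2) if fc2 > 0 else 0.0
    raise ValueError(f"unknown scale method {method!r}")


def r_factor(fobs: np.ndarray, fcalc: np.ndarray, scale: str = "sum") -> float:
    """R = sum||Fo| - k|Fc|| / sum|Fo| with the closed-form scale k."""
    fobs = np.abs(np.asarray(fobs, float))
    fcalc = np.abs(np.asarray(fcalc, float))
    if len(fobs) == 0 or len(fobs) != len(fcalc):
        raise ValueError("R factor needs matched non-empty amplitude lists")
    denom = fobs.sum()
    if denom == 0:
        raise ValueError("all observed amplitudes are zero")
    k = scale_factor(fobs, fcalc, scale)
    return float(np.abs(fobs - k * fcalc).sum() / denom)


def _nonh_mask(model: AtomicModel) -> np.ndarray:
    return np.array([str(e).strip().upper() != "H" for e in model.element], dtype=bool)


def _circular_shift(ref: np.ndarray, mov: np.ndarray) -> float:
    """Offset (frac) aligning the circular mean of mov onto ref along one axis."""
    ang_r = np.angle(np.exp(2j * np.pi * ref).mean())
    ang_m = np.angle(np.exp(2j * np.pi * mov).mean())
    return float((ang_r - ang_m) / (2 * np.pi))


def evaluate_model_accuracy(
    model: AtomicModel,
    reference: AtomicModel,
    cell: UnitCell,
    sg: SpaceGroup,
    tol: float = 0.6,
    polar_steps: int = 48,
) -> float:
    """Fraction of non-H reference atoms matched within ``tol`` angstrom.

    The comparison is between crystal contents: each reference atom may be
    matched by any symmetry image of the (origin-shifted) model, because a
    molecular-replacement solution is only defined up to the space group's
    allowed origin shifts and each placed copy can occupy a different
    asymmetric-unit slot.  Along polar axes the free origin component is
    optimized by a coarse scan plus golden-section style refinement.
    Distances are minimum-image.
    """
    ref = reference.select(_nonh_mask(reference))
    if ref.n_atoms == 0:
        raise ValueError("reference model has no non-H atoms")
    mov = model.select(_nonh_mask(model))
    if mov.n_atoms == 0:
        return 0.0

    x_ref = cell.fractionalize(ref.xyz) % 1.0
    x_mov0 = cell.fractionalize(mov.xyz)
    polar = sg.polar_axes
    offsets = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
    ref_orth = x_ref @ cell.orth.T

    def fraction_matched(delta: np.ndarray) -> float:
        imgs = []
        for rot, tran in sg.operators:
            x = (x_mov0 + delta) @ np.asarray(rot, float).T + tran
            x = x % 1.0
            imgs.append((x[None, :, :] + offsets[:, None, :]).reshape(-1, 3))
        pts = np.concatenate(imgs) @ cell.orth.T
        dist, _ = cKDTree(pts).query(ref_orth, k=1)
        return float(np.mean(dist <= tol))

    # polar-axis candidate offsets: coarse scan refined around the best
    if polar.any():
        coarse = np.linspace(0.0, 1.0, polar_steps, endpoint=False)
    best = 0.0
    for shift in sg.origin_shifts:
        if not polar.any():
            best = max(best, fraction_matched(shift))
        else:
            axis = int(np.flatnonzero(polar)[0])  # one polar axis per group here
            scores = []
            for c in coarse:
                d = shift.copy()
                d[axis] = c
                if polar.sum() > 1:
                    # fully polar (P1): align remaining axes by circular mean
                    for j in np.flatnonzero(polar)[1:]:
                        d[j] = _circular_shift(x_ref[:, j], x_mov0[:, j])
                scores.append(fraction_matched(d))
            k = int(np.argmax(scores))
            best_local, step = coarse[k], 1.0 / polar_steps
            d = shift.copy()
            for fine in np.linspace(best_local - step, best_local + step, 9):
                d[axis] = fine % 1.0
                if polar.sum() > 1:
                    for j in np.flatnonzero(polar)[1:]:
                        d[j] = _circular_shift(x_ref[:, j], x_mov0[:, j])
                best = max(best, fraction_matched(d))
        if best == 1.0:
            return 1.0
    return best
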