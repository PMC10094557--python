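"""Pose refinement and solution bookkeeping: downhill-simplex rigid-body
optimization, clash fraction, the copy-acceptance rules, alaninization and
the sequence-identity / coordinate-error relation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .cell import UnitCell
from .model import AtomicModel
from .pose import Pose
from .symmetry import SpaceGroup

__all__ = [
    "SearchConfig", "Solution", "simplex_refine", "clash_fraction",
    "accept_copy", "alaninize", "chothia_lesk_rmsd",
]

CLASH_DISTANCE = 3.0  # angstrom

# side-chain atoms kept when a residue is alaninized
_ALA_KEEP = {"N", "CA", "C", "O", "CB", "OXT"}


@dataclass
class SearchConfig:
    """Thresholds and knobs of the multi-copy search (printed defaults)."""

    si: float = 1.0               # model/target sequence identity
    dtheta: float = 5.0           # rotation grid spacing, degrees
    n_keep_rot: int = 200         # orientations carried to translation
    n_keep_trans: int = 2         # translations kept per orientation
    n_carry: int = 5              # solutions carried between copies
    n_refine: int = 10            # candidates refined by simplex per copy
    clash_cutoff: float = 0.35    # hard clash rejection
    fast_accept_dr: float = 0.02  # R drop that skips the clash check
    reject_dr: float = 0.15       # R rise that rejects outright
    ratio_cutoff: float = 0.10    # (R(n)-R(n+1))/CLASH acceptance ratio
    clash_floor: float = 0.05     # clamp for the ratio test
    restart_r: float = 0.50       # final-R restart trigger
    restart_si: float = 0.40      # SI below which restart/alaninize applies
    ala_fraction: float = 0.80    # fraction of residues alaninized up front
    d_max_active: float = 7.0     # low-resolution cutoff (lifted when SI < 0.5)
    d_min_active: float = 2.5     # high-resolution cutoff
    e_max: float = 3.5            # |E| outlier rejection
    e_min: float = 0.05
    nmod: int | None = None       # override for the copy count
    seed: int = 0


@dataclass
class Solution:
    poses: list[Pose]
    rfom: float = np.nan
    tfom: float = np.nan
    clash: float = 0.0
    r: float = np.nan
    rank: int = 0
    rule: str = ""                # acceptance-rule tag of the last copy

    @property
    def n_copies(self) -> int:
        return len(self.poses)


def simplex_refine(
    pose: Pose,
    objective: Callable[[Pose], float],
    rot_step: float = 2.0,
    trans_step: float = 0.02,
    maxiter: int = 400,
) -> tuple[Pose, float]:
    """Downhill-simplex maximization of ``objective`` over the 6 pose
    parameters.  Returns (pose, score); never worse than the input pose."""
    x0 = np.concatenate([pose.euler, pose.tfrac])
    start = objective(pose)
    if not np.isfinite(start):
        warnings.warn("non-finite objective at the starting pose; refinement skipped", stacklevel=2)
        return pose.copy(), start

    def neg(x):
        val = objective(Pose(x[:3], x[3:]))
        return -val if np.isfinite(val) else 1e30

    steps = np.array([rot_step] * 3 + [trans_step] * 3)
    simplex = np.vstack([x0, x0 + np.diag(steps)])
    res = minimize(
        neg, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "maxiter": maxiter,
                 "xatol": 1e-3, "fatol": 1e-7},
    )
    best = -res.fun
    if best < start:
        return pose.copy(), start
    return Pose(res.x[:3], res.x[3:]), float(best)


def _reference_mask(model: AtomicModel) -> np.ndarray:
    """Clash reference atoms: CA for protein; P, backbone C (primed names)
    and base N for nucleic acids."""
    if model.moltype == "protein":
        return np.array([str(n).strip() == "CA" for n in model.name], dtype=bool)
    mask = np.zeros(model.n_atoms, bool)
    for i in range(model.n_atoms):
        el = str(model.element[i]).strip().upper()
        nm = str(model.name[i]).strip()
        if el == "P":
            mask[i] = True
        elif el == "C" and "'" in nm:
            mask[i] = True
        elif el == "N":
            mask[i] = True
    return mask


def clash_fraction(
    placed_models: list[AtomicModel],
    cell: UnitCell,
    sg: SpaceGroup,
    cutoff: float = CLASH_DISTANCE,
) -> float:
    """Fraction of reference atoms within ``cutoff`` of a reference atom of
    another copy or of any symmetry mate (own mates included)."""
    refs = []
    for ci, mdl in enumerate(placed_models):
        mask = _reference_mask(mdl)
        if not mask.any():
            raise ValueError(f"copy {ci} has no clash reference atoms")
        refs.append(cell.fractionalize(mdl.xyz[mask]))
    total = sum(len(x) for x in refs)
    clashed = 0
    identity = np.eye(3)
    for ci, xa in enumerate(refs):
        hit = np.zeros(len(xa), bool)
        for cj, xb in enumerate(refs):
            for rot, tran in sg.operators:
                rot = np.asarray(rot, float)
                is_identity = cj == ci and np.allclose(rot, identity) and np.allclose(tran % 1.0, 0)
                xb_op = xb @ rot.T + tran
                diff = xa[:, None, :] - xb_op[None, :, :]
                offs = np.round(diff)
                diff = diff - offs
                if is_identity:
                    # the copy against itself: only non-zero lattice offsets count
                    same_cell = np.all(offs == 0, axis=-1)
                else:
                    same_cell = np.zeros(diff.shape[:2], bool)
                d = np.linalg.norm(diff @ cell.orth.T, axis=-1)
                d[same_cell] = np.inf
                hit |= (d < cutoff).any(axis=1)
        clashed += int(hit.sum())
    return clashed / total


def accept_copy(r_n: float, r_n1: float, clash_n1: float, cfg: SearchConfig | None = None) -> tuple[bool, str]:
    """Decide whether the (n+1)th copy joins the solution.

    Rule order: a large R drop accepts outright (clash unchecked); a heavy
    clash or large R rise rejects; otherwise the R-drop/clash ratio decides,
    with the clash clamped to a floor to avoid divergence.
    """
    cfg = cfg or SearchConfig()
    if r_n - r_n1 > cfg.fast_accept_dr:
        return True, "fast"
    if clash_n1 > cfg.clash_cutoff or r_n1 - r_n > cfg.reject_dr:
        return False, "eq1"
    clash = max(clash_n1, cfg.clash_floor)
    if (r_n - r_n1) / clash > cfg.ratio_cutoff:
        return True, "eq2"
    return False, "eq2"


def alaninize(model: AtomicModel, fraction: float = 0.8) -> AtomicModel:
    """Trim side chains beyond CB for the ``fraction`` of residues with the
    largest mean B factor.  Nucleic-acid models are returned unchanged."""
    if model.moltype != "protein":
        warnings.warn("alaninization applies to protein models only; no-op", stacklevel=2)
        return model.copy()
    if fraction <= 0:
        return model.copy()
    keys = model.residue_keys()
    mean_b = {}
    for key in keys:
        mask = (model.chain == key[0]) & (model.resseq == key[1])
        mean_b[key] = float(model.b_iso[mask].mean())
    n_trim = int(round(min(1.0, fraction) * len(keys)))
    trimmed = set(sorted(keys, key=lambda k: -mean_b[k])[:n_trim])
    keep = np.ones(model.n_atoms, bool)
    for i in range(model.n_atoms):
        key = (str(model.chain[i]), int(model.resseq[i]))
        if key in trimmed and str(model.name[i]).strip() not in _ALA_KEEP:
            keep[i] = False
    return model.select(keep)


def chothia_lesk_rmsd(si: float) -> float:
    """Expected backbone coordinate error (angstrom) at sequence identity
    ``si``: rmsd = 0.40 * exp(1.87 * (1 - si))."""
    if si <= 0:
        raise ValueError("sequence identity must be positive")
    return float(0.40 * np.exp(1.87 * (1.0 - si)))
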