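"""Translation search: FFT product function, TFOM ranking, pseudo-translation.

For an oriented copy the product function

    S(t) = sum_h w_h |sum_s C_s(h) exp(2 pi i (R_s^T h) . t)|^2

expands into cross terms; the weights w_h are the corrected normalized
intensities divided by the translation-averaged model intensity
sum_s |C_s(h)|^2 (+ |F_located|^2), which keeps a handful of huge
low-resolution model terms from swamping the score.  The expansion
attaches cross coefficients C_s C_s'^* to index differences h(R_s - R_s'); scattering those
coefficients into a 3-D array and applying one inverse FFT evaluates S on
the whole translation grid at once.  Evaluation on the grid is exact:
index differences wrap modulo the grid without aliasing error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cell import UnitCell
from .reflections import ReflectionSet, calc_e2
from .sfcalc import atom_weights, symmetry_coefficients
from .symmetry import SpaceGroup

__all__ = [
    "TranslationCandidate", "TranslationMap", "translation_fft",
    "pick_translations", "tfom_corr", "detect_pseudo_translation", "tfom_pst",
]

WEAK_E = 0.3          # |E| threshold of the pseudo-translation score
MIN_WEAK = 30         # minimum weak-subset size before falling back
PST_PEAK_FRACTION = 0.2


@dataclass
class TranslationCandidate:
    euler: np.ndarray
    tfrac: np.ndarray
    product_score: float
    tfom: float = np.nan
    variant: str = "corr"


@dataclass
class TranslationMap:
    scores: np.ndarray           # (n1, n2, n3) real score map
    shape: tuple[int, int, int]
    flat: bool = False

    def argmax_frac(self) -> np.ndarray:
        idx = np.unravel_index(np.argmax(self.scores), self.shape)
        return np.array(idx, float) / np.array(self.shape)


def _fft_grid_shape(cell: UnitCell, spacing: float) -> tuple[int, int, int]:
    import scipy.fft
    dims = []
    for length in (cell.a, cell.b, cell.c):
        n = max(4, int(np.ceil(length / spacing)))
        dims.append(scipy.fft.next_fast_len(n, real=False))
    return tuple(dims)


def translation_fft(
    refl: ReflectionSet,
    x_frac: np.ndarray,
    weights_fw: np.ndarray,
    sg: SpaceGroup,
    located_f: np.ndarray | None = None,
    grid_spacing: float | None = None,
) -> TranslationMap:
    """Product-function score map over the translation grid.

    ``x_frac`` are fractional coordinates of the *oriented* copy placed at
    t = 0; ``weights_fw`` the matching (n_active, n_atoms) scattering
    weights from :func:`mrkit.sfcalc.atom_weights` (active subset rows).
    """
    cell = refl.cell
    d_min = float(refl.d[refl.active].min())
    if grid_spacing is None:
        grid_spacing = d_min / 4.0
    if grid_spacing > d_min / 3.0:
        raise ValueError(
            f"translation grid spacing {grid_spacing:.2f} A coarser than d_min/3 = {d_min / 3.0:.2f} A"
        )
    shape = _fft_grid_shape(cell, grid_spacing)
    active = refl.active
    hkl = refl.hkl[active]
    coeff, h_rot = symmetry_coefficients(x_frac, weights_fw, sg, hkl)
    h_rot = np.round(h_rot).astype(int)
    w = refl.e2[active] / _model_normalizer(coeff, located_f, active)
    grid = np.zeros(shape, complex)
    nvec = np.array(shape)
    for s in range(sg.m):
        for sp in range(sg.m):
            delta = (h_rot[s] - h_rot[sp]) % nvec
            vals = w * coeff[s] * np.conj(coeff[sp])
            np.add.at(grid, (delta[:, 0], delta[:, 1], delta[:, 2]), vals)
    if located_f is not None:
        fl = located_f[active]
        np.add.at(grid, (0, 0, 0), (w * np.abs(fl) ** 2).sum())
        for s in range(sg.m):
            idx = h_rot[s] % nvec
            vals = w * np.conj(fl) * coeff[s]
            np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), vals)
            idx_m = (-h_rot[s]) % nvec
            np.add.at(grid, (idx_m[:, 0], idx_m[:, 1], idx_m[:, 2]), np.conj(vals))
    scores = np.real(np.fft.ifftn(grid)) * grid.size
    flat = bool(scores.max() - scores.min() <= 1e-9 * max(1.0, abs(scores.max())))
    return TranslationMap(scores=scores, shape=shape, flat=flat)


def _model_normalizer(coeff: np.ndarray, located_f, active) -> np.ndarray:
    """Translation-averaged model intensity per reflection."""
    eps = (np.abs(coeff) ** 2).sum(axis=0)
    if located_f is not None:
        eps = eps + np.abs(located_f[active]) ** 2
    return np.maximum(eps, 1e-30)


def translation_direct(
    refl: ReflectionSet,
    x_frac: np.ndarray,
    weights_fw: np.ndarray,
    sg: SpaceGroup,
    tfracs: np.ndarray,
    located_f: np.ndarray | None = None,
) -> np.ndarray:
    """Direct-summation product function at arbitrary translations (oracle)."""
    active = refl.active
    hkl = refl.hkl[active]
    coeff, h_rot = symmetry_coefficients(x_frac, weights_fw, sg, hkl)
    w = refl.e2[active] / _model_normalizer(coeff, located_f, active)
    tfracs = np.atleast_2d(np.asarray(tfracs, float))
    out = np.empty(len(tfracs))
    fl = located_f[active] if located_f is not None else 0.0
    for i, t in enumerate(tfracs):
        f = (coeff * np.exp(2j * np.pi * (h_rot @ t))).sum(axis=0) + fl
        out[i] = float((w * np.abs(f) ** 2).sum())
    return out


def pick_translations(
    tmap: TranslationMap,
    sg: SpaceGroup,
    k: int = 2,
    first_copy: bool = False,
    cluster_steps: float = 1.5,
) -> list[np.ndarray]:
    """Top-k local maxima after origin-shift reduction and peak clustering.

    For the first copy in a polar space group the free translation
    components are pinned to zero (the score is invariant along them).
    """
    shape = np.array(tmap.shape)
    if tmap.flat:
        return [np.zeros(3)]
    polar = sg.polar_axes

    def canonical(tf: np.ndarray) -> tuple:
        cands = []
        for shift in sg.origin_shifts:
            v = (tf + shift) % 1.0
            cands.append(tuple(np.round(v, 4)))
        return min(cands)

    order = np.argsort(tmap.scores, axis=None)[::-1]
    picked: list[np.ndarray] = []
    for flat_idx in order[: max(2000, 50 * k)]:
        idx = np.array(np.unravel_index(flat_idx, tmap.shape), float)
        tf = idx / shape
        if first_copy:
            tf = np.where(polar, 0.0, tf)
        # cluster against picked peaks and all their origin-shifted copies
        close = False
        for p in picked:
            for s in sg.origin_shifts:
                dg = (tf - p - s) * shape
                dg -= np.round(dg / shape) * shape
                if np.linalg.norm(dg) <= cluster_steps:
                    close = True
                    break
            if close:
                break
        if close:
            continue
        picked.append(tf)
        if len(picked) >= k:
            break
    return picked


def tfom_corr(fobs: np.ndarray, f_total: np.ndarray) -> float:
    """Pearson correlation of observed amplitudes with |sum of placed F|."""
    fp = np.abs(f_total)
    a = fobs - fobs.mean()
    b = fp - fp.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        warnings.warn("zero variance in TFOM operands", stacklevel=2)
        return 0.0
    return float((a * b).sum() / denom)


def detect_pseudo_translation(refl: ReflectionSet, grid_spacing: float | None = None):
    """Sharpened-Patterson scan for pseudo-translational symmetry.

    Returns (flag, vector): flag is True when a non-origin peak of the
    E^2 - 1 synthesis exceeds 20% of the E^2 origin peak.
    """
    if refl.e2 is None:
        raise ValueError("reflection set must be normalized first")
    cell = refl.cell
    if grid_spacing is None:
        grid_spacing = max(refl.d_min / 3.0, 1.0)
    shape = _fft_grid_shape(cell, grid_spacing)
    nvec = np.array(shape)
    grid = np.zeros(shape, complex)
    act = refl.active
    hkl = refl.hkl[act]
    coeff = refl.e2[act] - 1.0
    for sign in (1, -1):
        idx = (sign * hkl) % nvec
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), coeff)
    pmap = np.real(np.fft.ifftn(grid)) * grid.size
    origin_ref = 2.0 * refl.e2[act].sum()
    # exclude a small sphere (3 A) around the origin
    fr = [np.arange(n) / n for n in shape]
    fx, fy, fz = np.meshgrid(*fr, indexing="ij")
    fcoords = np.stack([fx, fy, fz], axis=-1)
    fcoords -= np.round(fcoords)
    orth = fcoords.reshape(-1, 3) @ cell.orth.T
    dist = np.linalg.norm(orth, axis=1).reshape(shape)
    away = dist > 3.0
    if not away.any():
        return False, np.zeros(3)
    peak_idx = np.argmax(np.where(away, pmap, -np.inf))
    peak = pmap.flat[peak_idx]
    vec = np.array(np.unravel_index(peak_idx, shape), float) / nvec
    vec[vec > 0.5] -= 1.0
    return bool(peak > PST_PEAK_FRACTION * origin_ref), vec % 1.0


def tfom_pst(refl: ReflectionSet, f_total: np.ndarray, min_weak: int = MIN_WEAK) -> float:
    """Weak-reflection score 1 - <|Ep|^2> for pseudo-translated crystals.

    |Ep| is the shell-normalized calculated amplitude; the mean runs over
    reflections with observed |E| < 0.3.  Falls back to the correlation
    score when too few weak reflections exist.
    """
    if refl.e2 is None or refl.shell is None:
        raise ValueError("reflection set must be normalized first")
    act = refl.active
    weak = act & (np.sqrt(refl.e2) < WEAK_E)
    if weak.sum() < min_weak:
        warnings.warn(
            f"only {int(weak.sum())} weak reflections; falling back to the correlation score",
            stacklevel=2,
        )
        return tfom_corr(refl.fobs[act], f_total[act])
    ep2 = calc_e2(np.abs(f_total) ** 2, refl.shell)
    return float(1.0 - ep2[weak].mean())
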