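"""Diffraction anisotropy: directional von Mises fits and ellipsoid correction.

For each low-resolution "polar" direction [hkl] the reciprocal lattice is
binned into cones around that direction; the mean normalized intensity
<E^2> per cone is fitted with M = A exp(G cos 2a), where ``a`` is the cone
half-angle.  A large positive G means intensities fall off more slowly
along that direction.  Axis values feed a crystal-system-specific
ellipsoid O(hkl); corrected intensities are E^2 / O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .reflections import ReflectionSet
from .symmetry import SpaceGroup

__all__ = [
    "PolarFit", "AnisotropyField", "polar_directions", "cone_shells",
    "fit_von_mises", "build_correction", "apply_correction", "analyze",
    "SIGNIFICANCE_G",
]

SIGNIFICANCE_G = 0.2        # max |G| above which the correction is applied
DEFAULT_NSHELL = 10
PERP_TOL_DEG = (15.0, 30.0)  # widening steps for the perpendicularity search


@dataclass
class PolarFit:
    direction: tuple[int, int, int]
    G: float
    A: float
    shells: list[tuple[float, float, int]]  # (mean alpha deg, mean E2, count)
    sigma_g: float = 0.0                    # standard error of G from the fit


@dataclass
class AnisotropyField:
    system: str
    axis_dirs: np.ndarray        # (k, 3) float directions (integer for most systems)
    axis_e2: np.ndarray          # (k,) <E^2> along each axis
    fits: list[PolarFit]
    significant: bool
    cell: UnitCell

    def correction(self, hkl: np.ndarray) -> np.ndarray:
        """Ellipsoid surface O(hkl) combining the axis <E^2> values with
        cos^2 direction weights.

        The combination is done on the logarithmic scale,
        ln O = sum_i ln<E^2>_i cos^2(theta_i), which is the form consistent
        with the exponential directional law M = exp(G cos 2a); to first
        order in the anisotropy it coincides with the plain weighted sum of
        <E^2> values, but it leaves no quartic residual for an imposed
        Gaussian (overall anisotropic B) falloff.
        """
        hkl = np.atleast_2d(np.asarray(hkl, float))
        if len(self.axis_dirs) == 0:
            return np.ones(len(hkl))
        q = self.cell.recip_vectors(hkl)
        qn = q / np.linalg.norm(q, axis=1, keepdims=True)
        log_o = np.zeros(len(hkl))
        for d, e2 in zip(self.axis_dirs, self.axis_e2):
            v = self.cell.recip_vectors(np.asarray(d, float))[0]
            v = v / np.linalg.norm(v)
            log_o += np.log(e2) * (qn @ v) ** 2
        return np.exp(log_o)


def _direction_angle_cos(cell: UnitCell, d1, d2) -> float:
    v1 = cell.recip_vectors(np.asarray(d1, float))[0]
    v2 = cell.recip_vectors(np.asarray(d2, float))[0]
    return float(abs(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))


def polar_directions(cell: UnitCell, sg: SpaceGroup, n: int = 30) -> list[tuple[int, int, int]]:
    """Low-resolution coprime directions, unique up to inversion and point symmetry.

    The three reciprocal axes are always included when symmetry-distinct;
    remaining slots are filled lowest-resolution-first from |h|,|k|,|l| <= 2.
    """
    laue = sg.laue_rotations
    seen: dict[tuple, tuple[int, int, int]] = {}

    def canon(d: np.ndarray) -> tuple:
        orbit = []
        for r in laue:
            img = d @ r  # direction transforms with R^T: rows h -> h R
            img = np.round(img).astype(int)
            orbit.append(tuple(img))
            orbit.append(tuple(-img))
        return max(orbit)

    cands = []
    for h in range(-2, 3):
        for k in range(-2, 3):
            for l in range(-2, 3):
                d = np.array([h, k, l])
                if not d.any():
                    continue
                if np.gcd.reduce(np.abs(d)[np.abs(d) > 0]) != 1:
                    continue
                cands.append(d)
    axes = [np.array(a) for a in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
    ordered = axes + sorted(
        (c for c in cands), key=lambda c: -cell.d_values(c)[0]
    )
    out: list[tuple[int, int, int]] = []
    for d in ordered:
        key = canon(d)
        if key in seen:
            continue
        seen[key] = tuple(int(x) for x in d)
        out.append(seen[key])
        if len(out) >= n:
            break
    return out


def cone_shells(
    refl: ReflectionSet,
    direction,
    nshell: int = DEFAULT_NSHELL,
) -> list[tuple[float, float, int]]:
    """Equal-population cone shells around a polar direction.

    Returns (mean alpha in degrees, mean E^2, count) per shell, ordered by
    increasing alpha; alpha is folded to [0, 90] (Friedel symmetry).
    """
    if refl.e2 is None:
        raise ValueError("reflection set must be normalized first")
    act = refl.active
    q = refl.cell.recip_vectors(refl.hkl[act])
    v = refl.cell.recip_vectors(np.asarray(direction, float))[0]
    cosa = np.abs(q @ v) / (np.linalg.norm(q, axis=1) * np.linalg.norm(v))
    alpha = np.degrees(np.arccos(np.clip(cosa, -1, 1)))
    e2 = refl.e2[act]
    n = len(alpha)
    if n < nshell * 10:
        new = max(1, n // 10)
        warnings.warn(f"only {n} reflections: reducing cone shells {nshell} -> {new}", stacklevel=2)
        nshell = new
    order = np.argsort(alpha)
    shells = []
    for chunk in np.array_split(order, nshell):
        shells.append((float(alpha[chunk].mean()), float(e2[chunk].mean()), len(chunk)))
    return shells


def fit_von_mises(shells, with_uncertainty: bool = False):
    """Weighted least-squares fit of ln<E^2> = ln A + G cos 2a.

    Returns (G, A), or (G, A, sigma_G) with ``with_uncertainty``; shells
    with non-positive mean E^2 are dropped with a warning.
    """
    shells = [s for s in shells]
    kept = [(a, m, c) for a, m, c in shells if m > 0]
    if len(kept) < len(shells):
        warnings.warn("dropping cone shells with non-positive mean E^2", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("need at least two usable cone shells")
    alpha = np.radians([a for a, _, _ in kept])
    y = np.log([m for _, m, _ in kept])
    counts = np.array([c for _, _, c in kept], float)
    x = np.cos(2 * alpha)
    design = np.column_stack([np.ones_like(x), x])
    # ln of a shell mean of N exponential draws has variance ~ 1/N
    wvar = 1.0 / counts
    wd = design / np.sqrt(wvar)[:, None]
    coef, *_ = np.linalg.lstsq(wd, y / np.sqrt(wvar), rcond=None)
    ln_a, g = coef
    if not with_uncertainty:
        return float(g), float(np.exp(ln_a))
    try:
        cov = np.linalg.inv(wd.T @ wd)
        sigma_g = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        sigma_g = np.inf
    return float(g), float(np.exp(ln_a)), sigma_g


def _axis_e2(fit: PolarFit) -> float:
    """<E^2> along the fitted direction, evaluated from the whole fit at a = 0."""
    return fit.A * np.exp(fit.G)


def _most_perpendicular(cell, dirs, ref_dirs, tol_steps=PERP_TOL_DEG):
    """Pick the direction most perpendicular to all of ``ref_dirs``.

    Directions outside the current tolerance are skipped; the tolerance
    widens stepwise (with a warning) if nothing qualifies, and as a last
    resort the least-bad direction is returned.
    """
    def worst_dev(d):
        return max(
            90.0 - np.degrees(np.arccos(np.clip(
                _direction_angle_cos(cell, d.direction, r.direction), 0, 1)))
            for r in ref_dirs
        )

    for tol in tol_steps:
        ok = [d for d in dirs if worst_dev(d) <= tol]
        if ok:
            if tol != tol_steps[0]:
                warnings.warn(f"perpendicularity tolerance widened to {tol} degrees", stacklevel=2)
            return max(ok, key=lambda d: abs(d.G))
    warnings.warn("no near-perpendicular direction found; using the least oblique", stacklevel=2)
    return min(dirs, key=worst_dev)


def _refine_axis_e2(
    axes: np.ndarray,
    groups: list[int],
    e2_start: np.ndarray,
    fits: list[PolarFit],
    cell: UnitCell,
) -> np.ndarray:
    """Weighted LSQ of all directional <E^2> measurements on the ellipsoid.

    ``groups`` maps each axis to a free parameter (symmetry-equal axes share
    one); the direct axis evaluations are the fallback when the fit is
    degenerate or non-positive.
    """
    n_par = max(groups) + 1
    qn_ax = []
    for d in axes:
        v = cell.recip_vectors(np.asarray(d, float))[0]
        qn_ax.append(v / np.linalg.norm(v))
    rows, vals, wts = [], [], []
    for f in fits:
        v = cell.recip_vectors(np.asarray(f.direction, float))[0]
        v = v / np.linalg.norm(v)
        row = np.zeros(n_par)
        for ax_i, par in enumerate(groups):
            row[par] += float((v @ qn_ax[ax_i]) ** 2)
        rows.append(row)
        vals.append(np.log(max(_axis_e2(f), 1e-6)))  # log scale, see correction()
        wts.append(sum(c for _, _, c in f.shells) or 1.0)
    w = np.sqrt(wts)
    try:
        sol, *_ = np.linalg.lstsq(np.array(rows) * w[:, None], np.array(vals) * w, rcond=None)
    except np.linalg.LinAlgError:
        return e2_start
    if np.any(~np.isfinite(sol)):
        return e2_start
    e2 = np.exp(np.array([sol[par] for par in groups]))
    if np.any(e2 <= 0.05) or np.any(e2 > 20):
        return e2_start
    return e2


def build_correction(fits: list[PolarFit], cell: UnitCell, sg: SpaceGroup) -> AnisotropyField:
    """Assemble the per-crystal-system ellipsoid from directional fits.

    The axis directions follow the crystal system's symmetry constraints;
    the axis <E^2> values start from the von Mises fits evaluated at the
    axes and are refined by least squares over every fitted direction.
    """
    system = sg.crystal_system
    by_dir = {tuple(f.direction): f for f in fits}
    # significant anisotropy: a G beyond the threshold that is also well
    # above its own fit uncertainty (guards small noisy data sets)
    significant = any(
        abs(f.G) > SIGNIFICANCE_G and abs(f.G) > 3.0 * f.sigma_g for f in fits
    )

    def need(d):
        f = by_dir.get(tuple(d))
        if f is None:
            raise ValueError(f"missing polar fit for required axis {d}")
        return f

    if system == "cubic":
        return AnisotropyField(system=system, axis_dirs=np.zeros((0, 3)),
                               axis_e2=np.zeros(0), fits=fits,
                               significant=False, cell=cell)
    if system in ("trigonal", "hexagonal"):
        fa, fc = need((1, 0, 0)), need((0, 0, 1))
        axes = np.array([(1, 0, 0), (1, -2, 0), (0, 0, 1)], float)
        groups = [0, 0, 1]
        e2 = np.array([_axis_e2(fa), _axis_e2(fa), _axis_e2(fc)])
    elif system == "tetragonal":
        fa, fc = need((1, 0, 0)), need((0, 0, 1))
        axes = np.array([(1, 0, 0), (0, 1, 0), (0, 0, 1)], float)
        groups = [0, 0, 1]
        e2 = np.array([_axis_e2(fa), _axis_e2(fa), _axis_e2(fc)])
    elif system == "orthorhombic":
        fs = [need((1, 0, 0)), need((0, 1, 0)), need((0, 0, 1))]
        axes = np.eye(3)
        groups = [0, 1, 2]
        e2 = np.array([_axis_e2(f) for f in fs])
    elif system == "monoclinic":
        fb = need((0, 1, 0))
        plane = [f for f in fits if f.direction[1] == 0]
        if not plane:
            raise ValueError("monoclinic correction needs [h0l] polar fits")
        f1 = max(plane, key=lambda f: abs(f.G))
        rest = [f for f in plane if f is not f1]
        f2 = _most_perpendicular(cell, rest, [f1]) if rest else f1
        axes = np.array([f1.direction, (0, 1, 0), f2.direction], float)
        groups = [0, 1, 2]
        e2 = np.array([_axis_e2(f1), _axis_e2(fb), _axis_e2(f2)])
    else:  # triclinic
        f1 = max(fits, key=lambda f: abs(f.G))
        rest = [f for f in fits if f is not f1]
        f2 = _most_perpendicular(cell, rest, [f1])
        rest2 = [f for f in rest if f is not f2]
        f3 = _most_perpendicular(cell, rest2, [f1, f2]) if rest2 else f2
        axes = np.array([f1.direction, f2.direction, f3.direction], float)
        groups = [0, 1, 2]
        e2 = np.array([_axis_e2(f1), _axis_e2(f2), _axis_e2(f3)])

    e2 = _refine_axis_e2(axes, groups, e2, fits, cell)
    return AnisotropyField(system=system, axis_dirs=axes, axis_e2=e2,
                           fits=fits, significant=significant, cell=cell)


def apply_correction(refl: ReflectionSet, field: AnisotropyField) -> ReflectionSet:
    """Divide E^2 by O(hkl); identity when the field is insignificant.

    The corrected values are re-normalized within the existing resolution
    shells so <E^2> stays at 1.
    """
    out = refl.copy()
    if not field.significant or len(field.axis_dirs) == 0:
        return out
    o = field.correction(out.hkl)
    if np.any(o <= 0):
        raise ValueError("non-positive anisotropy correction encountered")
    out.e2 = out.e2 / o
    if out.shell is not None:
        from .reflections import calc_e2
        out.e2 = calc_e2(out.e2, out.shell)
    return out


def analyze(
    refl: ReflectionSet,
    n_directions: int = 30,
    nshell: int = DEFAULT_NSHELL,
) -> AnisotropyField:
    """Fit all polar directions and assemble the correction field."""
    dirs = polar_directions(refl.cell, refl.sg, n_directions)
    fits = []
    for d in dirs:
        shells = cone_shells(refl, d, nshell)
        g, a, sig = fit_von_mises(shells, with_uncertainty=True)
        fits.append(PolarFit(direction=d, G=g, A=a, shells=shells, sigma_g=sig))
    return build_correction(fits, refl.cell, refl.sg)
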