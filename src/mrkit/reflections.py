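"""Reflection data: indexed amplitudes, Wilson normalization, I/O.

Text format is one record per line, ``h k l F sigF``, ``#`` comments.
MTZ files are read and written through gemmi with configurable column
labels (default ``H K L F SIGF``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroup

__all__ = ["ReflectionSet", "read_text", "write_text", "read_mtz", "write_mtz", "normalize"]


@dataclass
class ReflectionSet:
    """Unique asymmetric-unit reflections with cell/symmetry context."""

    cell: UnitCell
    sg: SpaceGroup
    hkl: np.ndarray                      # (n, 3) int
    fobs: np.ndarray                     # (n,)
    sigf: np.ndarray                     # (n,)
    d: np.ndarray = None                 # (n,) resolution, filled if None
    e2: np.ndarray = None                # normalized squared amplitudes
    active: np.ndarray = None            # working-set flags
    shell: np.ndarray = None             # shell index from the last normalize
    eps: np.ndarray = None               # symmetry-enhancement (epsilon) factors

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.fobs = np.asarray(self.fobs, float)
        self.sigf = np.asarray(self.sigf, float)
        n = len(self.hkl)
        if self.d is None:
            self.d = self.cell.d_values(self.hkl)
        if self.active is None:
            self.active = np.ones(n, bool)
        if np.any(self.d <= 0):
            raise ValueError("non-positive resolution")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def n(self) -> int:
        return len(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.sg, self.hkl.copy(), self.fobs.copy(), self.sigf.copy(),
            self.d.copy(),
            None if self.e2 is None else self.e2.copy(),
            self.active.copy(),
            None if self.shell is None else self.shell.copy(),
            None if self.eps is None else self.eps.copy(),
        )

    def merge_asu(self) -> "ReflectionSet":
        """Reduce indices to asu representatives and average duplicates."""
        reduced = self.sg.asu_reduce(self.hkl)
        keys = {}
        order = []
        for i, h in enumerate(map(tuple, reduced)):
            if h not in keys:
                keys[h] = []
                order.append(h)
            keys[h].append(i)
        hkl = np.array(order, int)
        fobs = np.array([self.fobs[keys[h]].mean() for h in order])
        sigf = np.array([self.sigf[keys[h]].mean() for h in order])
        return ReflectionSet(self.cell, self.sg, hkl, fobs, sigf)


def _equal_population_shells(order_values: np.ndarray, nshell: int) -> np.ndarray:
    """Shell index per reflection; shells equal-populated in sorted order."""
    n = len(order_values)
    order = np.argsort(order_values)[::-1]  # low resolution (large d) first
    shell = np.empty(n, int)
    bounds = np.linspace(0, n, nshell + 1).astype(int)
    for k in range(nshell):
        shell[order[bounds[k]:bounds[k + 1]]] = k
    return shell


def normalize(refl: ReflectionSet, nshell: int = 20) -> ReflectionSet:
    """Fill E^2 by shell-wise scaling: E^2 = F^2 / (eps <F^2/eps>_shell).

    ``eps`` is the symmetry-enhancement factor of the reflection class
    (reflections on rotation/screw zones have eps-fold expected intensity);
    dividing it out makes <E^2> = 1 for every class.  Resolution shells are
    equal-population; the shell count is reduced with a warning when the
    data are too few (floor of one shell).
    """
    out = refl.copy()
    n = len(out)
    if n == 0:
        raise ValueError("empty reflection set")
    if n < nshell * 20:
        nshell_new = max(1, n // 20)
        warnings.warn(
            f"{n} reflections support only {nshell_new} shells (requested {nshell})",
            stacklevel=2,
        )
        nshell = nshell_new
    shell = _equal_population_shells(out.d, nshell)
    if out.eps is None:
        out.eps = out.sg.epsilon_factors(out.hkl)
    f2eps = out.fobs**2 / out.eps
    e2 = np.empty(n, float)
    for k in range(nshell):
        sel = shell == k
        mean = f2eps[sel].mean()
        if mean <= 0:
            raise ValueError(f"shell {k} has non-positive mean intensity")
        e2[sel] = f2eps[sel] / mean
    out.e2 = e2
    out.shell = shell
    return out


def calc_e2(values2: np.ndarray, shell: np.ndarray) -> np.ndarray:
    """Normalize arbitrary squared amplitudes within pre-assigned shells."""
    out = np.empty_like(values2, dtype=float)
    for k in np.unique(shell):
        sel = shell == k
        mean = values2[sel].mean()
        out[sel] = values2[sel] / mean if mean > 0 else 0.0
    return out


# ---------------------------------------------------------------- text I/O

def read_text(path: str, cell: UnitCell, sg: SpaceGroup) -> ReflectionSet:
    hkl, f, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 'h k l F sigF'")
            hkl.append([int(parts[0]), int(parts[1]), int(parts[2])])
            f.append(float(parts[3]))
            sig.append(float(parts[4]))
    if not hkl:
        raise ValueError(f"{path}: no reflections")
    return ReflectionSet(cell, sg, np.array(hkl), np.array(f), np.array(sig)).merge_asu()


def write_text(refl: ReflectionSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# h k l F sigF\n")
        for (h, k, l), f, s in zip(refl.hkl, refl.fobs, refl.sigf):
            fh.write(f"{h:5d} {k:5d} {l:5d} {f:14.6f} {s:12.6f}\n")


# ----------------------------------------------------------------- MTZ I/O

def read_mtz(path: str, labels: tuple[str, str] = ("F", "SIGF")) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    cell = UnitCell(mtz.cell.a, mtz.cell.b, mtz.cell.c, mtz.cell.alpha, mtz.cell.beta, mtz.cell.gamma)
    sg = SpaceGroup(mtz.spacegroup.hm)
    arr = np.array(mtz, copy=True)
    cols = [c.label for c in mtz.columns]
    try:
        idx = [cols.index(x) for x in ("H", "K", "L", labels[0], labels[1])]
    except ValueError as exc:
        raise ValueError(f"MTZ columns {cols} lack requested labels {labels}") from exc
    data = arr[:, idx]
    data = data[~np.isnan(data[:, 3])]
    return ReflectionSet(cell, sg, data[:, :3].astype(int), data[:, 3], data[:, 4]).merge_asu()


def write_mtz(refl: ReflectionSet, path: str, labels: tuple[str, str] = ("F", "SIGF")) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.cell = gemmi.UnitCell(*refl.cell.parameters())
    mtz.spacegroup = gemmi.find_spacegroup_by_name(refl.sg.symbol)
    mtz.add_dataset("mrkit")
    mtz.add_column(labels[0], "F")
    mtz.add_column(labels[1], "Q")
    data = np.column_stack([refl.hkl.astype(float), refl.fobs, refl.sigf])
    mtz.set_data(data)
    mtz.write_to_file(str(path))
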