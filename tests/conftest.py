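import warnings

import numpy as np
import pytest

from mrkit.cell import UnitCell
from mrkit.model import AtomicModel
from mrkit.reflections import ReflectionSet, normalize
from mrkit.symmetry import SpaceGroup


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(10, 10, 10)


@pytest.fixture(scope="session")
def ortho_cell():
    return UnitCell(10, 20, 30)


@pytest.fixture(scope="session")
def p1():
    return SpaceGroup("P 1")


@pytest.fixture(scope="session")
def p212121():
    return SpaceGroup("P 21 21 21")


@pytest.fixture(scope="session")
def p21():
    return SpaceGroup("P 1 21 1")


def make_model(xyz, elements=None, b=None, occ=None, moltype="protein", names=None):
    """Tiny helper to assemble ad-hoc models in tests."""
    xyz = np.asarray(xyz, float).reshape(-1, 3)
    n = len(xyz)
    elements = np.array(elements if elements is not None else ["C"] * n, object)
    names = np.array(names if names is not None else ["CA"] * n, object)
    return AtomicModel(
        element=elements, xyz=xyz,
        b_iso=np.asarray(b if b is not None else np.zeros(n), float),
        occ=np.asarray(occ if occ is not None else np.ones(n), float),
        chain=np.array(["A"] * n, object),
        resseq=np.arange(1, n + 1),
        resname=np.array(["ALA"] * n, object),
        name=names, moltype=moltype,
    )


@pytest.fixture(scope="session")
def wilson_reflections(p1):
    """Synthetic acentric Wilson amplitudes in a 30 A cubic cell."""
    rng = np.random.default_rng(42)
    cell = UnitCell(30, 30, 30)
    hkl = np.unique(rng.integers(-9, 10, size=(8000, 3)), axis=0)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    f = np.sqrt(rng.exponential(size=len(hkl)))
    refl = ReflectionSet(cell, p1, hkl, f, 0.01 * f).merge_asu()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return normalize(refl)
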