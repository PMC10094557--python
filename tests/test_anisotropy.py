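import warnings

import numpy as np
import pytest

from mrkit.anisotropy import (
    PolarFit, analyze, apply_correction, build_correction, cone_shells,
    fit_von_mises, polar_directions,
)
from mrkit.cell import UnitCell
from mrkit.reflections import ReflectionSet, normalize
from mrkit.symmetry import SpaceGroup


def _make_refl(cell, sg, e2_func, seed=0, hmax=9):
    """Reflection set whose E^2 follows e2_func(hkl) times Wilson noise."""
    rng = np.random.default_rng(seed)
    hs = np.arange(-hmax, hmax + 1)
    hkl = np.array([[h, k, l] for h in hs for k in hs for l in range(0, hmax + 1)])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    hkl = np.unique(sg.asu_reduce(hkl), axis=0)
    shape = e2_func(hkl)
    f = np.sqrt(shape * rng.exponential(size=len(hkl)))
    refl = ReflectionSet(cell, sg, hkl, f, 0.01 * f)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return normalize(refl)


class TestPolarDirections:
    def test_triclinic_starts_with_axes(self):
        cell = UnitCell(20, 21, 22, 85, 95, 93)
        dirs = polar_directions(cell, SpaceGroup("P 1"))
        assert dirs[:3] == [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        assert len(dirs) <= 30

    def test_cubic_symmetry_collapses_axes(self):
        cell = UnitCell(20, 20, 20)
        dirs = polar_directions(cell, SpaceGroup("P 21 3"))
        axes = [d for d in dirs if sorted(np.abs(d)) == [0, 0, 1]]
        assert len(axes) == 1

    def test_unique_up_to_inversion(self):
        cell = UnitCell(20, 21, 22)
        dirs = polar_directions(cell, SpaceGroup("P 1"))
        keys = {tuple(d) for d in dirs} | {tuple(-np.array(d)) for d in dirs}
        assert len(keys) == 2 * len(dirs)


class TestConeShells:
    def test_isotropic_means_near_one(self, p1):
        cell = UnitCell(25, 25, 25)
        refl = _make_refl(cell, p1, lambda h: np.ones(len(h)))
        shells = cone_shells(refl, (0, 0, 1), nshell=8)
        for _, mean_e2, _ in shells:
            assert mean_e2 == pytest.approx(1.0, abs=0.15)

    def test_equal_population(self, p1):
        cell = UnitCell(25, 25, 25)
        refl = _make_refl(cell, p1, lambda h: np.ones(len(h)))
        counts = [c for _, _, c in cone_shells(refl, (1, 0, 0), nshell=10)]
        assert max(counts) - min(counts) <= 1

    def test_imposed_profile_orders_means(self, p1):
        cell = UnitCell(25, 25, 25)

        def profile(hkl):
            q = hkl @ cell.frac
            cos2 = (q[:, 0] / np.linalg.norm(q, axis=1)) ** 2
            alpha = np.arccos(np.clip(np.sqrt(cos2), 0, 1))
            return np.exp(0.6 * np.cos(2 * alpha))

        refl = _make_refl(cell, p1, profile, seed=1)
        shells = cone_shells(refl, (1, 0, 0), nshell=8)
        means = [m for _, m, _ in shells]
        assert means[0] > means[-1]  # stronger along the polar axis


class TestVonMisesFit:
    def test_flat_shells_give_zero_g(self):
        shells = [(a, 1.0, 100) for a in (10, 30, 50, 70, 85)]
        g, a = fit_von_mises(shells)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(1.0, abs=1e-12)

    def test_exact_inversion_of_generating_model(self):
        alphas = np.array([5, 20, 40, 60, 80.0])
        shells = [(a, np.exp(0.5 * np.cos(2 * np.radians(a))), 50) for a in alphas]
        g, amp = fit_von_mises(shells)
        assert g == pytest.approx(0.5, abs=1e-6)
        assert amp == pytest.approx(1.0, abs=1e-6)

    def test_sign_convention_positive_g_means_strong_axis(self):
        alphas = np.array([5, 20, 40, 60, 80.0])
        shells = [(a, np.exp(0.8 * np.cos(2 * np.radians(a))), 50) for a in alphas]
        g, amp = fit_von_mises(shells)
        assert g > 0
        assert amp * np.exp(g) > 1.0  # <E^2> at alpha=0 exceeds 1

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2)
        errs = []
        for _ in range(20):
            alphas = np.linspace(5, 85, 10)
            true = np.exp(0.5 * np.cos(2 * np.radians(alphas)))
            n = 500
            means = true * rng.exponential(size=(n, 10)).mean(axis=0)
            g, _ = fit_von_mises([(a, m, n) for a, m in zip(alphas, means)])
            errs.append(abs(g - 0.5) / 0.5)
        assert np.mean(errs) < 0.10


class TestCorrectionField:
    def _fit(self, direction, g, a=1.0):
        return PolarFit(direction=tuple(direction), G=g, A=a, shells=[])

    def test_flat_g_insignificant(self):
        cell = UnitCell(20, 24, 30)
        sg = SpaceGroup("P 21 21 21")
        fits = [self._fit(d, 0.01) for d in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        field = build_correction(fits, cell, sg)
        assert not field.significant

    def test_orthorhombic_unit_axes_give_unit_o(self):
        cell = UnitCell(20, 24, 30)
        sg = SpaceGroup("P 21 21 21")
        fits = [self._fit(d, 0.0, 1.0) for d in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        field = build_correction(fits, cell, sg)
        hkl = np.array([[1, 2, 3], [5, 0, 2], [0, 0, 4], [2, 2, 2]])
        assert np.allclose(field.correction(hkl), 1.0, atol=1e-12)

    def test_axis_reflection_gets_axis_value(self):
        cell = UnitCell(20, 24, 30)
        sg = SpaceGroup("P 21 21 21")
        fits = [self._fit((1, 0, 0), np.log(2.0), 1.0),
                self._fit((0, 1, 0), 0.0, 1.0), self._fit((0, 0, 1), 0.0, 1.0)]
        field = build_correction(fits, cell, sg)
        assert field.correction([[4, 0, 0]])[0] == pytest.approx(2.0, rel=1e-9)

    def test_o_invariant_under_point_symmetry(self):
        cell = UnitCell(20, 24, 30)
        sg = SpaceGroup("P 21 21 21")
        fits = [self._fit((1, 0, 0), 0.4, 1.1), self._fit((0, 1, 0), -0.3, 0.9),
                self._fit((0, 0, 1), 0.1, 1.0)]
        field = build_correction(fits, cell, sg)
        hkl = np.array([[1, 2, 3], [3, 1, 2], [2, 5, 1]])
        o0 = field.correction(hkl)
        for rot, _ in sg.operators:
            o_eq = field.correction(hkl @ np.asarray(rot, float))
            assert np.allclose(o_eq, o0, atol=1e-9)


def _dense_refl(cell, sg, d_min=1.8):
    hm = [int(np.floor(L / d_min)) + 1 for L in (cell.a, cell.b, cell.c)]
    hkl = np.array(np.meshgrid(
        np.arange(-hm[0], hm[0] + 1), np.arange(-hm[1], hm[1] + 1), np.arange(0, hm[2] + 1),
    )).reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = np.linalg.norm(hkl @ cell.frac, axis=1)
    return np.unique(sg.asu_reduce(hkl[q <= 1 / d_min]), axis=0)


class TestRoundTrip:
    def test_imposed_anisotropy_detected_and_flattened(self, p212121):
        """Overall anisotropic B of a few angstrom^2 (a mild, realistic
        level): detected (max |G| > 0.2), then the corrected data refit to
        |G| < 0.05 with global <E^2> ~ 1."""
        cell = UnitCell(60, 64, 70)
        hkl = _dense_refl(cell, p212121)
        b1, b3 = 2.0 / cell.a**2, -1.5 / cell.c**2
        rng = np.random.default_rng(3)
        f = np.sqrt(rng.exponential(size=len(hkl)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refl = normalize(ReflectionSet(cell, p212121, hkl, f, 0.01 * f))
        refl.e2 = refl.e2 * np.exp(-(b1 * hkl[:, 0] ** 2 + b3 * hkl[:, 2] ** 2))
        field = analyze(refl)
        gmax = max(abs(ft.G) for ft in field.fits)
        assert gmax > 0.2
        assert field.significant
        corrected = apply_correction(refl, field)
        assert len(corrected) == len(refl)
        refit = analyze(corrected)
        assert max(abs(ft.G) for ft in refit.fits) < 0.05
        assert corrected.e2.mean() == pytest.approx(1.0, abs=0.05)

    def test_insignificant_field_is_identity(self, p212121):
        cell = UnitCell(60, 64, 70)
        hkl = _dense_refl(cell, p212121, d_min=2.5)
        rng = np.random.default_rng(4)
        f = np.sqrt(rng.exponential(size=len(hkl)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refl = normalize(ReflectionSet(cell, p212121, hkl, f, 0.01 * f))
        field = analyze(refl)
        assert not field.significant
        corrected = apply_correction(refl, field)
        assert np.array_equal(corrected.e2, refl.e2)
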