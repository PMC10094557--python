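import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mrkit.fixtures import make_fixture, make_polymer
from mrkit.reflections import normalize
from mrkit.rotation import (
    build_molecular_transform, covering_radius, euler_to_matrix,
    expected_intensity, generate_rotation_grid, rfom, search_orientations,
)
from mrkit.sfcalc import calc_structure_factors
from mrkit.symmetry import SpaceGroup

from conftest import make_model


@pytest.fixture(scope="module")
def small_fixture():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fx = make_fixture("P212121", n_copies=1, seed=3)
        refl = normalize(fx.refl)
    refl.active &= refl.d >= 2.5
    return fx, refl


class TestRotationGrid:
    def test_primitive_covering_radius(self):
        assert covering_radius("primitive") == pytest.approx(np.sqrt(3) / 2, abs=1e-3)

    def test_bcc_covering_radius(self):
        r = covering_radius("bcc")
        assert r == pytest.approx(np.sqrt(5) / 4, abs=1e-3)
        assert r <= 0.56

    def test_bcc_doubles_point_count(self, p1):
        prim = generate_rotation_grid(p1, 15.0, "primitive")
        bcc = generate_rotation_grid(p1, 15.0, "bcc")
        assert len(bcc.points) == 2 * len(prim.points)

    def test_symmetry_reduction_shrinks_grid(self, p212121):
        cell_mod = __import__("mrkit.cell", fromlist=["UnitCell"]).UnitCell(20, 24, 30)
        full = generate_rotation_grid(p212121, 15.0, "primitive")
        red = generate_rotation_grid(p212121, 15.0, "primitive", cell=cell_mod)
        assert len(red.points) < len(full.points)
        # 222 proper rotations: roughly a four-fold reduction
        assert len(red.points) == pytest.approx(len(full.points) / 4, rel=0.2)

    def test_invalid_dtheta(self, p1):
        with pytest.raises(ValueError):
            generate_rotation_grid(p1, 45.0)


class TestMolecularTransform:
    def test_box_edge_is_four_times_max_dimension(self):
        model = make_polymer("protein", 10, seed=0)
        tr = build_molecular_transform(model, d_min=2.5)
        assert tr.box == pytest.approx(4 * model.centered().max_dimension())

    def test_exact_grid_point_matches_direct_value(self, p1):
        from mrkit.cell import UnitCell
        model = make_polymer("protein", 8, seed=1).centered()
        tr = build_molecular_transform(model, d_min=3.0)
        # pick an in-sphere grid point and compare with a P1 box calculation
        h = np.array([3, -2, 4])
        box_cell = UnitCell(tr.box, tr.box, tr.box)
        f_direct = np.abs(calc_structure_factors(model, box_cell, SpaceGroup("P 1"), [h]))[0]
        f_interp = tr.interpolate((h / tr.box).reshape(1, 3))[0]
        assert f_interp == pytest.approx(f_direct, rel=1e-10)

    def test_offgrid_interpolation_close_to_direct_sum(self):
        from mrkit.cell import UnitCell
        model = make_polymer("protein", 8, seed=1).centered()
        tr = build_molecular_transform(model, d_min=3.0)
        rng = np.random.default_rng(0)
        # random reciprocal points inside the data sphere
        q = rng.normal(size=(100, 3))
        q = q / np.linalg.norm(q, axis=1, keepdims=True) * rng.uniform(0.05, 1 / 3.2, (100, 1))
        box_cell = UnitCell(tr.box, tr.box, tr.box)
        f_direct = np.abs(calc_structure_factors(model, box_cell, SpaceGroup("P 1"), q * tr.box))
        f_interp = tr.interpolate(q)
        scale = np.abs(f_direct).max()
        assert np.abs(f_interp - f_direct).max() / scale < 0.02

    def test_single_atom_floors_box_with_warning(self):
        model = make_model([[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="10 angstrom"):
            tr = build_molecular_transform(model, d_min=3.0)
        assert tr.box == pytest.approx(40.0)


class TestExpectedIntensity:
    def test_no_located_copies_is_incoherent_symmetry_sum(self, small_fixture):
        fx, refl = small_fixture
        tr = build_molecular_transform(fx.target_model.centered(), refl.d[refl.active].min())
        euler = fx.true_poses[0].euler
        none_path = expected_intensity(euler, tr, None, refl, refl.sg)
        zeros = expected_intensity(euler, tr, np.zeros(len(refl), complex), refl, refl.sg)
        assert np.array_equal(none_path, zeros)  # located sum of zero adds nothing

    def test_located_contribution_is_additive_coherent_square(self, small_fixture):
        fx, refl = small_fixture
        tr = build_molecular_transform(fx.target_model.centered(), refl.d[refl.active].min())
        located = np.linspace(1, 2, len(refl)) * np.exp(1j * 0.3)
        euler = (10.0, 20.0, 30.0)
        with_loc = expected_intensity(euler, tr, located, refl, refl.sg)
        without = expected_intensity(euler, tr, None, refl, refl.sg)
        expected_delta = np.abs(located[refl.active]) ** 2 / refl.eps[refl.active]
        assert np.allclose(with_loc - without, expected_delta)


class TestRfom:
    def test_perfect_agreement(self):
        x = np.linspace(1, 5, 100)
        assert rfom(x, x.copy()) == pytest.approx(1.0)

    def test_permuted_values_uncorrelated(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=10_000)
        y = rng.permutation(x)
        assert abs(rfom(x, y)) < 0.03

    def test_matches_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 9.0])
        xm, ym = x - x.mean(), y - y.mean()
        expected = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert rfom(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert rfom(np.ones(60), np.arange(60.0)) == 0.0


class TestOrientationSearch:
    def test_true_orientation_found_and_decoy_scores_below(self, small_fixture):
        """On noise-free data the top cluster lies within the bcc covering
        radius of the truth and outranks a 20-degree decoy."""
        fx, refl = small_fixture
        cell, sg = refl.cell, refl.sg
        tr = build_molecular_transform(fx.target_model.centered(), float(refl.d[refl.active].min()))
        grid = generate_rotation_grid(sg, 10.0, "bcc", cell)
        cands = search_orientations(refl, tr, None, grid, sg)
        assert len(cands) <= 200
        assert all(a.rfom >= b.rfom for a, b in zip(cands, cands[1:]))

        w_true = fx.true_poses[0].matrix()

        def ang_to_true(euler):
            w = euler_to_matrix(euler)
            best = 180.0
            for r in sg.proper_rotations:
                s = cell.orth @ r @ cell.frac
                c = (np.trace(s @ w @ w_true.T) - 1) / 2
                best = min(best, np.degrees(np.arccos(np.clip(c, -1, 1))))
            return best

        # the cluster carried to the translation step must contain the truth
        dists = [ang_to_true(c.euler) for c in cands[:20]]
        assert min(dists) <= 0.56 * 10.0 * 1.35  # covering radius + slack
        # ... and near the top of the list
        assert int(np.argmin(dists)) < 5

        # a 20-degree-off decoy must not outrank the true-orientation score
        decoy = Rotation.from_matrix(w_true).as_euler("zyz", degrees=True) + np.array([20.0, 0, 0])
        decoy_expected = expected_intensity(decoy, tr, None, refl, sg)
        decoy_score = rfom(refl.e2[refl.active], decoy_expected)
        true_euler = Rotation.from_matrix(w_true).as_euler("zyz", degrees=True)
        true_score = rfom(refl.e2[refl.active],
                          expected_intensity(true_euler, tr, None, refl, sg))
        assert decoy_score < true_score
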