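import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkit.cell import UnitCell
from mrkit.fixtures import make_fixture, make_polymer
from mrkit.pipeline import _pose_objective
from mrkit.pose import Pose, apply_pose
from mrkit.refine import (
    SearchConfig, accept_copy, alaninize, chothia_lesk_rmsd, clash_fraction,
    simplex_refine,
)
from mrkit.reflections import normalize
from mrkit.symmetry import SpaceGroup

from conftest import make_model


class TestSimplexRefine:
    @pytest.fixture(scope="class")
    def setup(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fx = make_fixture("P212121", n_copies=1, seed=3)
            refl = normalize(fx.refl)
        refl.active &= refl.d >= 2.5
        model0 = fx.target_model.centered()
        objective = _pose_objective(refl, model0, refl.cell, refl.sg, None, "corr")
        return fx, objective

    def test_never_returns_worse_than_start(self, setup):
        fx, objective = setup
        start = fx.true_poses[0]
        refined, score = simplex_refine(start, objective, maxiter=50)
        assert score >= objective(start) - 1e-12

    def test_recovers_from_small_offset(self, setup):
        """2 degrees / 0.03 fractional off the truth on noise-free data must
        refine back to sub-degree, sub-0.005 accuracy."""
        fx, objective = setup
        truth = fx.true_poses[0]
        start = Pose(truth.euler + np.array([2.0, -1.5, 1.0]),
                     truth.tfrac + np.array([0.03, -0.02, 0.02]))
        refined, score = simplex_refine(start, objective)
        assert score > 0.999
        w_err = refined.matrix() @ truth.matrix().T
        ang = np.degrees(np.arccos(np.clip((np.trace(w_err) - 1) / 2, -1, 1)))
        assert ang < 0.5
        dt = (refined.tfrac - truth.tfrac) % 1.0
        dt = np.minimum(dt, 1 - dt)
        assert np.all(dt < 0.005)

    def test_non_finite_objective_returns_input(self):
        pose = Pose([10, 20, 30], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="non-finite"):
            out, score = simplex_refine(pose, lambda p: np.nan)
        assert np.allclose(out.euler, pose.euler)


class TestClashFraction:
    def setup_method(self):
        self.cell = UnitCell(60, 60, 60)
        self.sg = SpaceGroup("P 1")

    def _ca_model(self, xyz):
        return make_model(xyz, names=["CA"] * len(xyz))

    def test_superposed_copies_fully_clash(self):
        xyz = np.random.default_rng(0).uniform(20, 30, (10, 3))
        m = self._ca_model(xyz)
        assert clash_fraction([m, m.copy()], self.cell, self.sg) == 1.0

    def test_separated_copies_no_clash(self):
        xyz = np.random.default_rng(1).uniform(20, 25, (10, 3))
        a = self._ca_model(xyz)
        b = self._ca_model(xyz + 15.0)
        assert clash_fraction([a, b], self.cell, self.sg) == 0.0

    def test_partial_overlap_fraction(self):
        """4 of 20 CA atoms (2 per copy) within 3 A -> fraction 0.2."""
        base = np.array([[float(5 * i + 10), 25.0, 25.0] for i in range(10)])
        a = self._ca_model(base)
        b_xyz = base + np.array([0.0, 20.0, 0.0])
        b_xyz[0] = base[0] + np.array([1.0, 0.0, 0.0])
        b_xyz[1] = base[1] + np.array([0.0, 1.5, 0.0])
        b = self._ca_model(b_xyz)
        assert clash_fraction([a, b], self.cell, self.sg) == pytest.approx(4 / 20)

    def test_symmetry_mate_contacts_counted(self):
        sg = SpaceGroup("P 21 21 21")
        cell = UnitCell(20, 22, 24)
        # an atom close to the 2-fold screw image of itself
        m = self._ca_model([[0.5, 0.2, 5.9]])
        frac = clash_fraction([m], cell, sg)
        assert frac in (0.0, 1.0)  # single reference atom

    def test_nucleic_reference_atoms(self):
        na = make_polymer("dna", 6, seed=0)
        assert clash_fraction([na, na.copy()], self.cell, self.sg) == 1.0

    def test_no_reference_atoms_rejected(self):
        m = make_model([[1.0, 1, 1]], names=["CB"])
        with pytest.raises(ValueError, match="reference"):
            clash_fraction([m], self.cell, self.sg)


class TestAcceptCopy:
    @pytest.mark.parametrize("r_n,r_n1,clash,expected,tag", [
        (0.50, 0.45, 0.60, True, "fast"),    # big R drop: clash unchecked
        (0.50, 0.51, 0.40, False, "eq1"),    # heavy clash
        (0.50, 0.30, 0.80, True, "fast"),    # fast rule fires before clash
        (0.30, 0.50, 0.01, False, "eq1"),    # R rise above 0.15
        (0.500, 0.485, 0.02, True, "eq2"),   # clash clamped to 0.05 -> ratio 0.30
        (0.500, 0.495, 0.30, False, "eq2"),  # ratio 0.017 below 0.10
    ])
    def test_printed_rules(self, r_n, r_n1, clash, expected, tag):
        ok, rule = accept_copy(r_n, r_n1, clash)
        assert ok is expected
        assert rule == tag

    def test_truth_table_matches_literal_transcription(self):
        """Exhaustive grid against an independent transcription of the
        three printed rules."""
        cfg = SearchConfig()

        def literal(r_n, r_n1, clash):
            if r_n - r_n1 > 0.02:
                return True
            if clash > 0.35 or r_n1 - r_n > 0.15:
                return False
            return (r_n - r_n1) / max(clash, 0.05) > 0.10

        grid = np.linspace(0.0, 1.0, 20)
        for r_n in grid:
            for r_n1 in grid:
                for clash in grid:
                    assert accept_copy(r_n, r_n1, clash, cfg)[0] == literal(r_n, r_n1, clash)


class TestAlaninize:
    def _ladder_model(self, n=10):
        model = make_polymer("protein", n, seed=2)
        return model

    def test_zero_fraction_is_identity(self):
        m = self._ladder_model()
        out = alaninize(m, 0.0)
        assert out.n_atoms == m.n_atoms

    def test_full_fraction_trims_everything_beyond_cb(self):
        m = self._ladder_model()
        out = alaninize(m, 1.0)
        assert all(str(n) in ("N", "CA", "C", "O", "CB") for n in out.name)

    def test_highest_b_residues_trimmed_first(self):
        """B ladder rises with residue index: fraction 0.8 on 10 residues
        trims exactly the last 8."""
        m = self._ladder_model(10)
        out = alaninize(m, 0.8)
        trimmed = set()
        for key in m.residue_keys():
            atoms_before = ((m.chain == key[0]) & (m.resseq == key[1])).sum()
            atoms_after = ((out.chain == key[0]) & (out.resseq == key[1])).sum()
            if atoms_after < atoms_before:
                trimmed.add(key[1])
        assert trimmed <= set(range(3, 11))
        # the first two residues (lowest B) keep all their atoms
        assert 1 not in trimmed and 2 not in trimmed

    def test_nucleic_model_noop_with_warning(self):
        na = make_polymer("rna", 6, seed=1)
        with pytest.warns(UserWarning):
            out = alaninize(na, 0.8)
        assert out.n_atoms == na.n_atoms


class TestChothiaLesk:
    def test_perfect_identity(self):
        assert chothia_lesk_rmsd(1.0) == pytest.approx(0.40)

    def test_restart_trigger_value(self):
        assert chothia_lesk_rmsd(0.4) == pytest.approx(1.226, abs=0.005)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0.05, 0.99))
    def test_strictly_decreasing(self, si):
        assert chothia_lesk_rmsd(si) > chothia_lesk_rmsd(si + 0.01)

    def test_nonpositive_identity_rejected(self):
        with pytest.raises(ValueError):
            chothia_lesk_rmsd(0.0)
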