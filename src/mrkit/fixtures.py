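"""Self-contained synthetic test crystals with recorded ground truth.

A fixture is a small ideal polymer (alpha-helical protein or a crude
nucleic-acid single helix) placed at known poses in a cell sized so the
volume per non-H atom lands near the composition target for its molecule
type, with amplitudes computed from the placed copies.  Optional knobs
impose an overall anisotropic falloff, multiplicative amplitude noise,
coordinate noise on the search model, and a pseudo-translation pairing of
copies.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .cell import UnitCell
from .composition import VOLAT_TARGETS
from .model import AtomicModel, write_pdb
from .pose import Pose, apply_pose
from .refine import clash_fraction
from .reflections import ReflectionSet, read_text, write_text
from .rotation import matrix_to_euler
from .sfcalc import calc_structure_factors
from .symmetry import SpaceGroup

__all__ = ["Fixture", "make_polymer", "make_fixture", "write_fixture"]

SUPPORTED_SG = {"P1": "P 1", "P21": "P 1 21 1", "P212121": "P 21 21 21", "C2": "C 1 2 1"}

_PROTEIN_CODES = "ADEFGHIKLMNQRSTVWY"  # one-letter codes used for random sequences
_ONE_TO_THREE = {
    "A": "ALA", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY", "H": "HIS",
    "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN", "Q": "GLN",
    "R": "ARG", "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "C": "CYS", "P": "PRO",
}


@dataclass
class Fixture:
    cell: UnitCell
    sg: SpaceGroup
    true_poses: list[Pose]
    target_model: AtomicModel        # centroid-centered template
    search_model: AtomicModel        # noisy copy of the template (centered frame)
    refl: ReflectionSet
    sequence: str
    moltype: str
    seed: int
    noise_level: float
    model_noise: float
    aniso_betas: tuple[float, float, float] | None
    pst_vector: np.ndarray | None
    d_min: float

    def placed_target(self) -> AtomicModel:
        """Ground-truth structure: all copies placed in the cell."""
        from .pipeline import _combine_model
        return _combine_model([apply_pose(self.target_model, p, self.cell) for p in self.true_poses])


def make_polymer(moltype: str, n_residues: int, seed: int = 0) -> AtomicModel:
    """Ideal small polymer with a B-factor ladder.

    Protein: two ideal alpha-helical segments (rise 1.5 A, twist 100
    deg/residue, radius 2.3 A) joined by a rigid 50-degree bend, with
    CB/CG/CD stubs on larger residues; the bend and the fanned stubs keep
    the model free of rotational pseudo-symmetry.  Nucleic acid: a single
    helical strand carrying P, primed-carbon backbone atoms and base
    nitrogens, so all clash-reference rules are exercised.
    """
    if not 5 <= n_residues <= 60:
        raise ValueError("n_residues must lie in [5, 60]")
    rng = np.random.default_rng(seed)
    el, xyz, nm, rn, rs = [], [], [], [], []

    def add(name, element, pos, res_i, resname):
        el.append(element)
        nm.append(name)
        xyz.append(pos)
        rs.append(res_i + 1)
        rn.append(resname)

    if moltype == "protein":
        seq = "".join(rng.choice(list(_PROTEIN_CODES), n_residues))
        radius, rise, twist = 2.3, 1.5, np.radians(100.0)
        # helix-turn-helix: the C-terminal half is bent 50 degrees about x
        # through the middle CA, so the model has no rotational
        # pseudo-symmetry about a single helix axis
        kink_at = n_residues // 2
        kink = Rotation.from_euler("x", 50, degrees=True).as_matrix()
        th_k = kink_at * twist
        ca_kink = np.array([radius * np.cos(th_k), radius * np.sin(th_k), rise * kink_at])
        for i in range(n_residues):
            th = i * twist
            ca = np.array([radius * np.cos(th), radius * np.sin(th), rise * i])
            axis_out = np.array([np.cos(th), np.sin(th), 0.0])
            prev_dir = np.array([-np.sin(th), np.cos(th), 0.3])
            prev_dir /= np.linalg.norm(prev_dir)
            resname = _ONE_TO_THREE[seq[i]]
            add("N", "N", ca - 1.46 * prev_dir, i, resname)
            add("CA", "C", ca, i, resname)
            add("C", "C", ca + 1.52 * prev_dir, i, resname)
            add("O", "O", ca + 1.52 * prev_dir + 1.23 * axis_out, i, resname)
            # side-chain stubs fan out at residue-dependent azimuths so the
            # model is not rotationally self-similar about the helix axis
            up = np.array([0.0, 0.0, 1.0])
            tangent = np.cross(up, axis_out)
            phi = np.radians(47.0 * i)
            stub_dir = (np.cos(phi) * 0.35 * tangent + np.sin(phi) * 0.35 * up + axis_out)
            stub_dir /= np.linalg.norm(stub_dir)
            if seq[i] != "G":
                add("CB", "C", ca + 1.53 * stub_dir, i, resname)
            if seq[i] in "DEFHIKLMNQRWY":
                add("CG", "C", ca + 2.9 * stub_dir + 0.5 * up, i, resname)
            if seq[i] in "FKRWY":
                add("CD", "C", ca + 4.1 * stub_dir + 0.9 * np.cos(phi) * tangent, i, resname)
        # rigid bend of the C-terminal half about the middle CA preserves
        # all intra-segment geometry (consecutive CA-CA stays 3.8 A)
        xyz = [p if r - 1 < kink_at else kink @ (p - ca_kink) + ca_kink
               for p, r in zip(xyz, rs)]
    elif moltype in ("dna", "rna"):
        bases = "ACGT" if moltype == "dna" else "ACGU"
        seq = "".join(rng.choice(list(bases), n_residues))
        radius, rise, twist = 9.0, 3.3, np.radians(36.0)
        for i in range(n_residues):
            th = i * twist
            resname = ("D" + seq[i]) if moltype == "dna" else seq[i]
            outward = np.array([np.cos(th), np.sin(th), 0.0])
            tangent = np.array([-np.sin(th), np.cos(th), 0.0])
            p = radius * outward + np.array([0, 0, rise * i])
            add("P", "P", p, i, resname)
            add("O5'", "O", p + 1.6 * tangent, i, resname)
            add("C5'", "C", p + 1.6 * tangent + 1.4 * np.array([0, 0, 1.0]), i, resname)
            add("C4'", "C", p - 1.2 * outward + 1.1 * tangent, i, resname)
            add("C3'", "C", p - 1.5 * outward - 0.9 * tangent, i, resname)
            add("C1'", "C", p - 2.6 * outward + 0.5 * tangent, i, resname)
            base_n = "N9" if seq[i] in "AG" else "N1"
            add(base_n, "N", p - 4.2 * outward, i, resname)
            add("N3", "N", p - 5.5 * outward + 0.8 * tangent, i, resname)
    else:
        raise ValueError(f"unknown moltype {moltype!r}")

    n = len(xyz)
    res_index = np.array(rs) - 1
    b = 10.0 + 20.0 * res_index / max(1, n_residues - 1)
    mdl = AtomicModel(
        np.array(el, object), np.array(xyz), b, np.ones(n),
        np.array(["A"] * n, object), np.array(rs, int),
        np.array(rn, object), np.array(nm, object), moltype,
    )
    mdl.sequence = seq  # type: ignore[attr-defined]
    return mdl


def _cell_for(sg: SpaceGroup, sg_key: str, extents: np.ndarray, n_copies: int,
              n_atoms: int, moltype: str) -> UnitCell:
    """Cell shaped like the padded molecule, scaled to the VOLAT target."""
    target = VOLAT_TARGETS[moltype]
    v_needed = target * n_atoms * n_copies * sg.m
    base = extents + 6.0   # 6 A solvent margin around each copy
    scale = (v_needed / np.prod(base)) ** (1.0 / 3.0)
    edges = base * max(scale, 1.0)
    if sg_key in ("P21", "C2"):
        beta = 100.0
        # volume shrinks by sin(beta); stretch to compensate
        edges = edges * (1.0 / np.sin(np.radians(beta))) ** (1 / 3)
        return UnitCell(*edges, 90.0, beta, 90.0)
    return UnitCell(*edges)


def _random_pose(rng: np.random.Generator, sg: SpaceGroup, first: bool) -> Pose:
    quat = rng.normal(size=4)
    rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
    t = rng.random(3)
    if first:
        t = np.where(sg.polar_axes, 0.0, t)
    return Pose(matrix_to_euler(rot), t)


def _hkl_sphere(cell: UnitCell, sg: SpaceGroup, d_min: float) -> np.ndarray:
    """Unique, present reflections to d_min (one asu representative each)."""
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    hs, ks, ls = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(0, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([hs, ks, ls], axis=-1).reshape(-1, 3)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = 1.0 / np.linalg.norm(hkl @ cell.frac, axis=1)
    hkl = hkl[d >= d_min]
    reduced = sg.asu_reduce(hkl)
    uniq = np.unique(reduced, axis=0)
    keep = np.array([not sg.is_absent(h) for h in uniq])
    return uniq[keep]


def make_fixture(
    sg_symbol: str = "P212121",
    n_copies: int = 1,
    model_noise_A: float = 0.0,
    data_noise_frac: float = 0.0,
    aniso_betas=None,
    pst=None,
    seed: int = 0,
    moltype: str = "protein",
    n_residues: int = 10,
    d_min: float = 2.5,
    max_tries: int = 1000,
) -> Fixture:
    """Build a synthetic crystal with known poses; see the module docstring."""
    key = sg_symbol.replace(" ", "")
    if key not in SUPPORTED_SG:
        raise ValueError(f"unsupported fixture space group {sg_symbol!r}; use one of {sorted(SUPPORTED_SG)}")
    if not 1 <= n_copies <= 4:
        raise ValueError("n_copies must lie in 1..4")
    sg = SpaceGroup(SUPPORTED_SG[key])
    rng = np.random.default_rng(seed)
    raw = make_polymer(moltype, n_residues, seed=seed)
    sequence = getattr(raw, "sequence", "")
    polymer = raw.centered()
    extents = polymer.xyz.max(axis=0) - polymer.xyz.min(axis=0)
    # size the cell by the nominal sequence content (what composition sees),
    # not by the stub model's smaller atom count
    from .composition import count_nonh_atoms
    seq_atoms = count_nonh_atoms(sequence, moltype)
    cell = _cell_for(sg, key, extents, n_copies, seq_atoms, moltype)

    poses: list[Pose] = []
    paired = pst is not None and n_copies >= 2
    for attempt in range(max_tries):
        poses = [_random_pose(rng, sg, first=True)]
        for i in range(1, n_copies):
            if paired and i == 1:
                poses.append(Pose(poses[0].euler.copy(), poses[0].tfrac + np.asarray(pst, float)))
            else:
                poses.append(_random_pose(rng, sg, first=False))
        placed = [apply_pose(polymer, p, cell) for p in poses]
        if clash_fraction(placed, cell, sg) == 0.0:
            break
    else:
        raise RuntimeError(f"could not place {n_copies} copies without clashes in {max_tries} tries")

    hkl = _hkl_sphere(cell, sg, d_min)
    f = np.zeros(len(hkl), complex)
    for mdl in placed:
        f += calc_structure_factors(mdl, cell, sg, hkl)
    fobs = np.abs(f)
    if aniso_betas is not None:
        b1, b2, b3 = aniso_betas
        fobs = fobs * np.exp(-(b1 * hkl[:, 0] ** 2 + b2 * hkl[:, 1] ** 2 + b3 * hkl[:, 2] ** 2))
    if data_noise_frac > 0:
        fobs = fobs * (1.0 + data_noise_frac * rng.standard_normal(len(fobs)))
        fobs = np.abs(fobs)
    sigf = np.maximum(data_noise_frac, 0.01) * fobs
    refl = ReflectionSet(cell, sg, hkl, fobs, sigf)

    search = polymer.copy()
    if model_noise_A > 0:
        search.xyz = search.xyz + model_noise_A * rng.standard_normal(search.xyz.shape)

    return Fixture(
        cell=cell, sg=sg, true_poses=poses, target_model=polymer, search_model=search,
        refl=refl, sequence=sequence, moltype=moltype, seed=seed,
        noise_level=data_noise_frac, model_noise=model_noise_A,
        aniso_betas=tuple(aniso_betas) if aniso_betas is not None else None,
        pst_vector=np.asarray(pst, float) if pst is not None else None, d_min=d_min,
    )


def write_fixture(fixture: Fixture, out_dir: str) -> dict[str, str]:
    """Emit model PDBs, reflection text, FASTA, directive file and the
    ground truth table; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "target": os.path.join(out_dir, "target.pdb"),
        "search": os.path.join(out_dir, "search_model.pdb"),
        "hkl": os.path.join(out_dir, "reflections.hkl"),
        "fasta": os.path.join(out_dir, "sequence.fasta"),
        "directives": os.path.join(out_dir, "job.mr"),
        "truth": os.path.join(out_dir, "ground_truth.tsv"),
    }
    write_pdb(fixture.placed_target(), paths["target"], fixture.cell, fixture.sg.symbol)
    write_pdb(fixture.search_model, paths["search"])
    write_text(fixture.refl, paths["hkl"])
    with open(paths["fasta"], "w") as fh:
        fh.write(f">chain_A synthetic {fixture.moltype}\n{fixture.sequence}\n")
    a, b, c = fixture.cell.a, fixture.cell.b, fixture.cell.c
    with open(paths["directives"], "w") as fh:
        fh.write(
            "%structure synthetic\n"
            f"%job synthetic {fixture.moltype} fixture seed {fixture.seed}\n"
            "%data\n"
            "hkl reflections.hkl\n"
            "label H K L F SIGF\n"
            f"cell {a:.4f} {b:.4f} {c:.4f} "
            f"{fixture.cell.alpha:.2f} {fixture.cell.beta:.2f} {fixture.cell.gamma:.2f}\n"
            f"spacegroup {fixture.sg.symbol}\n"
            "sequence sequence.fasta\n"
            "%mr\n"
            "fragment search_model.pdb\n"
            f"nmod {len(fixture.true_poses)}\n"
            "%end\n"
        )
    with open(paths["truth"], "w") as fh:
        fh.write("# copy\talpha\tbeta\tgamma\ttx\tty\ttz\n")
        fh.write(f"# seed={fixture.seed} sg={fixture.sg.symbol} noise={fixture.noise_level}"
                 f" model_noise={fixture.model_noise}\n")
        for i, p in enumerate(fixture.true_poses, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in p.euler)
                     + "\t" + "\t".join(f"{v:.6f}" for v in p.tfrac) + "\n")
    return paths


def read_fixture_reflections(path: str, cell: UnitCell, sg: SpaceGroup) -> ReflectionSet:
    return read_text(path, cell, sg)
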