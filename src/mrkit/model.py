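"""Atomic models: typed polymer coordinates with B factors and occupancies.

Coordinates are stored in orthogonal angstrom; fractionalization happens
against an explicit :class:`~mrkit.cell.UnitCell` when structure factors
or packing are computed.  PDB and mmCIF files are read through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .cell import UnitCell

__all__ = ["AtomicModel", "read_model", "write_pdb"]

_PROTEIN_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "UNK",
}
_DNA_RES = {"DA", "DC", "DG", "DT", "DI", "DU"}
_RNA_RES = {"A", "C", "G", "U", "I"}


@dataclass
class AtomicModel:
    """Flat arrays of atoms plus residue/chain bookkeeping.

    ``chain``, ``resseq``, ``resname`` and ``name`` run parallel to the
    coordinate rows; ``moltype`` is one of ``protein``, ``dna``, ``rna``.
    """

    element: np.ndarray          # (n,) str
    xyz: np.ndarray              # (n, 3) orthogonal angstrom
    b_iso: np.ndarray            # (n,)
    occ: np.ndarray              # (n,)
    chain: np.ndarray            # (n,) str
    resseq: np.ndarray           # (n,) int
    resname: np.ndarray          # (n,) str
    name: np.ndarray             # (n,) atom names
    moltype: str = "protein"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, float).reshape(-1, 3)
        n = len(self.xyz)
        self.element = np.asarray(self.element, dtype=object)
        self.b_iso = np.asarray(self.b_iso, float)
        self.occ = np.asarray(self.occ, float)
        for arr_name in ("element", "b_iso", "occ", "chain", "resseq", "resname", "name"):
            arr = np.asarray(getattr(self, arr_name))
            if len(arr) != n:
                raise ValueError(f"{arr_name} length {len(arr)} != {n} atoms")
            setattr(self, arr_name, arr)
        if np.any((self.occ < 0) | (self.occ > 1)):
            raise ValueError("occupancies must lie in [0, 1]")
        if np.any(self.b_iso < 0):
            raise ValueError("B factors must be non-negative")
        if self.moltype not in ("protein", "dna", "rna"):
            raise ValueError(f"moltype must be protein/dna/rna, got {self.moltype!r}")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.element.copy(), self.xyz.copy(), self.b_iso.copy(), self.occ.copy(),
            self.chain.copy(), self.resseq.copy(), self.resname.copy(), self.name.copy(),
            self.moltype,
        )

    def select(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.element[mask], self.xyz[mask], self.b_iso[mask], self.occ[mask],
            self.chain[mask], self.resseq[mask], self.resname[mask], self.name[mask],
            self.moltype,
        )

    def centroid(self) -> np.ndarray:
        return self.xyz.mean(axis=0)

    def centered(self) -> "AtomicModel":
        out = self.copy()
        out.xyz = out.xyz - self.centroid()
        return out

    def transformed(self, rot: np.ndarray | None = None, shift_orth: np.ndarray | None = None) -> "AtomicModel":
        """Rigid transform in orthogonal space: x -> rot @ x + shift."""
        out = self.copy()
        if rot is not None:
            out.xyz = out.xyz @ np.asarray(rot, float).T
        if shift_orth is not None:
            out.xyz = out.xyz + np.asarray(shift_orth, float)
        return out

    def max_dimension(self) -> float:
        """Maximum inter-atomic distance (angstrom)."""
        xyz = self.xyz
        if len(xyz) < 2:
            return 0.0
        # brute force is fine at the model sizes this package handles
        d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, resseq) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for ch, rs in zip(self.chain, self.resseq):
            seen.setdefault((str(ch), int(rs)), None)
        return list(seen)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for ch in self.chain:
            seen.setdefault(str(ch), None)
        return list(seen)


def infer_moltype(resnames) -> str:
    names = {str(r).strip().upper() for r in resnames}
    if names & _PROTEIN_RES:
        return "protein"
    if names & _DNA_RES:
        return "dna"
    if names & _RNA_RES:
        return "rna"
    return "protein"


def from_gemmi(structure: gemmi.Structure, moltype: str | None = None) -> AtomicModel:
    el, xyz, b, occ, ch, rs, rn, nm = [], [], [], [], [], [], [], []
    mdl = structure[0]
    for chain in mdl:
        for res in chain:
            for atom in res:
                el.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                b.append(atom.b_iso)
                occ.append(min(max(atom.occ, 0.0), 1.0))
                ch.append(chain.name)
                rs.append(res.seqid.num)
                rn.append(res.name)
                nm.append(atom.name)
    if not xyz:
        raise ValueError("structure contains no atoms")
    mt = moltype or infer_moltype(rn)
    return AtomicModel(np.array(el, object), np.array(xyz), np.array(b), np.array(occ),
                       np.array(ch, object), np.array(rs, int), np.array(rn, object),
                       np.array(nm, object), mt)


def read_model(path: str, moltype: str | None = None) -> AtomicModel:
    """Read a model from PDB or mmCIF (format detected by gemmi)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return from_gemmi(st, moltype)


def to_gemmi(model: AtomicModel, cell: UnitCell | None = None, sg_symbol: str = "P 1") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "mrkit"
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell.parameters())
        st.spacegroup_hm = sg_symbol
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple[str, int], gemmi.Residue] = {}
    for i in range(model.n_atoms):
        cid = str(model.chain[i])
        if cid not in chains:
            chains[cid] = gemmi.Chain(cid)
        key = (cid, int(model.resseq[i]))
        if key not in residues:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(int(model.resseq[i]), " ")
            chains[cid].add_residue(res)
            residues[key] = chains[cid][-1]
        atom = gemmi.Atom()
        atom.name = str(model.name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        atom.pos = gemmi.Position(*model.xyz[i])
        atom.b_iso = float(model.b_iso[i])
        atom.occ = float(model.occ[i])
        residues[key].add_atom(atom)
    for chain in chains.values():
        md.add_chain(chain)
    st.add_model(md)
    return st


def write_pdb(model: AtomicModel, path: str, cell: UnitCell | None = None, sg_symbol: str = "P 1") -> None:
    to_gemmi(model, cell, sg_symbol).write_pdb(str(path))
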