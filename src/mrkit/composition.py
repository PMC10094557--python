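"""Asymmetric-unit composition: chains per asu (NCHT) and model copies (NMOD).

The primary criterion picks the chain count whose volume per non-H atom
(VOLAT = V_asu / n_atoms) is closest to an empirical target -- 38 A^3 for
proteins, 34.5 for DNA, 44 for RNA -- subject to a hard floor of 22 A^3.
A Matthews-style solvent-fraction estimate (volume fraction closest to
0.50) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .model import AtomicModel
from .symmetry import SpaceGroup

__all__ = [
    "CompositionEstimate", "count_nonh_atoms", "estimate_chain_count",
    "estimate_chain_count_matthews", "estimate_model_copies",
    "VOLAT_TARGETS", "VOLAT_FLOOR",
]

VOLAT_TARGETS = {"protein": 38.0, "dna": 34.5, "rna": 44.0}
VOLAT_FLOOR = 22.0

# non-H atoms per residue in a polymerized chain (water of condensation lost)
PROTEIN_ATOMS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8,
    "Q": 9, "K": 9, "E": 9, "H": 10, "R": 11, "F": 11, "Y": 12, "W": 14,
}
# deoxyribose-phosphate backbone = 11 atoms, ribose adds O2'
DNA_ATOMS = {"A": 21, "G": 22, "C": 19, "T": 20}
RNA_ATOMS = {"A": 22, "G": 23, "C": 20, "U": 19}

# average residue masses (Da) in a chain
PROTEIN_MASS = {
    "G": 57.05, "A": 71.08, "S": 87.08, "P": 97.12, "V": 99.13, "T": 101.10,
    "C": 103.14, "L": 113.16, "I": 113.16, "N": 114.10, "D": 115.09,
    "Q": 128.13, "K": 128.17, "E": 129.12, "M": 131.19, "H": 137.14,
    "F": 147.18, "R": 156.19, "Y": 163.18, "W": 186.21,
}
DNA_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
RNA_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}

_AVOGADRO_A3 = 0.6022  # N_A expressed so that M[Da]/(delta[g/cm^3]*0.6022) = volume in A^3


def _table(moltype: str, which: str) -> dict[str, float]:
    tables = {
        ("protein", "atoms"): PROTEIN_ATOMS, ("dna", "atoms"): DNA_ATOMS,
        ("rna", "atoms"): RNA_ATOMS, ("protein", "mass"): PROTEIN_MASS,
        ("dna", "mass"): DNA_MASS, ("rna", "mass"): RNA_MASS,
    }
    try:
        return tables[(moltype, which)]
    except KeyError:
        raise ValueError(f"unknown moltype {moltype!r}") from None


def count_nonh_atoms(sequence: str, moltype: str = "protein") -> int:
    """Non-H atom count of one polymerized chain."""
    table = _table(moltype, "atoms")
    total = 0
    for pos, code in enumerate(sequence.strip().upper(), start=1):
        if code not in table:
            raise ValueError(f"unknown {moltype} residue code {code!r} at position {pos}")
        total += table[code]
    return total


def chain_mass(sequence: str, moltype: str = "protein") -> float:
    """Average molecular mass (Da) of the chain, terminal water included."""
    table = _table(moltype, "mass")
    mass = 18.02
    for pos, code in enumerate(sequence.strip().upper(), start=1):
        if code not in table:
            raise ValueError(f"unknown {moltype} residue code {code!r} at position {pos}")
        mass += table[code]
    return mass


DEFAULT_PROTEIN_DENSITY = 1.35  # g/cm^3, generic value when mass is unknown


def protein_density(mass_da: float | None = None) -> float:
    """Chain density in g/cm^3.

    Without a mass the generic 1.35 is returned.  With a mass, small chains
    are denser: 1.50 at or below 7 kDa, 1.41 at or above 30 kDa, linear in
    between.
    """
    if mass_da is None:
        return DEFAULT_PROTEIN_DENSITY
    if mass_da <= 7000.0:
        return 1.50
    if mass_da >= 30000.0:
        return 1.41
    return 1.50 + (1.41 - 1.50) * (mass_da - 7000.0) / (30000.0 - 7000.0)


@dataclass
class CompositionEstimate:
    ncht: int
    nmod: int
    volat: float
    candidates: list[tuple[int, float]]
    method: str = "volat"
    moltype: str = "protein"
    asu_volume: float = 0.0
    atoms_per_set: int = 0


def _normalize_moltypes(sequences, moltype):
    if isinstance(sequences, str):
        sequences = [sequences]
    if isinstance(moltype, str):
        moltypes = [moltype] * len(sequences)
    else:
        moltypes = list(moltype)
    if len(moltypes) != len(sequences):
        raise ValueError("one moltype per sequence required")
    return list(sequences), moltypes


def _dominant_target(sequences, moltypes) -> tuple[str, float]:
    counts = {"protein": 0, "dna": 0, "rna": 0}
    for seq, mt in zip(sequences, moltypes):
        counts[mt] += count_nonh_atoms(seq, mt)
    dominant = max(counts, key=counts.get)
    return dominant, VOLAT_TARGETS[dominant]


def estimate_chain_count(
    cell: UnitCell,
    sg: SpaceGroup,
    sequences,
    moltype="protein",
    max_n: int = 64,
) -> CompositionEstimate:
    """NCHT by the volume-per-atom rule.

    One "chain set" is the full list of ``sequences``; candidates n = 1, 2,
    ... score VOLAT(n) = V_asu / (n * atoms_per_set); the winner minimizes
    |VOLAT - target| among candidates with VOLAT >= 22 A^3 (ties break to
    the smaller n).
    """
    sequences, moltypes = _normalize_moltypes(sequences, moltype)
    atoms = sum(count_nonh_atoms(s, m) for s, m in zip(sequences, moltypes))
    if atoms == 0:
        raise ValueError("empty sequence set")
    dominant, target = _dominant_target(sequences, moltypes)
    v_asu = cell.volume / sg.m
    candidates = []
    for n in range(1, max_n + 1):
        volat = v_asu / (n * atoms)
        candidates.append((n, volat))
        if volat < VOLAT_FLOOR:
            break
    feasible = [(n, v) for n, v in candidates if v >= VOLAT_FLOOR]
    if not feasible:
        raise ValueError(
            f"content exceeds asu volume: VOLAT(1) = {candidates[0][1]:.1f} A^3 < {VOLAT_FLOOR}"
        )
    best_n, best_v = min(feasible, key=lambda nv: (abs(nv[1] - target), nv[0]))
    return CompositionEstimate(
        ncht=best_n, nmod=best_n, volat=best_v, candidates=candidates,
        method="volat", moltype=dominant, asu_volume=v_asu, atoms_per_set=atoms,
    )


def estimate_chain_count_matthews(
    cell: UnitCell,
    sg: SpaceGroup,
    sequences,
    moltype="protein",
    max_n: int = 64,
) -> CompositionEstimate:
    """NCHT by the solvent-fraction rule: volume fraction closest to 0.50."""
    sequences, moltypes = _normalize_moltypes(sequences, moltype)
    mass = sum(chain_mass(s, m) for s, m in zip(sequences, moltypes))
    atoms = sum(count_nonh_atoms(s, m) for s, m in zip(sequences, moltypes))
    dominant, _ = _dominant_target(sequences, moltypes)
    v_chain = mass / (protein_density(mass) * _AVOGADRO_A3)
    v_asu = cell.volume / sg.m
    candidates = []
    for n in range(1, max_n + 1):
        frac = n * v_chain / v_asu
        candidates.append((n, frac))
        if frac > 1.0:
            break
    feasible = [(n, f) for n, f in candidates if f <= 1.0]
    if not feasible:
        raise ValueError("content exceeds asu volume at n = 1")
    best_n, best_f = min(feasible, key=lambda nf: (abs(nf[1] - 0.50), nf[0]))
    return CompositionEstimate(
        ncht=best_n, nmod=best_n, volat=v_asu / (best_n * atoms), candidates=candidates,
        method="protfrac", moltype=dominant, asu_volume=v_asu, atoms_per_set=atoms,
    )


def _model_chain_inventory(model: AtomicModel) -> tuple[int, int]:
    """(number of chains, 1 if all chains identical else 0) -> (n_chains, n_identical)."""
    sizes = {}
    for cid in model.chain_ids():
        mask = model.chain == cid
        key = tuple(model.resname[mask])
        sizes.setdefault(cid, key)
    keys = list(sizes.values())
    n_chains = len(keys)
    identical = n_chains > 1 and all(k == keys[0] for k in keys[1:])
    return n_chains, (n_chains if identical else 1)


def estimate_model_copies(
    estimate: CompositionEstimate,
    target_sequences,
    model: AtomicModel,
    moltype="protein",
) -> CompositionEstimate:
    """NMOD from NCHT and the search model's chain inventory.

    If the model is n identical chains, NCHT is snapped to the nearest
    multiple of n (ties round up).  Target chains shorter than half the
    longest are disregarded when the model comprises only the long chain.
    """
    sequences, _ = _normalize_moltypes(target_sequences, moltype)
    n_chains, n_ident = _model_chain_inventory(model)
    ncht = estimate.ncht
    if n_ident > 1:
        ncht = max(n_ident, n_ident * int(np.floor(ncht / n_ident + 0.5)))
    lengths = [len(s) for s in sequences]
    longest = max(lengths)
    model_res = len(model.residue_keys())
    retained = len(lengths)
    if n_chains == 1 and len(lengths) > 1:
        # model covers only the long chain: short target chains are dropped
        if abs(model_res - longest) <= max(5, 0.2 * longest):
            retained = sum(1 for L in lengths if L >= 0.5 * longest)
    nmod = max(1, (ncht * retained) // n_chains)
    out = CompositionEstimate(
        ncht=ncht, nmod=int(nmod), volat=estimate.asu_volume / max(1, ncht * estimate.atoms_per_set)
        if estimate.atoms_per_set else estimate.volat,
        candidates=estimate.candidates, method=estimate.method,
        moltype=estimate.moltype, asu_volume=estimate.asu_volume,
        atoms_per_set=estimate.atoms_per_set,
    )
    return out
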