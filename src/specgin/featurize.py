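"""SMILES to featurised molecular graphs.

Atom vectors are 56-dimensional:

==========================  =====  ==============================================
block                       slots  encoding
==========================  =====  ==============================================
formal charge               7      one-hot over {-3 .. +3}
degree                      12     one-hot over {0 .. 10, >=11}
hybridization               6      one-hot over {sp, sp2, sp3, sp3d, sp3d2, other}
in ring                     1      binary
aromatic                    1      binary
atomic mass (scaled)        1      (m - 10.812) / 116.092
van der Waals radius        1      (r - 1.5) / 0.6
covalent radius             1      (r - 0.64) / 0.76
element                     26     one-hot over a fixed drug-like element list
==========================  =====  ==============================================

Bond vectors are 9-dimensional: bond-order one-hot over {single, double,
triple, aromatic} (4), conjugation flag (1), stereo one-hot over
{none, any, E, Z} (4).

Molecules are modelled heavy-atom-only (implicit hydrogens), the convention
for SMILES property benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdchem

from .graph import MolecularGraph, N_ATOM_FEATURES, N_BOND_FEATURES

__all__ = [
    "ELEMENTS",
    "AtomDescriptor",
    "compute_formal_charge",
    "count_hybrid_orbitals",
    "map_hybridization",
    "scale_atomic_mass",
    "scale_vdw_radius",
    "scale_covalent_radius",
    "featurize_atom",
    "featurize_bond",
    "smiles_to_graph",
]

#: Supported drug-like elements, in feature order.
ELEMENTS = (
    "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si", "P", "S", "Cl",
    "K", "Ca", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "As", "Se",
    "Br", "Sn", "I",
)

HYBRIDIZATIONS = ("sp", "sp2", "sp3", "sp3d", "sp3d2", "other")
BOND_ORDERS = ("single", "double", "triple", "aromatic")
STEREO_LABELS = ("none", "any", "E", "Z")

MAX_DEGREE = 11  # degrees >= 11 share the last bucket

_CHARGE_OFFSET = 3  # one-hot slot of charge c is c + 3


def compute_formal_charge(valence_electrons: int, nonbonding_electrons: int,
                          bonding_electrons: int) -> int:
    """Formal charge V - N - B/2, clamped to [-3, 3].

    ``bonding_electrons`` counts electrons (two per bond) and must be even.
    """
    for v in (valence_electrons, nonbonding_electrons, bonding_electrons):
        if v < 0:
            raise ValueError("electron counts must be nonnegative")
    if bonding_electrons % 2:
        raise ValueError(
            f"odd bonding-electron count {bonding_electrons}: formal charge undefined"
        )
    charge = valence_electrons - nonbonding_electrons - bonding_electrons // 2
    return int(np.clip(charge, -3, 3))


def count_hybrid_orbitals(valence: int, monovalent_neighbors: int,
                          cation_charge: int = 0, anion_charge: int = 0) -> int:
    """H = (V + M - C + A) / 2, rounded to the nearest integer."""
    for v in (valence, monovalent_neighbors, cation_charge, anion_charge):
        if v < 0:
            raise ValueError("inputs must be nonnegative")
    h = 0.5 * (valence + monovalent_neighbors - cation_charge + anion_charge)
    return int(round(h))


def map_hybridization(n_orbitals: int) -> str:
    """Hybridization class from the hybrid-orbital count."""
    return {2: "sp", 3: "sp2", 4: "sp3", 5: "sp3d", 6: "sp3d2"}.get(
        n_orbitals, "other"
    )


def scale_atomic_mass(mass: float) -> float:
    """Affine rescaling of atomic mass (u), anchored at B and I."""
    return (mass - 10.812) / 116.092


def scale_vdw_radius(radius: float) -> float:
    """Affine rescaling of the van der Waals radius (Angstrom)."""
    return (radius - 1.5) / 0.6


def scale_covalent_radius(radius: float) -> float:
    """Affine rescaling of the covalent radius (Angstrom)."""
    return (radius - 0.64) / 0.76


@dataclass
class AtomDescriptor:
    """Plain atom description consumed by :func:`featurize_atom`."""

    element: str
    formal_charge: int = 0
    degree: int = 0
    hybridization: str = "other"
    in_ring: bool = False
    aromatic: bool = False
    mass: float = 12.011
    vdw_radius: float = 1.7
    covalent_radius: float = 0.76


def featurize_atom(atom: AtomDescriptor) -> np.ndarray:
    """Assemble the 56-d atom vector from a descriptor."""
    if atom.element not in ELEMENTS:
        raise ValueError(f"unsupported element: {atom.element!r}")
    v = np.zeros(N_ATOM_FEATURES)
    charge = int(np.clip(atom.formal_charge, -3, 3))
    v[charge + _CHARGE_OFFSET] = 1.0
    v[7 + min(atom.degree, MAX_DEGREE)] = 1.0
    hyb = atom.hybridization if atom.hybridization in HYBRIDIZATIONS else "other"
    v[19 + HYBRIDIZATIONS.index(hyb)] = 1.0
    v[25] = float(bool(atom.in_ring))
    v[26] = float(bool(atom.aromatic))
    v[27] = scale_atomic_mass(atom.mass)
    v[28] = scale_vdw_radius(atom.vdw_radius)
    v[29] = scale_covalent_radius(atom.covalent_radius)
    v[30 + ELEMENTS.index(atom.element)] = 1.0
    return v


def featurize_bond(order: str, conjugated: bool = False,
                   stereo: str = "none") -> np.ndarray:
    """Assemble the 9-d bond vector."""
    if order not in BOND_ORDERS:
        raise ValueError(f"unknown bond order: {order!r}")
    if stereo not in STEREO_LABELS:
        raise ValueError(f"unknown stereo label: {stereo!r}")
    v = np.zeros(N_BOND_FEATURES)
    v[BOND_ORDERS.index(order)] = 1.0
    v[4] = float(bool(conjugated))
    v[5 + STEREO_LABELS.index(stereo)] = 1.0
    return v


_RDKIT_HYB = {
    rdchem.HybridizationType.SP: "sp",
    rdchem.HybridizationType.SP2: "sp2",
    rdchem.HybridizationType.SP3: "sp3",
    rdchem.HybridizationType.SP3D: "sp3d",
    rdchem.HybridizationType.SP3D2: "sp3d2",
}

_RDKIT_BOND = {
    rdchem.BondType.SINGLE: "single",
    rdchem.BondType.DOUBLE: "double",
    rdchem.BondType.TRIPLE: "triple",
    rdchem.BondType.AROMATIC: "aromatic",
}

_RDKIT_STEREO = {
    rdchem.BondStereo.STEREONONE: "none",
    rdchem.BondStereo.STEREOANY: "any",
    rdchem.BondStereo.STEREOE: "E",
    rdchem.BondStereo.STEREOTRANS: "E",
    rdchem.BondStereo.STEREOZ: "Z",
    rdchem.BondStereo.STEREOCIS: "Z",
}


def _atom_hybridization(atom: rdchem.Atom) -> str:
    """RDKit hybridization label, with the orbital-count rule as fallback."""
    label = _RDKIT_HYB.get(atom.GetHybridization())
    if label is not None:
        return label
    pt = Chem.GetPeriodicTable()
    valence = pt.GetNOuterElecs(atom.GetAtomicNum())
    monovalent = sum(
        1
        for nbr in atom.GetNeighbors()
        if nbr.GetDegree() + nbr.GetTotalNumHs() == 1
    ) + atom.GetTotalNumHs()
    charge = atom.GetFormalCharge()
    cation = max(charge, 0)
    anion = max(-charge, 0)
    return map_hybridization(
        count_hybrid_orbitals(valence, monovalent, cation, anion)
    )


def _describe_atom(atom: rdchem.Atom) -> AtomDescriptor:
    symbol = atom.GetSymbol()
    if symbol not in ELEMENTS:
        raise ValueError(f"unsupported element: {symbol!r}")
    pt = Chem.GetPeriodicTable()
    return AtomDescriptor(
        element=symbol,
        formal_charge=atom.GetFormalCharge(),
        degree=atom.GetDegree(),
        hybridization=_atom_hybridization(atom),
        in_ring=atom.IsInRing(),
        aromatic=atom.GetIsAromatic(),
        mass=atom.GetMass(),
        vdw_radius=pt.GetRvdw(atom.GetAtomicNum()),
        covalent_radius=pt.GetRcovalent(atom.GetAtomicNum()),
    )


def _describe_bond(bond: rdchem.Bond) -> np.ndarray:
    order = _RDKIT_BOND.get(bond.GetBondType())
    if order is None:
        raise ValueError(f"unsupported bond type: {bond.GetBondType()}")
    stereo = _RDKIT_STEREO.get(bond.GetStereo(), "any")
    return featurize_bond(order, bond.GetIsConjugated(), stereo)


def smiles_to_graph(smiles: str, labels=None) -> MolecularGraph:
    """Parse a SMILES string into a featurised :class:`MolecularGraph`.

    Raises ``ValueError`` for unparsable SMILES, zero-atom results and
    unsupported elements.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"SMILES yields no heavy atoms: {smiles!r}")
    node_features = np.stack(
        [featurize_atom(_describe_atom(a)) for a in mol.GetAtoms()]
    )
    edges, edge_feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        fv = _describe_bond(bond)
        edges.extend([(i, j), (j, i)])
        edge_feats.extend([fv, fv.copy()])
    edge_index = np.array(edges, dtype=np.int64).reshape(-1, 2)
    edge_features = (
        np.stack(edge_feats) if edge_feats else np.zeros((0, N_BOND_FEATURES))
    )
    return MolecularGraph(
        node_features=node_features,
        edge_index=edge_index,
        edge_features=edge_features,
        labels=labels,
        smiles=smiles,
    )
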