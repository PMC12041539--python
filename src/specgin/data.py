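"""Datasets: CSV readers, in-repo fixture molecules and a synthetic task.

The fixture collection is a deterministic list of >200 small drug-like
molecules assembled from curated drugs plus substituted-scaffold and
homologous series, covering aromatic rings, charged atoms and E/Z double
bonds. The synthetic classification task labels a molecule 1 iff it
contains a ring — a rule that is literally visible to the featurisation
(the in-ring node flag), so the task is structurally learnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .featurize import ELEMENTS, smiles_to_graph
from .graph import MolecularGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetTable",
    "read_smiles_csv",
    "fixture_molecules",
    "synthetic_classification_dataset",
    "save_graphs",
    "load_graphs",
]


@dataclass
class DatasetTable:
    """SMILES records with an optional (n, k) label matrix (NaN = missing)."""

    smiles: list[str]
    labels: np.ndarray | None = None
    label_columns: list[str] = field(default_factory=list)
    task_mode: str = "classification"
    n_dropped: int = 0

    @property
    def n_tasks(self) -> int:
        return 0 if self.labels is None else self.labels.shape[1]

    def __len__(self) -> int:
        return len(self.smiles)

    def to_graphs(self) -> list[MolecularGraph]:
        out = []
        for i, smi in enumerate(self.smiles):
            lab = None if self.labels is None else self.labels[i]
            out.append(smiles_to_graph(smi, labels=lab))
        return out


def read_smiles_csv(path, task_mode: str = "classification") -> DatasetTable:
    """Read a MoleculeNet-layout CSV: a ``smiles`` column plus label columns.

    Empty label cells become NaN (missing), never 0. Rows whose SMILES
    cannot be featurised are dropped with a logged warning.
    """
    frame = pd.read_csv(path)
    if "smiles" not in frame.columns:
        raise ValueError(f"{path}: no 'smiles' column found")
    label_columns = [c for c in frame.columns if c != "smiles"]
    smiles, rows, dropped = [], [], 0
    for _, row in frame.iterrows():
        smi = str(row["smiles"])
        try:
            smiles_to_graph(smi)
        except ValueError as exc:
            dropped += 1
            logger.warning("dropping row: %s", exc)
            continue
        smiles.append(smi)
        rows.append([pd.to_numeric(row[c], errors="coerce") for c in label_columns])
    labels = (
        np.asarray(rows, dtype=np.float64).reshape(len(smiles), len(label_columns))
        if label_columns else None
    )
    return DatasetTable(
        smiles=smiles, labels=labels, label_columns=label_columns,
        task_mode=task_mode, n_dropped=dropped,
    )


_DRUGS = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CN1CCCC1c1cccnc1",                 # nicotine
    "c1ccc2[nH]ccc2c1",                 # indole
    "OCC1OC(O)C(O)C(O)C1O",             # glucopyranose
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "CC(N)Cc1ccccc1",                   # amphetamine
]

_CHARGED = [
    "C[N+](C)(C)C",
    "CC(=O)[O-]",
    "C[NH3+]",
    "[O-]C(=O)c1ccccc1",
    "C[N+](C)(C)CCO",
]

_STEREO = [
    "C/C=C/C",
    "C/C=C\\C",
    "C/C=C/C(=O)O",
    "CC/C=C\\CC",
    "C/C=C/c1ccccc1",
]

_RING_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1",
    "C1CCCCC1", "C1CCNCC1", "C1CCOC1", "c1cncnc1",
]

_SUBSTITUENTS = [
    "", "C", "CC", "CCC", "CCCC", "N", "O", "OC", "OCC",
    "ClC", "FC", "BrC", "NC",
]

_CHAIN_TAILS = [
    "", "O", "N", "Cl", "Br", "F", "S", "OC",
    "C(=O)O", "C(=O)N", "C#N", "C=C", "C(=O)C",
]


@lru_cache(maxsize=1)
def _fixture_list() -> tuple[tuple[str, int], ...]:
    candidates: list[str] = []
    candidates += _DRUGS + _CHARGED + _STEREO
    for scaffold in _RING_SCAFFOLDS:
        for sub in _SUBSTITUENTS:
            candidates.append(sub + scaffold)
    for k in range(1, 9):
        chain = "C" * k
        for tail in _CHAIN_TAILS:
            candidates.append(chain + tail)
    out, seen = [], set()
    for smi in candidates:
        if smi in seen:
            continue
        seen.add(smi)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumAtoms() == 0:
            continue
        if any(a.GetSymbol() not in ELEMENTS for a in mol.GetAtoms()):
            continue
        label = int(mol.GetRingInfo().NumRings() > 0)
        out.append((smi, label))
    return tuple(out)


def fixture_molecules() -> list[tuple[str, int]]:
    """Deterministic list of >=200 valid drug-like (SMILES, ring-label) pairs."""
    return list(_fixture_list())


def _ring_label(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return int(mol.GetRingInfo().NumRings() > 0)


_ATTACH_VOCAB = ["C", "CC", "CCC", "N", "O", "OC"]


def synthetic_classification_dataset(n: int, rng: np.random.Generator,
                                     task_mode: str = "classification") -> DatasetTable:
    """Sample a balanced ring/no-ring labelled dataset of size ``n``.

    Molecules are drawn from the fixtures (each class with probability
    1/2) and randomly decorated with a small substituent when the
    decorated SMILES is still valid and keeps its class. Labels are a
    deterministic function of the graph (ring presence).
    """
    if n < 10:
        raise ValueError("n must be at least 10")
    fixtures = fixture_molecules()
    ring_pool = [s for s, lab in fixtures if lab == 1]
    chain_pool = [s for s, lab in fixtures if lab == 0]
    smiles, labels = [], []
    for _ in range(n):
        want_ring = rng.random() < 0.5
        pool = ring_pool if want_ring else chain_pool
        base = pool[rng.integers(len(pool))]
        smi = base
        if rng.random() < 0.5:
            candidate = _ATTACH_VOCAB[rng.integers(len(_ATTACH_VOCAB))] + base
            RDLogger.DisableLog("rdApp.error")  # invalid candidates are expected
            try:
                mol = Chem.MolFromSmiles(candidate)
            finally:
                RDLogger.EnableLog("rdApp.error")
            if (
                mol is not None
                and mol.GetNumAtoms() > 0
                and all(a.GetSymbol() in ELEMENTS for a in mol.GetAtoms())
                and _ring_label(candidate) == int(want_ring)
            ):
                smi = candidate
        smiles.append(smi)
        labels.append(_ring_label(smi))
    return DatasetTable(
        smiles=smiles,
        labels=np.asarray(labels, dtype=np.float64)[:, None],
        label_columns=["has_ring"],
        task_mode=task_mode,
    )


def save_graphs(path, graphs: list[MolecularGraph]) -> None:
    """Serialise featurised graphs to an .npz container."""
    arrays: dict[str, np.ndarray] = {"n_graphs": np.array(len(graphs))}
    for i, g in enumerate(graphs):
        arrays[f"x_{i}"] = g.node_features
        arrays[f"ei_{i}"] = g.edge_index
        arrays[f"ef_{i}"] = g.edge_features
        if g.labels is not None:
            arrays[f"y_{i}"] = g.labels
        arrays[f"smi_{i}"] = np.array(g.smiles)
    np.savez_compressed(path, **arrays)


def load_graphs(path) -> list[MolecularGraph]:
    with np.load(path, allow_pickle=False) as data:
        n = int(data["n_graphs"])
        out = []
        for i in range(n):
            out.append(MolecularGraph(
                node_features=data[f"x_{i}"],
                edge_index=data[f"ei_{i}"],
                edge_features=data[f"ef_{i}"],
                labels=data[f"y_{i}"] if f"y_{i}" in data else None,
                smiles=str(data[f"smi_{i}"]),
            ))
    return out
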