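"""The in-memory molecular graph container.

A molecule is an undirected heavy-atom graph. Every bond is stored as two
directed entries (message-passing convention) with identical 9-d feature
vectors on the mirrored pair. Node features are the 56-d atom vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MolecularGraph"]

N_ATOM_FEATURES = 56
N_BOND_FEATURES = 9


@dataclass
class MolecularGraph:
    """Featurised molecular graph.

    Parameters
    ----------
    node_features : (n, 56) float array
    edge_index : (m, 2) int array
        Directed edges, 0-based; every undirected bond appears in both
        directions. No self-loops.
    edge_features : (m, 9) float array
        One bond vector per stored direction; mirrored pairs are equal.
    labels : optional (k,) float array
        Task labels; NaN marks a missing classification label.
    smiles : str
        Provenance string.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    labels: np.ndarray | None = None
    smiles: str = ""
    _adjacency: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64).reshape(
            -1, N_BOND_FEATURES
        )
        if self.labels is not None:
            self.labels = np.atleast_1d(np.asarray(self.labels, dtype=np.float64))
        n = self.node_features.shape[0]
        if n < 1:
            raise ValueError("a molecular graph needs at least one atom")
        if self.node_features.shape[1] != N_ATOM_FEATURES:
            raise ValueError(
                f"node features must be {N_ATOM_FEATURES}-dimensional, "
                f"got {self.node_features.shape[1]}"
            )
        m = self.edge_index.shape[0]
        if self.edge_features.shape[0] != m:
            raise ValueError("edge_features row count must match edge_index")
        if m:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise ValueError("edge index out of range")
            if np.any(self.edge_index[:, 0] == self.edge_index[:, 1]):
                raise ValueError("self-loops are not allowed")
            fwd = {tuple(e) for e in self.edge_index}
            if {(j, i) for i, j in fwd} != fwd:
                raise ValueError("edge set must be symmetric (both directions stored)")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return self.edge_index.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edge_index.shape[0] // 2

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (cached)."""
        if self._adjacency is None:
            a = np.zeros((self.n_nodes, self.n_nodes))
            if self.n_directed_edges:
                a[self.edge_index[:, 0], self.edge_index[:, 1]] = 1.0
            self._adjacency = a
        return self._adjacency

    def undirected_edges(self) -> list[tuple[int, int]]:
        """Unique (i, j) bond pairs with i < j, sorted."""
        pairs = {tuple(sorted(e)) for e in self.edge_index}
        return sorted(pairs)

    def permute(self, perm: np.ndarray) -> "MolecularGraph":
        """Relabel nodes: new index of old node i is perm[i]."""
        perm = np.asarray(perm, dtype=np.int64)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return MolecularGraph(
            node_features=self.node_features[inv],
            edge_index=perm[self.edge_index],
            edge_features=self.edge_features.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            smiles=self.smiles,
        )
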