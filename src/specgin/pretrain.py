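"""Contrastive self-supervised pre-training of the spectral encoder.

Each molecular graph is encoded to per-node embeddings z. Two perturbed
copies are formed by stepping along random unit directions k1, k2 with
Gaussian magnitudes eps1, eps2 ~ N(0, sigma^2), where sigma^2 is the
(population) variance of z's entries:

    z1 = z + eps1 k1,     z2 = z + eps2 k2.

All three embeddings are decoded to edge-probability matrices through the
inner-product decoder. The objective is

    Loss = ReconstructionLoss + lambda * InformationLoss,   lambda = 0.4,

where the reconstruction term is binary cross-entropy over true edges
(positives) and negatively-sampled absent edges (1:1 ratio), and the
information term contrasts the clean reconstruction against the two
perturbed ones through a cosine link:

    InfoLoss = -log[ exp(g(x, p)) / (exp(g(x, p1)) + exp(g(x, p2)) + eps) ].

Optimised with Adam(beta1=0.5, beta2=0.999, lr=2e-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .autodiff import Tensor, stack
from .featurize import smiles_to_graph
from .graph import MolecularGraph
from .optim import Adam
from .spectral import ChebEncoder, ScaledLaplacian, decode, graph_scaled_laplacian

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationDraw",
    "PretrainLoss",
    "perturb_embedding",
    "cosine_link",
    "information_loss",
    "negative_sample",
    "reconstruction_loss",
    "SpectralGraphAutoencoder",
    "pretrain",
]

PROB_CLIP = 1e-7  # probabilities are kept inside [PROB_CLIP, 1 - PROB_CLIP]


@dataclass
class PerturbationDraw:
    """A pair of Gaussian latent perturbations of one embedding."""

    k1: np.ndarray
    k2: np.ndarray
    eps1: float
    eps2: float
    z1: np.ndarray
    z2: np.ndarray
    sigma2: float


@dataclass
class PretrainLoss:
    """Composite pre-training loss; total = reconstruction + lambda * information."""

    reconstruction: float
    information: float
    penalty_lambda: float = 0.4

    @property
    def total(self) -> float:
        return self.reconstruction + self.penalty_lambda * self.information


def perturb_embedding(z: np.ndarray, rng: np.random.Generator) -> PerturbationDraw:
    """Draw z1, z2 = z + eps_i * k_i with unit k_i and eps_i ~ N(0, var(z)).

    A constant z (zero variance) yields z1 = z2 = z exactly.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.size < 1:
        raise ValueError("embedding must be non-empty")
    sigma2 = float(z.var())  # population variance over all entries
    sigma = np.sqrt(sigma2)

    def unit_direction() -> np.ndarray:
        k = rng.standard_normal(z.shape)
        norm = np.linalg.norm(k)
        while norm == 0.0:  # probability-zero fallback
            k = rng.standard_normal(z.shape)
            norm = np.linalg.norm(k)
        return k / norm

    k1, k2 = unit_direction(), unit_direction()
    eps1 = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    eps2 = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    return PerturbationDraw(
        k1=k1, k2=k2, eps1=eps1, eps2=eps2,
        z1=z + eps1 * k1, z2=z + eps2 * k2, sigma2=sigma2,
    )


def _cosine_link_t(x: Tensor, p: Tensor) -> Tensor:
    xf, pf = x.ravel(), p.ravel()
    nx = float(np.linalg.norm(xf.data))
    np_ = float(np.linalg.norm(pf.data))
    if nx == 0.0 or np_ == 0.0:
        raise ValueError("cosine similarity is undefined for an all-zero input")
    return (xf * pf).sum() / ((xf * xf).sum().sqrt() * (pf * pf).sum().sqrt())


def cosine_link(x, p) -> float:
    """Cosine similarity of two (flattened) matrices, in [-1, 1]."""
    return float(_cosine_link_t(Tensor(np.asarray(x)), Tensor(np.asarray(p))).data)


def _information_loss_t(x_adj: Tensor, p: Tensor, p1: Tensor, p2: Tensor,
                        eps_num: float = 1e-8) -> Tensor:
    g = _cosine_link_t(x_adj, p)
    g1 = _cosine_link_t(x_adj, p1)
    g2 = _cosine_link_t(x_adj, p2)
    return -(g.exp() / (g1.exp() + g2.exp() + eps_num)).log()


def information_loss(x, p, p1, p2, eps_num: float = 1e-8) -> float:
    """Contrastive information loss of the clean vs perturbed reconstructions."""
    return float(
        _information_loss_t(
            Tensor(np.asarray(x)), Tensor(np.asarray(p)),
            Tensor(np.asarray(p1)), Tensor(np.asarray(p2)), eps_num,
        ).data
    )


def negative_sample(graph: MolecularGraph, count: int,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample ``count`` distinct absent (non-self-loop) node pairs."""
    n = graph.n_nodes
    present = set(graph.undirected_edges())
    absent = [
        (i, j) for i in range(n) for j in range(i + 1, n) if (i, j) not in present
    ]
    if not absent:
        raise ValueError("graph is complete: no negative pairs exist")
    if count > len(absent):
        raise ValueError(
            f"requested {count} negatives but only {len(absent)} absent pairs exist"
        )
    idx = rng.choice(len(absent), size=count, replace=False)
    return [absent[i] for i in idx]


def _reconstruction_loss_t(p: Tensor, positives, negatives) -> Tensor:
    pos = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
    neg = np.asarray(negatives, dtype=np.int64).reshape(-1, 2) if len(negatives) else None
    p_pos = p[(pos[:, 0], pos[:, 1])].clip(PROB_CLIP, 1 - PROB_CLIP)
    terms = -(p_pos.log().sum())
    total = len(pos)
    if neg is not None:
        p_neg = p[(neg[:, 0], neg[:, 1])].clip(PROB_CLIP, 1 - PROB_CLIP)
        terms = terms + -((1.0 - p_neg).log().sum())
        total += len(neg)
    return terms / total


def _reconstruction_loss_logits_t(a: Tensor, positives, negatives) -> Tensor:
    """BCE computed from raw inner products a = z z^T (stable form).

    Identical in value to the probability form away from the clipping
    floor, but keeps gradients alive when sigmoid(a) saturates.
    """
    pos = np.asarray(positives, dtype=np.int64).reshape(-1, 2)
    neg = np.asarray(negatives, dtype=np.int64).reshape(-1, 2) if len(negatives) else None
    terms = (-a[(pos[:, 0], pos[:, 1])]).softplus().sum()  # -log sigmoid(a)
    total = len(pos)
    if neg is not None:
        terms = terms + a[(neg[:, 0], neg[:, 1])].softplus().sum()  # -log(1-sigmoid)
        total += len(neg)
    return terms / total


def reconstruction_loss(p, positive_edges, negative_pairs) -> float:
    """Mean binary cross-entropy over positive edges and negative pairs."""
    if len(positive_edges) == 0 or len(negative_pairs) == 0:
        raise ValueError("both positive and negative lists must be nonempty")
    return float(
        _reconstruction_loss_t(Tensor(np.asarray(p)), positive_edges, negative_pairs).data
    )


def _as_graphs(X) -> list[MolecularGraph]:
    out = []
    for item in X:
        if isinstance(item, MolecularGraph):
            out.append(item)
        elif isinstance(item, str):
            out.append(smiles_to_graph(item))
        else:
            raise TypeError(f"expected MolecularGraph or SMILES, got {type(item)}")
    return out


class SpectralGraphAutoencoder(TransformerMixin, BaseEstimator):
    """Contrastively pre-trained spectral graph autoencoder.

    Parameters
    ----------
    epochs : int
        Training epochs over the dataset.
    batch_size : int
        Graphs per optimiser step; per-graph losses are averaged.
    penalty_lambda : float
        Weight of the information term in the composite loss.
    learning_rate, beta1, beta2 : float
        Adam settings; beta1 = 0.5 stabilises the contrastive stage.
    init : {"scaled", "normal"}
        Weight initialisation: variance-scaled normal (default) or N(0, 1).
    laplacian : {"sym", "comb"}
        Symmetric-normalised (default) or combinatorial Laplacian.
    lambda_max : "power" or float
        Per-graph power iteration, or a fixed scaling constant.
    eps_num : float
        Numerical floor in the information-loss denominator.
    random_state : int or None
        Seed for init, batching, perturbations and negative sampling.

    Attributes
    ----------
    encoder_ : ChebEncoder
        The trained backbone.
    loss_trace_ : list of dict
        Per-epoch mean total / reconstruction / information losses.
    n_skipped_ : int
        Graphs excluded because they have no positive edge or no absent pair.
    """

    def __init__(self, epochs: int = 30, batch_size: int = 32,
                 penalty_lambda: float = 0.4, learning_rate: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, init: str = "scaled",
                 laplacian: str = "sym", lambda_max="power",
                 eps_num: float = 1e-8, random_state: int | None = None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.penalty_lambda = penalty_lambda
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.init = init
        self.laplacian = laplacian
        self.lambda_max = lambda_max
        self.eps_num = eps_num
        self.random_state = random_state

    # -- internals ------------------------------------------------------------
    def _prepare(self, graphs: list[MolecularGraph]):
        """Cache Laplacians, positives and negative-pool sizes per graph."""
        usable, skipped = [], 0
        for g in graphs:
            positives = g.undirected_edges()
            n_pairs = g.n_nodes * (g.n_nodes - 1) // 2
            if not positives or len(positives) >= n_pairs:
                skipped += 1  # no edge to reconstruct, or complete graph
                continue
            lap = graph_scaled_laplacian(g, self.laplacian, self.lambda_max)
            usable.append((g, lap, positives))
        return usable, skipped

    def _graph_loss(self, graph: MolecularGraph, lap: ScaledLaplacian,
                    positives, rng: np.random.Generator):
        z = self.encoder_(Tensor(graph.node_features), lap)
        draw = perturb_embedding(z.data, rng)
        z1 = z + Tensor(draw.eps1 * draw.k1)
        z2 = z + Tensor(draw.eps2 * draw.k2)
        a = z @ z.T
        p = a.sigmoid()
        p1 = decode(z1)
        p2 = decode(z2)
        n_pairs = graph.n_nodes * (graph.n_nodes - 1) // 2
        n_neg = min(len(positives), n_pairs - len(positives))  # 1:1 where possible
        negatives = negative_sample(graph, n_neg, rng)
        rec = _reconstruction_loss_logits_t(a, positives, negatives)
        info = _information_loss_t(
            Tensor(graph.adjacency()), p, p1, p2, self.eps_num
        )
        return rec, info

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y=None):
        """Pre-train on a collection of molecular graphs (or SMILES)."""
        graphs = _as_graphs(X)
        if not graphs:
            raise ValueError("training set is empty")
        rng = np.random.default_rng(self.random_state)
        self.encoder_ = ChebEncoder(rng, init=self.init)
        usable, self.n_skipped_ = self._prepare(graphs)
        if not usable:
            raise ValueError("no graph has both a positive edge and an absent pair")
        if self.n_skipped_:
            logger.info("skipping %d graphs without usable edge structure",
                        self.n_skipped_)
        opt = Adam(self.encoder_.parameters(), lr=self.learning_rate,
                   beta1=self.beta1, beta2=self.beta2)
        self.loss_trace_ = []
        order = np.arange(len(usable))
        for epoch in range(self.epochs):
            rng.shuffle(order)
            sums = np.zeros(3)
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                losses = []
                for idx in batch:
                    g, lap, positives = usable[idx]
                    rec, info = self._graph_loss(g, lap, positives, rng)
                    loss_g = rec + self.penalty_lambda * info
                    if not np.isfinite(loss_g.data):
                        raise RuntimeError(
                            f"non-finite loss at epoch {epoch} on graph "
                            f"{idx} ({g.smiles!r})"
                        )
                    losses.append(loss_g)
                    sums += (float(loss_g.data), float(rec.data), float(info.data))
                batch_loss = stack(losses).mean()
                opt.zero_grad()
                batch_loss.backward()
                opt.step()
            n = len(order)
            self.loss_trace_.append({
                "epoch": epoch,
                "total": sums[0] / n,
                "reconstruction": sums[1] / n,
                "information": sums[2] / n,
            })
        return self

    def transform(self, X) -> list[np.ndarray]:
        """Per-node 512-d embeddings for each graph."""
        self._check_fitted()
        return [
            self.encoder_.encode(g, self.laplacian, self.lambda_max)
            for g in _as_graphs(X)
        ]

    def reconstruction_score(self, X, random_state: int | None = None) -> float:
        """Mean reconstruction BCE on held-out graphs (1:1 negative sampling)."""
        self._check_fitted()
        rng = np.random.default_rng(
            random_state if random_state is not None else self.random_state
        )
        usable, _ = self._prepare(_as_graphs(X))
        if not usable:
            raise ValueError("no scorable graphs")
        vals = []
        for g, lap, positives in usable:
            z = self.encoder_.encode(g, self.laplacian, self.lambda_max)
            p = decode(z)
            n_pairs = g.n_nodes * (g.n_nodes - 1) // 2
            negatives = negative_sample(
                g, min(len(positives), n_pairs - len(positives)), rng
            )
            vals.append(reconstruction_loss(p, positives, negatives))
        return float(np.mean(vals))

    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


def pretrain(dataset, config: dict | None = None):
    """Functional wrapper: pre-train and return (estimator, loss trace)."""
    est = SpectralGraphAutoencoder(**(config or {}))
    est.fit(dataset)
    return est, est.loss_trace_
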