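"""White-box edge-sensitivity attack on the dual-branch victim model.

**Scheduler.** Attacks fire at random intervals: a point theta is drawn
uniformly on [0, pi] and the attack runs iff sin(theta) >= 0.5, which
happens with probability 2/3 (the measure of [pi/6, 5pi/6] over pi).

**Gradient attack.** With white-box access to the (pre-trained, possibly
fine-tuned) spectral backbone, a graph is encoded to z, perturbed to z1, z2
by the same Gaussian latent procedure used in pre-training, and the three
raw reconstructions A = z z^T, A1 = z1 z1^T, A2 = z2 z2^T are formed. The
contrastive pre-training loss evaluated on these matrices is differentiated
with respect to each of them:

    dL/dA' = dL/dA + dL/dA1 + dL/dA2        (symmetrised)

and mu_g is the mean of dL/dA' over existing-edge entries. An edge (i, j)
is dropped when mu_g > dL/dA'[i, j] (strictly): edges whose gradient sits
below the mean carry low loss sensitivity, and removing them perturbs the
graph while staying inside the original edge set, so the attacked
adjacency stays symmetric and 0/1-valued and never gains edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .graph import MolecularGraph
from .pretrain import (
    SpectralGraphAutoencoder,
    _information_loss_t,
    _reconstruction_loss_logits_t,
    negative_sample,
    perturb_embedding,
)

__all__ = [
    "AttackSchedule",
    "EdgeGradient",
    "AttackMask",
    "should_attack",
    "contrastive_adjacency_loss",
    "attack_gradients",
    "edge_drop_mask",
    "apply_attack",
    "EdgeDropAttack",
    "evaluate_under_attack",
]


@dataclass
class AttackSchedule:
    """Sine-wave random scheduler (threshold 0.5)."""

    rng: np.random.Generator
    threshold: float = 0.5


def should_attack(schedule: AttackSchedule, theta: float | None = None) -> bool:
    """Decide whether to attack: theta ~ U[0, pi], attack iff sin(theta) >= 0.5."""
    if theta is None:
        theta = schedule.rng.uniform(0.0, np.pi)
    return bool(np.sin(theta) >= schedule.threshold)


@dataclass
class EdgeGradient:
    """Combined symmetrised gradient dL/dA' and its mean over edges."""

    combined: np.ndarray
    mu_g: float


@dataclass
class AttackMask:
    """Symmetric boolean matrix of edges to drop (subset of the edge set)."""

    drop: np.ndarray

    @property
    def n_dropped_bonds(self) -> int:
        return int(self.drop.sum()) // 2


def contrastive_adjacency_loss(A, A1, A2, x_adj: np.ndarray, positives,
                               negatives, penalty_lambda: float = 0.4,
                               eps_num: float = 1e-8) -> Tensor:
    """Pre-training loss evaluated on raw reconstruction matrices.

    ``A, A1, A2`` may be arrays or leaf Tensors (the attack differentiates
    with respect to them). Probabilities are sigmoid(A).
    """
    a = A if isinstance(A, Tensor) else Tensor(A)
    a1 = A1 if isinstance(A1, Tensor) else Tensor(A1)
    a2 = A2 if isinstance(A2, Tensor) else Tensor(A2)
    p, p1, p2 = a.sigmoid(), a1.sigmoid(), a2.sigmoid()
    rec = _reconstruction_loss_logits_t(a, positives, negatives)
    info = _information_loss_t(Tensor(x_adj), p, p1, p2, eps_num)
    return rec + penalty_lambda * info


def _resolve_backbone(backbone):
    """Return a graph -> (n, 512) embedding callable."""
    if isinstance(backbone, SpectralGraphAutoencoder):
        backbone = backbone.encoder_
    if hasattr(backbone, "spectral_embedding"):
        return backbone.spectral_embedding
    if hasattr(backbone, "encode"):
        return backbone.encode
    raise TypeError(f"cannot use {type(backbone)} as an attack backbone")


def attack_gradients(graph: MolecularGraph, backbone,
                     rng: np.random.Generator, penalty_lambda: float = 0.4,
                     eps_num: float = 1e-8, mean_over: str = "edges",
                     laplacian: str = "sym", lambda_max="power") -> EdgeGradient:
    """Gradient of the contrastive loss w.r.t. the reconstructed adjacencies."""
    embed = _resolve_backbone(backbone)
    z = embed(graph, laplacian, lambda_max)
    draw = perturb_embedding(z, rng)
    A = Tensor(z @ z.T, requires_grad=True)
    A1 = Tensor(draw.z1 @ draw.z1.T, requires_grad=True)
    A2 = Tensor(draw.z2 @ draw.z2.T, requires_grad=True)
    positives = graph.undirected_edges()
    n_pairs = graph.n_nodes * (graph.n_nodes - 1) // 2
    if not positives:
        # an edgeless graph has nothing to attack
        return EdgeGradient(np.zeros((graph.n_nodes, graph.n_nodes)), 0.0)
    n_neg = min(len(positives), n_pairs - len(positives))
    negatives = negative_sample(graph, n_neg, rng) if n_neg else []
    loss = contrastive_adjacency_loss(
        A, A1, A2, graph.adjacency(), positives, negatives,
        penalty_lambda, eps_num,
    )
    loss.backward()
    combined = A.grad + A1.grad + A2.grad
    combined = 0.5 * (combined + combined.T)
    if not np.all(np.isfinite(combined)):
        raise RuntimeError("non-finite attack gradient")
    if mean_over == "edges":
        rows, cols = graph.edge_index[:, 0], graph.edge_index[:, 1]
        mu_g = float(combined[rows, cols].mean())
    elif mean_over == "all_entries":
        mu_g = float(combined.mean())
    else:
        raise ValueError(f"unknown mean_over: {mean_over!r}")
    return EdgeGradient(combined=combined, mu_g=mu_g)


def edge_drop_mask(grad: EdgeGradient, graph: MolecularGraph) -> AttackMask:
    """Drop edge (i, j) iff mu_g > combined[i, j], strictly; non-edges never."""
    drop = np.zeros((graph.n_nodes, graph.n_nodes), dtype=bool)
    for i, j in graph.undirected_edges():
        if grad.mu_g > grad.combined[i, j]:
            drop[i, j] = drop[j, i] = True
    return AttackMask(drop=drop)


def apply_attack(graph: MolecularGraph, mask: AttackMask) -> MolecularGraph:
    """Remove masked edges (both directions); node features untouched."""
    if mask.drop.shape != (graph.n_nodes, graph.n_nodes):
        raise ValueError("mask shape does not match graph")
    keep = ~mask.drop[graph.edge_index[:, 0], graph.edge_index[:, 1]]
    return MolecularGraph(
        node_features=graph.node_features.copy(),
        edge_index=graph.edge_index[keep],
        edge_features=graph.edge_features[keep],
        labels=None if graph.labels is None else graph.labels.copy(),
        smiles=graph.smiles,
    )


@dataclass
class EdgeDropAttack:
    """Bundled attack: gradients -> mask -> perturbed graph."""

    backbone: object
    penalty_lambda: float = 0.4
    eps_num: float = 1e-8
    mean_over: str = "edges"
    laplacian: str = "sym"
    lambda_max: object = "power"

    def __call__(self, graph: MolecularGraph,
                 rng: np.random.Generator) -> tuple[MolecularGraph, AttackMask]:
        grad = attack_gradients(
            graph, self.backbone, rng, self.penalty_lambda, self.eps_num,
            self.mean_over, self.laplacian, self.lambda_max,
        )
        mask = edge_drop_mask(grad, graph)
        return apply_attack(graph, mask), mask


def evaluate_under_attack(estimator, X, y, n_runs: int = 5,
                          schedule: AttackSchedule | None = None,
                          threshold: float = 0.5, batch_size: int = 32,
                          granularity: str = "batch",
                          random_state: int | None = None,
                          attack: EdgeDropAttack | None = None) -> dict:
    """Clean vs attacked test metrics over several randomised runs.

    The scheduler decides per batch (default) or per sample whether to
    attack. Returns clean/attacked metrics per run, their means, the
    percentage drop, and a per-sample log of attack decisions and edge
    drops. For classification the metric is macro ROC-AUC; for regression
    it is mean squared error.
    """
    from .metrics import roc_auc  # local import avoids a cycle
    from .pretrain import _as_graphs

    graphs = _as_graphs(X)
    labels = np.asarray(y, dtype=np.float64)
    if labels.ndim == 1:
        labels = labels[:, None]
    task_mode = estimator.model_.task_mode
    if attack is None:
        attack = EdgeDropAttack(
            backbone=estimator.model_,
            laplacian=estimator.laplacian,
            lambda_max=estimator.lambda_max,
        )

    def metric(scores: np.ndarray) -> float:
        if task_mode == "classification":
            return roc_auc(labels, scores)
        mask = ~np.isnan(labels)
        return float(np.mean((scores[mask] - labels[mask]) ** 2))

    clean_scores = estimator.decision_values(graphs)
    clean_metric = metric(clean_scores)

    root = np.random.default_rng(random_state)
    run_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    attacked_metrics, logs = [], []
    for seed in run_seeds:
        rng = np.random.default_rng(int(seed))
        sched = schedule if schedule is not None else AttackSchedule(rng, threshold)
        run_graphs: list[MolecularGraph] = []
        run_log: list[dict] = []
        for start in range(0, len(graphs), batch_size):
            batch = graphs[start:start + batch_size]
            fire_batch = (
                should_attack(sched) if granularity == "batch" else None
            )
            for offset, g in enumerate(batch):
                fire = (
                    fire_batch if granularity == "batch" else should_attack(sched)
                )
                if fire and g.n_directed_edges:
                    attacked_g, mask = attack(g, rng)
                    run_graphs.append(attacked_g)
                    run_log.append({
                        "index": start + offset, "attacked": True,
                        "edges_dropped": mask.n_dropped_bonds,
                    })
                else:
                    run_graphs.append(g)
                    run_log.append({
                        "index": start + offset, "attacked": bool(fire),
                        "edges_dropped": 0,
                    })
        attacked_scores = estimator.decision_values(run_graphs)
        attacked_metrics.append(metric(attacked_scores))
        logs.append(run_log)

    clean_mean = clean_metric
    attacked_mean = float(np.mean(attacked_metrics))
    return {
        "task_mode": task_mode,
        "clean_metric": clean_mean,
        "attacked_metrics": [float(m) for m in attacked_metrics],
        "attacked_metric_mean": attacked_mean,
        "drop_percent": 100.0 * (clean_mean - attacked_mean) / clean_mean
        if clean_mean else float("nan"),
        "logs": logs,
    }
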