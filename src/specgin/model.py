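"""Dual-branch molecular property prediction network.

Two parallel branches consume the featurised graph:

* a **spectral branch** — three Chebyshev convolutions (56 -> 128 -> 256 ->
  512, K = 3) whose weights can be transferred from the contrastively
  pre-trained autoencoder;
* an **isomorphic branch** — three GIN-style layers using injective sum
  aggregation, h'_v = ReLU(BN(Linear((1 + eps) h_v + sum_{u in N(v)} h_u))).

After every layer the two branch outputs are fused by elementwise addition
and the fused tensor feeds BOTH branches' next layers; the final fusion is
mean-pooled into a 512-d graph embedding, passed through a 512 -> 256
ReLU/batch-norm head and a 256 -> k output layer (sigmoid for
classification, identity for regression). The whole network stays under
one million trainable parameters for k <= 12 tasks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score

from .autodiff import Tensor, stack
from .graph import MolecularGraph
from .nn import BatchNorm1d, ChebConv, Linear, Module, Parameter
from .optim import Adam
from .pretrain import _as_graphs, SpectralGraphAutoencoder
from .spectral import ChebEncoder, ScaledLaplacian, graph_scaled_laplacian

__all__ = [
    "GINLayer",
    "DualBranchModel",
    "iso_layer",
    "fuse_layers",
    "global_mean_pool",
    "classification_loss",
    "count_parameters",
    "DualBranchGraphClassifier",
    "DualBranchGraphRegressor",
    "train_classifier",
]

DIMS = (56, 128, 256, 512)


class GINLayer(Module):
    """Graph-isomorphic convolution with a single affine link function."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 init: str = "scaled", epsilon_self: float = 0.0,
                 learn_epsilon: bool = False, batch_norm: bool = True):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.link = Linear(in_dim, out_dim, rng, init=init)
        # per-graph normalisation: node statistics of the current graph
        self.bn = BatchNorm1d(out_dim, track_running_stats=False) if batch_norm else None
        if learn_epsilon:
            self.epsilon = Parameter(np.array(float(epsilon_self)))
        else:
            object.__setattr__(self, "epsilon", Tensor(float(epsilon_self)))

    def forward(self, x, adjacency, activate: bool = True):
        x = x if isinstance(x, Tensor) else Tensor(x)
        adj = adjacency if isinstance(adjacency, Tensor) else Tensor(adjacency)
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"GINLayer expected {self.in_dim} input features, got {x.shape[-1]}"
            )
        # injective multiset aggregation: (1 + eps) h_v + sum over neighbours
        h = self.link((1.0 + self.epsilon) * x + adj @ x)
        if self.bn is not None:
            h = self.bn(h)
        return h.relu() if activate else h

    __call__ = forward


def iso_layer(x, adjacency, params: GINLayer) -> np.ndarray:
    """Functional form of the isomorphic convolution (eval mode)."""
    was_training = params.training
    params.eval()
    try:
        out = params(Tensor(np.asarray(x, dtype=np.float64)), adjacency)
    finally:
        params.train(was_training)
    return out.data


def fuse_layers(spectral_out, iso_out):
    """Per-layer branch fusion: elementwise sum (commutative)."""
    a = spectral_out if isinstance(spectral_out, Tensor) else np.asarray(spectral_out)
    b = iso_out if isinstance(iso_out, Tensor) else np.asarray(iso_out)
    shape_a = a.shape if isinstance(a, Tensor) else a.shape
    shape_b = b.shape if isinstance(b, Tensor) else b.shape
    if shape_a != shape_b:
        raise ValueError(f"cannot fuse shapes {shape_a} and {shape_b}")
    return a + b


def global_mean_pool(x):
    """Graph readout: arithmetic mean over nodes."""
    if isinstance(x, Tensor):
        if x.shape[0] == 0:
            raise ValueError("cannot pool an empty graph")
        return x.mean(axis=0)
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    return x.mean(axis=0)


def _masked_nll_t(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood over observed (non-NaN) labels."""
    labels = np.asarray(labels, dtype=np.float64).reshape(probs.shape)
    mask = ~np.isnan(labels)
    if not mask.any():
        raise ValueError("all labels are missing")
    idx = np.nonzero(mask)
    p = probs[idx].clip(1e-7, 1 - 1e-7)
    y = labels[idx]
    terms = -(Tensor(y) * p.log()) - (Tensor(1.0 - y) * (1.0 - p).log())
    return terms.mean()


def _masked_nll_logits_t(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Masked BCE from logits: softplus(x) - x y, numerically stable."""
    labels = np.asarray(labels, dtype=np.float64).reshape(logits.shape)
    mask = ~np.isnan(labels)
    if not mask.any():
        raise ValueError("all labels are missing")
    idx = np.nonzero(mask)
    x = logits[idx]
    return (x.softplus() - x * Tensor(labels[idx])).mean()


def _masked_mse_t(preds: Tensor, labels: np.ndarray) -> Tensor:
    labels = np.asarray(labels, dtype=np.float64).reshape(preds.shape)
    mask = ~np.isnan(labels)
    if not mask.any():
        raise ValueError("all labels are missing")
    idx = np.nonzero(mask)
    diff = preds[idx] - Tensor(labels[idx])
    return (diff * diff).mean()


def classification_loss(probs, labels, task_mode: str = "classification") -> float:
    """Masked NLL (classification) or masked MSE (regression)."""
    t = probs if isinstance(probs, Tensor) else Tensor(np.asarray(probs))
    if task_mode == "classification":
        return float(_masked_nll_t(t, labels).data)
    if task_mode == "regression":
        return float(_masked_mse_t(t, labels).data)
    raise ValueError(f"unknown task_mode: {task_mode!r}")


class DualBranchModel(Module):
    """Parameter container and forward pass of the dual-branch network."""

    def __init__(self, rng: np.random.Generator, n_tasks: int = 1,
                 dims=DIMS, K: int = 3, init: str = "scaled",
                 epsilon_self: float = 0.0, learn_epsilon: bool = False,
                 task_mode: str = "classification"):
        super().__init__()
        if task_mode not in ("classification", "regression"):
            raise ValueError(f"unknown task_mode: {task_mode!r}")
        self.dims = tuple(dims)
        self.n_tasks = n_tasks
        self.task_mode = task_mode
        self.n_layers = len(dims) - 1
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            setattr(self, f"spec{i + 1}", ChebConv(d_in, d_out, rng, K=K, init=init))
            setattr(self, f"iso{i + 1}", GINLayer(
                d_in, d_out, rng, init=init,
                epsilon_self=epsilon_self, learn_epsilon=learn_epsilon,
            ))
        self.head = Linear(dims[-1], 256, rng, init=init)
        self.head_bn = BatchNorm1d(256)
        self.out = Linear(256, n_tasks, rng, init=init)

    # -- forward --------------------------------------------------------------
    def node_embeddings(self, x, lap_scaled, adjacency) -> Tensor:
        """Fused per-node features after the three dual layers."""
        lap = lap_scaled.matrix if isinstance(lap_scaled, ScaledLaplacian) else lap_scaled
        lap_t = lap if isinstance(lap, Tensor) else Tensor(lap)
        adj_t = adjacency if isinstance(adjacency, Tensor) else Tensor(adjacency)
        h = x if isinstance(x, Tensor) else Tensor(x)
        for i in range(self.n_layers):
            s = getattr(self, f"spec{i + 1}")(h, lap_t).relu()
            g = getattr(self, f"iso{i + 1}")(h, adj_t)
            h = fuse_layers(s, g)  # fused tensor feeds both next layers
        return h

    def graph_embedding(self, x, lap_scaled, adjacency) -> Tensor:
        return global_mean_pool(self.node_embeddings(x, lap_scaled, adjacency))

    def predict_from_embedding(self, emb: Tensor, return_logits: bool = False) -> Tensor:
        """Head on a (batch, 512) stack of graph embeddings."""
        h = self.head_bn(self.head(emb)).relu()
        logits = self.out(h)
        if return_logits or self.task_mode == "regression":
            return logits
        return logits.sigmoid()

    def forward_batch(self, prepared: list[tuple], return_logits: bool = False) -> Tensor:
        embs = [self.graph_embedding(x, lap, adj) for x, lap, adj in prepared]
        return self.predict_from_embedding(stack(embs), return_logits=return_logits)

    def spectral_embedding(self, graph: MolecularGraph, laplacian: str = "sym",
                           lambda_max="power") -> np.ndarray:
        """Pure spectral-branch embedding (the attack surface's backbone)."""
        lap = graph_scaled_laplacian(graph, laplacian, lambda_max)
        h = Tensor(graph.node_features)
        for i in range(self.n_layers):
            h = getattr(self, f"spec{i + 1}")(h, Tensor(lap.matrix)).relu()
        return h.data

    # -- weight transfer ------------------------------------------------------
    def load_backbone(self, encoder: ChebEncoder) -> None:
        """Copy pre-trained Chebyshev weights into the spectral branch."""
        mismatched = []
        for i in range(self.n_layers):
            src = getattr(encoder, f"conv{i + 1}")
            dst = getattr(self, f"spec{i + 1}")
            if src.theta.data.shape != dst.theta.data.shape:
                mismatched.append(
                    f"layer {i + 1}: {src.theta.data.shape} vs {dst.theta.data.shape}"
                )
        if mismatched:
            raise ValueError("backbone shape mismatch: " + "; ".join(mismatched))
        for i in range(self.n_layers):
            src = getattr(encoder, f"conv{i + 1}")
            dst = getattr(self, f"spec{i + 1}")
            dst.theta.data = src.theta.data.copy()
            dst.bias.data = src.bias.data.copy()


def count_parameters(model: Module) -> int:
    """Number of trainable scalars in the model."""
    return model.n_parameters()


class _BaseDualBranch(BaseEstimator):
    """Shared fit/predict machinery for the dual-branch estimators."""

    _task_mode = "classification"

    def __init__(self, n_tasks=None, epochs: int = 100, batch_size: int = 32,
                 learning_rate: float = 2e-4, beta1: float = 0.9,
                 beta2: float = 0.999, init: str = "scaled",
                 laplacian: str = "sym", lambda_max="power",
                 epsilon_self: float = 0.0, learn_epsilon: bool = False,
                 pretrained_backbone=None, validation_fraction: float = 0.1,
                 random_state: int | None = None):
        self.n_tasks = n_tasks
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.init = init
        self.laplacian = laplacian
        self.lambda_max = lambda_max
        self.epsilon_self = epsilon_self
        self.learn_epsilon = learn_epsilon
        self.pretrained_backbone = pretrained_backbone
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers --------------------------------------------------------------
    def _prepare(self, graphs: list[MolecularGraph]) -> list[tuple]:
        return [
            (g.node_features,
             graph_scaled_laplacian(g, self.laplacian, self.lambda_max).matrix,
             g.adjacency())
            for g in graphs
        ]

    def _labels(self, y, n: int) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if y.shape[0] != n:
            raise ValueError(f"y has {y.shape[0]} rows for {n} graphs")
        return y

    def _loss_t(self, outputs: Tensor, labels: np.ndarray) -> Tensor:
        """Training loss from logits (classification) or values (regression)."""
        if self._task_mode == "classification":
            return _masked_nll_logits_t(outputs, labels)
        return _masked_mse_t(outputs, labels)

    def _eval_loss(self, prepared, labels) -> float:
        self.model_.eval()
        out = self.model_.forward_batch(prepared, return_logits=True)
        val = float(self._loss_t(out, labels).data)
        self.model_.train()
        return val

    # -- API ------------------------------------------------------------------
    def fit(self, X, y):
        graphs = _as_graphs(X)
        labels = self._labels(y, len(graphs))
        k = labels.shape[1] if self.n_tasks is None else int(self.n_tasks)
        if labels.shape[1] != k:
            raise ValueError(f"n_tasks={k} but y has {labels.shape[1]} columns")
        rng = np.random.default_rng(self.random_state)
        self.model_ = DualBranchModel(
            rng, n_tasks=k, init=self.init, epsilon_self=self.epsilon_self,
            learn_epsilon=self.learn_epsilon, task_mode=self._task_mode,
        )
        self.n_tasks_ = k
        backbone = self.pretrained_backbone
        if backbone is not None:
            if isinstance(backbone, SpectralGraphAutoencoder):
                backbone = backbone.encoder_
            self.model_.load_backbone(backbone)
        prepared = self._prepare(graphs)

        # held-out split for epoch selection (best validation loss)
        n = len(prepared)
        n_val = int(round(self.validation_fraction * n))
        idx = rng.permutation(n)
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        if len(train_idx) == 0:
            raise ValueError("validation split leaves no training graphs")
        train_prep = [prepared[i] for i in train_idx]
        train_y = labels[train_idx]
        val_prep = [prepared[i] for i in val_idx]
        val_y = labels[val_idx]

        opt = Adam(self.model_.parameters(), lr=self.learning_rate,
                   beta1=self.beta1, beta2=self.beta2)
        self.loss_trace_ = []
        best = (np.inf, None)
        order = np.arange(len(train_prep))
        self.model_.train()
        for epoch in range(self.epochs):
            rng.shuffle(order)
            total, seen = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                out = self.model_.forward_batch(
                    [train_prep[i] for i in batch], return_logits=True
                )
                loss = self._loss_t(out, train_y[batch])
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                total += float(loss.data) * len(batch)
                seen += len(batch)
            record = {"epoch": epoch, "train_loss": total / seen}
            if len(val_prep):
                record["val_loss"] = self._eval_loss(val_prep, val_y)
                if record["val_loss"] < best[0]:
                    best = (record["val_loss"], self.model_.state_dict())
            self.loss_trace_.append(record)
        if best[1] is not None:
            self.model_.load_state_dict(best[1])
        self.model_.eval()
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def decision_values(self, X) -> np.ndarray:
        """Per-task outputs (probabilities or regression values), shape (n, k)."""
        self._check_fitted()
        graphs = X if (X and isinstance(X[0], tuple)) else self._prepare(_as_graphs(X))
        self.model_.eval()
        return self.model_.forward_batch(graphs).data

    def predict_proba(self, X) -> np.ndarray:
        return self.decision_values(X)

    def predict(self, X) -> np.ndarray:
        vals = self.decision_values(X)
        if self._task_mode == "classification":
            vals = (vals >= 0.5).astype(int)
        return vals[:, 0] if vals.shape[1] == 1 else vals


class DualBranchGraphClassifier(_BaseDualBranch):
    """Multi-task molecular graph classifier (sigmoid head, masked NLL).

    Accepts a list of :class:`MolecularGraph` (or SMILES strings) and an
    (n, k) label matrix with NaN marking missing task labels. ``score``
    returns the macro-averaged ROC-AUC across tasks.
    """

    _task_mode = "classification"

    def score(self, X, y) -> float:
        from .metrics import roc_auc

        return roc_auc(self._labels(y, len(X)), self.decision_values(X))


class DualBranchGraphRegressor(RegressorMixin, _BaseDualBranch):
    """Molecular graph regressor (identity head, masked MSE)."""

    _task_mode = "regression"

    def score(self, X, y) -> float:
        labels = self._labels(y, len(X))
        preds = self.decision_values(X)
        mask = ~np.isnan(labels)
        return r2_score(labels[mask], preds[mask])


def train_classifier(dataset, labels, pretrained_backbone=None,
                     config: dict | None = None):
    """Functional wrapper: fit a classifier, return (estimator, loss trace)."""
    est = DualBranchGraphClassifier(
        pretrained_backbone=pretrained_backbone, **(config or {})
    )
    est.fit(dataset, labels)
    return est, est.loss_trace_
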