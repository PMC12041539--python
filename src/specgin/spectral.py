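"""Spectral graph-convolution backbone.

The encoder stacks three Chebyshev spectral convolutions (56 -> 128 ->
256 -> 512, polynomial order K = 3), each followed by ReLU. Convolutions
operate on the rescaled Laplacian

    Lhat = 2 L / lambda_max - I,

where L is by default the symmetric-normalised Laplacian
I - D^{-1/2} A D^{-1/2} (the combinatorial D - A is available as an
option) and lambda_max is its largest eigenvalue, found by power
iteration (or fixed to a constant such as the L_sym upper bound 2).

The decoder is parameter-free: edge probabilities are sigmoid(z z^T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .graph import MolecularGraph
from .nn import ChebConv, Module

__all__ = [
    "ScaledLaplacian",
    "build_laplacian",
    "sym_normalized_laplacian",
    "largest_eigenvalue",
    "scale_laplacian",
    "graph_scaled_laplacian",
    "cheb_conv",
    "ChebEncoder",
    "decode",
]

ENCODER_DIMS = (56, 128, 256, 512)


@dataclass(frozen=True)
class ScaledLaplacian:
    """The rescaled Laplacian 2L/lambda_max - I together with lambda_max."""

    matrix: np.ndarray
    lambda_max: float


def _adjacency_of(graph) -> np.ndarray:
    if isinstance(graph, MolecularGraph):
        return graph.adjacency()
    a = np.asarray(graph, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return a


def build_laplacian(graph) -> np.ndarray:
    """Combinatorial Laplacian L = D - A; rows sum to zero."""
    a = _adjacency_of(graph)
    return np.diag(a.sum(axis=1)) - a


def sym_normalized_laplacian(graph) -> np.ndarray:
    """L_sym = I - D^{-1/2} A D^{-1/2}; degree-0 nodes get zero off-diagonals."""
    a = _adjacency_of(graph)
    deg = a.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return np.eye(len(a)) - (inv_sqrt[:, None] * a) * inv_sqrt[None, :]


def largest_eigenvalue(matrix: np.ndarray, tol: float = 1e-6,
                       max_iter: int = 200) -> float:
    """Largest eigenvalue of a symmetric PSD matrix by power iteration."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n == 1:
        return float(matrix[0, 0])
    # deterministic non-degenerate start vector
    v = np.cos(np.arange(n, dtype=np.float64)) + 1.5
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = matrix @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v_next = w / norm
        lam_next = float(v_next @ matrix @ v_next)
        if abs(lam_next - lam) < tol:
            return lam_next
        v, lam = v_next, lam_next
    return lam


def scale_laplacian(laplacian: np.ndarray, lambda_max: float) -> ScaledLaplacian:
    """Rescale a Laplacian to 2L/lambda_max - I."""
    if lambda_max <= 0:
        raise ValueError(f"lambda_max must be positive, got {lambda_max}")
    laplacian = np.asarray(laplacian, dtype=np.float64)
    return ScaledLaplacian(
        matrix=2.0 * laplacian / lambda_max - np.eye(laplacian.shape[0]),
        lambda_max=float(lambda_max),
    )


def graph_scaled_laplacian(graph, laplacian: str = "sym",
                           lambda_max: str | float = "power") -> ScaledLaplacian:
    """Build the rescaled Laplacian a graph is convolved with.

    ``laplacian`` selects ``"sym"`` (default) or ``"comb"``; ``lambda_max``
    is ``"power"`` (power iteration per graph) or a fixed positive float
    (e.g. 2.0, the exact upper bound for L_sym).
    """
    if laplacian == "sym":
        lap = sym_normalized_laplacian(graph)
    elif laplacian == "comb":
        lap = build_laplacian(graph)
    else:
        raise ValueError(f"unknown laplacian kind: {laplacian!r}")
    if lambda_max == "power":
        lam = largest_eigenvalue(lap)
        if lam <= 0:  # edgeless graph: L is the zero (or identity-free) matrix
            lam = 2.0
    else:
        lam = float(lambda_max)
    return scale_laplacian(lap, lam)


def cheb_conv(x: np.ndarray, lap_scaled: ScaledLaplacian,
              theta: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Chebyshev convolution on plain arrays (K taken from theta's shape)."""
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim != 3:
        raise ValueError("theta must be (K, in_dim, out_dim)")
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] != theta.shape[1]:
        raise ValueError(
            f"feature dim {x.shape[1]} does not match theta in_dim {theta.shape[1]}"
        )
    lap = lap_scaled.matrix if isinstance(lap_scaled, ScaledLaplacian) else lap_scaled
    z_prev, z = None, x
    out = z @ theta[0]
    for k in range(1, theta.shape[0]):
        z_next = lap @ z if z_prev is None else 2.0 * (lap @ z) - z_prev
        z_prev, z = z, z_next
        out = out + z @ theta[k]
    if bias is not None:
        out = out + bias
    return out


class ChebEncoder(Module):
    """Three-layer Chebyshev encoder mapping 56-d atoms to 512-d embeddings."""

    def __init__(self, rng: np.random.Generator, dims=ENCODER_DIMS, K: int = 3,
                 init: str = "scaled"):
        super().__init__()
        self.dims = tuple(dims)
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            setattr(self, f"conv{i + 1}", ChebConv(d_in, d_out, rng, K=K, init=init))
        self.n_layers = len(dims) - 1

    def forward(self, x, lap_scaled) -> Tensor:
        lap = lap_scaled.matrix if isinstance(lap_scaled, ScaledLaplacian) else lap_scaled
        lap_t = lap if isinstance(lap, Tensor) else Tensor(lap)
        h = x if isinstance(x, Tensor) else Tensor(x)
        for i in range(self.n_layers):
            h = getattr(self, f"conv{i + 1}")(h, lap_t).relu()
        return h

    __call__ = forward

    def encode(self, graph: MolecularGraph, laplacian: str = "sym",
               lambda_max: str | float = "power") -> np.ndarray:
        """Embed a molecular graph; returns the (n, 512) array."""
        lap = graph_scaled_laplacian(graph, laplacian, lambda_max)
        return self.forward(Tensor(graph.node_features), lap).data


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(z) -> np.ndarray | Tensor:
    """Inner-product decoder: sigmoid(z z^T), a symmetric matrix in (0, 1)."""
    if isinstance(z, Tensor):
        return (z @ z.T).sigmoid()
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("embedding must be finite")
    p = _sigmoid(z @ z.T)
    # keep the open-interval contract where float64 would round to 0 or 1
    tiny = np.finfo(np.float64).eps
    return np.clip(p, tiny, 1.0 - tiny)
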