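"""Neural-network building blocks on top of the autodiff engine.

Weight initialisation offers two schemes:

``scaled``
    variance-scaled normal, std = sqrt(2 / fan_in) (He), the default —
    keeps activations bounded through the 56 -> 128 -> 256 -> 512 stack.
``normal``
    standard normal N(0, 1) with zero biases.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Parameter", "Linear", "BatchNorm1d", "ChebConv"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with named parameters, submodules and a train/eval switch."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- checkpoint plumbing --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise ValueError(f"checkpoint is missing entries: {sorted(missing)}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: model {p.data.shape} "
                    f"vs checkpoint {state[name].shape}"
                )
            p.data = state[name].astype(np.float64).copy()
        for name, _ in buffers.items():
            self._set_buffer(name, state[name].astype(np.float64).copy())

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (f"{prefix}{name}", getattr(self, name))
        for name, mod in self._modules.items():
            yield from mod.named_buffers(prefix=f"{prefix}{name}.")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj._modules[part]
        object.__setattr__(obj, parts[-1], value)


def _init_weight(rng: np.random.Generator, shape, fan_in: int, scheme: str) -> np.ndarray:
    if scheme == "normal":
        return rng.standard_normal(shape)
    if scheme == "scaled":
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    raise ValueError(f"unknown init scheme: {scheme!r}")


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 init: str = "scaled"):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.weight = Parameter(_init_weight(rng, (in_dim, out_dim), in_dim, init))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"Linear expected last dim {self.in_dim}, got {x.shape[-1]}"
            )
        return x @ self.weight + self.bias

    __call__ = forward


class BatchNorm1d(Module):
    """Batch normalisation over axis 0.

    With ``track_running_stats=True`` (head usage) evaluation uses running
    averages. With ``track_running_stats=False`` the layer always
    normalises over the current axis-0 population — used inside the
    isomorphic branch, where the population is one graph's node set, so a
    graph's output never depends on what it was batched with.
    """

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1,
                 track_running_stats: bool = True):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.momentum = momentum
        self.track_running_stats = track_running_stats
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        if track_running_stats:
            object.__setattr__(self, "running_mean", np.zeros(dim))
            object.__setattr__(self, "running_var", np.ones(dim))
            object.__setattr__(self, "_buffer_names", ("running_mean", "running_var"))

    def forward(self, x: Tensor) -> Tensor:
        if self.training or not self.track_running_stats:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            xhat = centred / (var + self.eps).sqrt()
            if self.training and self.track_running_stats:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
                self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    __call__ = forward


class ChebConv(Module):
    """Chebyshev spectral graph convolution of polynomial order K.

    The filter is X' = sum_{k=1..K} Z^k Theta^k + bias with the recursion
    Z^1 = X, Z^2 = Lhat X, Z^k = 2 Lhat Z^{k-1} - Z^{k-2} on the rescaled
    Laplacian Lhat.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 K: int = 3, init: str = "scaled", bias: bool = True):
        super().__init__()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.K = K
        # one weight matrix per polynomial order; fan_in counts all K taps
        self.theta = Parameter(
            _init_weight(rng, (K, in_dim, out_dim), K * in_dim, init)
        )
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor, lap_scaled) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"ChebConv expected {self.in_dim} input features, got {x.shape[-1]}"
            )
        lap = lap_scaled if isinstance(lap_scaled, Tensor) else Tensor(lap_scaled)
        if lap.shape[0] != lap.shape[1] or lap.shape[0] != x.shape[0]:
            raise ValueError("scaled Laplacian shape does not match node count")
        z_prev, z = None, x
        out = z @ self.theta[0]
        for k in range(1, self.K):
            z_next = lap @ z if z_prev is None else 2.0 * (lap @ z) - z_prev
            z_prev, z = z, z_next
            out = out + z @ self.theta[k]
        if self.bias is not None:
            out = out + self.bias
        return out

    __call__ = forward
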