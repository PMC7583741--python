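"""Minimal dense neural networks with explicit backprop and Adam.

The policy and Q-functions here are small multilayer perceptrons over
flattened board observations; at this scale (hundreds of inputs and
outputs) explicit numpy forward/backward passes are fast and make every
gradient step exactly reproducible from a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully-connected net, ReLU hidden layers, linear output head."""

    def __init__(
        self,
        in_dim: int,
        hidden: Sequence[int],
        out_dim: int,
        rng: np.random.Generator,
        skip: bool = False,
    ):
        dims = [in_dim, *hidden, out_dim]
        # He initialization for the ReLU layers; small final layer so the
        # initial policy is near uniform and initial Q-values are near 0.
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for i in range(len(dims) - 1):
            scale = np.sqrt(2.0 / dims[i])
            if i == len(dims) - 2:
                scale = 1e-2 / np.sqrt(dims[i])
            self.W.append(rng.normal(0.0, scale, size=(dims[i], dims[i + 1])))
            self.b.append(np.zeros(dims[i + 1]))
        # optional linear shortcut from input to output: on board inputs it
        # lets a head express per-cell effects (e.g. "this cell is already
        # occupied") without routing them through the hidden layers
        self.S: np.ndarray | None = (
            np.zeros((in_dim, out_dim)) if skip else None
        )
        self.dims = dims

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """x: (batch, in_dim) -> (batch, out_dim). Pass a list to keep
        activations for a subsequent :meth:`backward`."""
        a = x
        if cache is not None:
            cache.append(a)
        n = len(self.W)
        for i in range(n):
            z = a @ self.W[i] + self.b[i]
            a = np.maximum(z, 0.0) if i < n - 1 else z
            if cache is not None:
                cache.append(a)
        if self.S is not None:
            a = a + x @ self.S
        return a

    def backward(self, cache: list, dout: np.ndarray) -> list[np.ndarray]:
        """Gradient of a scalar loss wrt parameters, given d(loss)/d(output).

        Returns grads ordered [dW0, db0, dW1, db1, ...].
        """
        grads: list[np.ndarray] = []
        delta = dout
        for i in reversed(range(len(self.W))):
            a_in = cache[i]
            if i < len(self.W) - 1:
                delta = delta * (cache[i + 1] > 0)  # ReLU gate
            grads.append(delta.sum(axis=0))  # db
            grads.append(a_in.T @ delta)  # dW
            if i > 0:
                delta = delta @ self.W[i].T
        grads.reverse()
        if self.S is not None:
            grads.append(cache[0].T @ dout)  # dS
        return grads

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.W, self.b):
            out.extend([w, b])
        if self.S is not None:
            out.append(self.S)
        return out

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        for i in range(len(self.W)):
            self.W[i] = params[2 * i].copy()
            self.b[i] = params[2 * i + 1].copy()
        if self.S is not None:
            self.S = params[-1].copy()

    def copy(self) -> "MLP":
        clone = object.__new__(MLP)
        clone.dims = list(self.dims)
        clone.W = [w.copy() for w in self.W]
        clone.b = [b.copy() for b in self.b]
        clone.S = None if self.S is None else self.S.copy()
        return clone

    def polyak_toward(self, local: "MLP", tau: float) -> None:
        """theta_bar <- tau * theta_bar + (1 - tau) * theta, in place."""
        mine = self.parameters()
        theirs = local.parameters()
        for p, q in zip(mine, theirs):
            p *= tau
            p += (1.0 - tau) * q


class Adam:
    """Adam optimizer over a fixed list of parameter arrays."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = 3e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        # p -= lr * m_hat / (sqrt(v_hat) + eps) with bias corrections folded
        # into scalars to avoid per-array temporaries
        step_size = self.lr * np.sqrt(bc2) / bc1
        eps = self.eps * np.sqrt(bc2)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            denom = np.sqrt(v)
            denom += eps
            update = m / denom
            update *= step_size
            p -= update

    def state(self) -> dict:
        return {
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
            "t": self.t,
        }

    def load_state(self, state: dict) -> None:
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
        self.t = state["t"]
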