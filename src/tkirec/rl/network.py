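"""Minimal dense Q-network and Adam optimizer on numpy.

The network is a fully connected multi-layer perceptron (default two hidden
layers of 64 ReLU units, four linear outputs — one Q-value per action).
Gradients are computed for the squared temporal-difference error on the
actions actually taken in the batch; everything draws from a caller-supplied
seeded generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np


class QNetwork:
    def __init__(self, dims: tuple[int, ...], rng: np.random.Generator):
        """``dims`` = (input, hidden..., output); He-initialized weights."""
        self.dims = tuple(int(d) for d in dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.dims[:-1], self.dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Q-values for a batch of states (n, input_dim) -> (n, output_dim)."""
        h = np.atleast_2d(np.asarray(x, dtype=float))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def _forward_cached(self, x: np.ndarray):
        activations = [np.atleast_2d(np.asarray(x, dtype=float))]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            activations.append(np.maximum(activations[-1] @ w + b, 0.0))
        out = activations[-1] @ self.weights[-1] + self.biases[-1]
        return out, activations

    def gradients(
        self, x: np.ndarray, actions: np.ndarray, targets: np.ndarray
    ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        """Mean squared TD error on the taken actions, and its gradients."""
        q, activations = self._forward_cached(x)
        n = len(q)
        taken = q[np.arange(n), actions]
        err = taken - targets
        loss = float(np.mean(err**2))

        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = 2.0 * err / n

        grad_w = [np.empty_like(w) for w in self.weights]
        grad_b = [np.empty_like(b) for b in self.biases]
        delta = dq
        for layer in range(len(self.weights) - 1, -1, -1):
            grad_w[layer] = activations[layer].T @ delta
            grad_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
        return loss, grad_w, grad_b

    def copy_from(self, other: "QNetwork") -> None:
        for mine, theirs in zip(self.weights, other.weights):
            mine[...] = theirs
        for mine, theirs in zip(self.biases, other.biases):
            mine[...] = theirs

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "QNetwork":
        net = cls.__new__(cls)
        net.dims = tuple(payload["dims"])
        net.weights = [np.asarray(w, dtype=float) for w in payload["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in payload["biases"]]
        return net


class Adam:
    """Standard Adam updates over a QNetwork's parameter list."""

    def __init__(self, net: QNetwork, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        params = net.weights + net.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, net: QNetwork, grad_w: list[np.ndarray], grad_b: list[np.ndarray]) -> None:
        self.t += 1
        params = net.weights + net.biases
        grads = grad_w + grad_b
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g**2
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
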