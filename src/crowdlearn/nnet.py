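"""Minimal fully-connected softmax classifier with Adam, in NumPy.

The backbone used throughout the package: an MLP with ReLU hidden layers and
a softmax output, trained full-batch (or mini-batch) by cross-entropy with
analytic gradients. Default architecture is two hidden layers of 512 and 256
units. Weights and biases use symmetric uniform fan-in initialisation
U(-1/sqrt(fan_in), +1/sqrt(fan_in)), drawn from a seeded generator so runs
are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkConfig", "MLP", "AdamState"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the classifier: ReLU MLP with softmax output."""

    input_dim: int
    class_count: int
    hidden_sizes: tuple[int, ...] = (512, 256)

    def __post_init__(self) -> None:
        if self.class_count < 2:
            raise ValueError("class_count must be >= 2")
        if len(self.hidden_sizes) < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("at least one positive hidden layer size required")
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_sizes, self.class_count]
        return list(zip(dims[:-1], dims[1:]))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """ReLU multilayer perceptron with a softmax head."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in config.layer_dims:
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    def forward(self, X: np.ndarray, cache: bool = False):
        """Predicted class probabilities for a batch; optionally keep
        pre-activation caches for backprop."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} != expected {self.config.input_dim}"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite input")
        activations = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            activations.append(h)
        probs = softmax(h @ self.weights[-1] + self.biases[-1])
        if cache:
            return probs, activations
        return probs

    def backward(
        self, activations: list[np.ndarray], dlogits: np.ndarray
    ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of the loss w.r.t. every (W, b), given the gradient at
        the output logits and the forward activation cache."""
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        delta = dlogits
        for i in range(len(self.weights) - 1, -1, -1):
            grads.append((activations[i].T @ delta, delta.sum(axis=0)))
            if i > 0:
                delta = (delta @ self.weights[i].T) * (activations[i] > 0)
        grads.reverse()
        return grads

    def get_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for i in range(len(self.weights)):
            self.weights[i] = np.asarray(params[f"W{i}"], dtype=float)
            self.biases[i] = np.asarray(params[f"b{i}"], dtype=float)


@dataclass
class AdamState:
    """Adam optimiser state over an MLP's parameter list."""

    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: list = field(default_factory=list)
    v: list = field(default_factory=list)

    def step(self, model: MLP, grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        flat = [g for pair in grads for g in pair]
        params = [p for pair in zip(model.weights, model.biases) for p in pair]
        if not self.m:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        lr_t = self.learning_rate * (
            np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        )
        for i, (p, g) in enumerate(zip(params, flat)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)
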