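"""Minimal feed-forward networks with manual backpropagation.

Desk-scale actor/critic networks (two hidden tanh layers by default) do not
need an autograd framework; implementing the forward/backward pass directly
keeps the package dependency-light and gives the relevance-propagation code
exact access to per-layer activations and weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(a.dtype)),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class MLP:
    """Fully connected network: linear layers with a hidden nonlinearity.

    The output layer is always linear (logits / raw value). ``sizes`` lists
    the layer widths including input and output, e.g. ``(10, 64, 64, 5)``.
    """

    sizes: tuple
    activation: str = "tanh"
    seed: int = 0
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    def __post_init__(self):
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unsupported activation {self.activation!r}")
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
                self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray):
        """Return (output, activations) where activations[0] is the input and
        activations[i] the post-nonlinearity output of hidden layer i."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        act, _ = _ACTIVATIONS[self.activation]
        activations = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = z if i == self.n_layers - 1 else act(z)
            activations.append(h)
        return h, activations

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, activations, grad_out):
        """Backpropagate d(loss)/d(output) through the cached activations.

        Returns (weight_grads, bias_grads) matching self.weights/biases.
        """
        _, dact = _ACTIVATIONS[self.activation]
        w_grads = [None] * self.n_layers
        b_grads = [None] * self.n_layers
        delta = np.asarray(grad_out, dtype=float)
        for i in range(self.n_layers - 1, -1, -1):
            a_prev = activations[i]
            w_grads[i] = a_prev.T @ delta
            b_grads[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * dact(activations[i])
        return w_grads, b_grads

    # -- serialization: architecture + flat parameter array (JSON) --

    def to_json(self) -> str:
        flat = np.concatenate([w.ravel() for w in self.weights]
                              + [b.ravel() for b in self.biases])
        return json.dumps({
            "sizes": list(self.sizes),
            "activation": self.activation,
            "params": flat.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "MLP":
        spec = json.loads(text)
        net = cls(sizes=tuple(spec["sizes"]), activation=spec["activation"])
        flat = np.asarray(spec["params"], dtype=float)
        pos = 0
        for i, w in enumerate(net.weights):
            net.weights[i] = flat[pos:pos + w.size].reshape(w.shape)
            pos += w.size
        for i, b in enumerate(net.biases):
            net.biases[i] = flat[pos:pos + b.size].reshape(b.shape)
            pos += b.size
        if pos != flat.size:
            raise ValueError("parameter array length does not match architecture")
        return net


class SGDMomentum:
    """Classical momentum optimizer for an MLP's parameters."""

    def __init__(self, net: MLP, lr: float, momentum: float = 0.9):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self._vw = [np.zeros_like(w) for w in net.weights]
        self._vb = [np.zeros_like(b) for b in net.biases]

    def step(self, w_grads, b_grads):
        for i in range(self.net.n_layers):
            self._vw[i] = self.momentum * self._vw[i] - self.lr * w_grads[i]
            self._vb[i] = self.momentum * self._vb[i] - self.lr * b_grads[i]
            self.net.weights[i] += self._vw[i]
            self.net.biases[i] += self._vb[i]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
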