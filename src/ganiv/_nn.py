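"""Small fully-connected networks and an Adam optimizer on the autodiff core."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, affine, concat_cols, elu, relu, sigmoid, tanh

_ACTIVATIONS = {
    "tanh": tanh,
    "elu": elu,
    "relu": relu,
    "sigmoid": sigmoid,
    "linear": lambda x: x,
}


class MLP:
    """Feed-forward network with a fixed activation in every hidden layer."""

    def __init__(self, in_dim, hidden, out_dim, activation, out_activation, rng):
        self.activation = activation
        self.out_activation = out_activation
        dims = [in_dim, *hidden, out_dim]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for a, b in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (a + b))
            w = rng.uniform(-limit, limit, size=(a, b))
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros((1, b)), requires_grad=True))

    @property
    def params(self):
        return [*self.weights, *self.biases]

    def __call__(self, x: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.activation]
        out_act = _ACTIVATIONS[self.out_activation]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = affine(h, w, b)
            h = out_act(h) if i == last else act(h)
        return h

    # plain-numpy forward pass for fast inference (sampling)
    def forward_numpy(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=np.float64)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w.data + b.data
            name = self.out_activation if i == last else self.activation
            if name == "tanh":
                h = np.tanh(h)
            elif name == "elu":
                h = np.where(h > 0, h, np.exp(np.minimum(h, 0.0)) - 1.0)
            elif name == "relu":
                h = np.maximum(h, 0.0)
            elif name == "sigmoid":
                h = 1.0 / (1.0 + np.exp(-h))
        return h

    def state(self):
        return {
            "weights": [w.data.tolist() for w in self.weights],
            "biases": [b.data.tolist() for b in self.biases],
            "activation": self.activation,
            "out_activation": self.out_activation,
        }

    @classmethod
    def from_state(cls, state):
        obj = cls.__new__(cls)
        obj.activation = state["activation"]
        obj.out_activation = state["out_activation"]
        obj.weights = [
            Tensor(np.asarray(w), requires_grad=True) for w in state["weights"]
        ]
        obj.biases = [
            Tensor(np.asarray(b), requires_grad=True) for b in state["biases"]
        ]
        return obj


class Adam:
    def __init__(self, params, lr=1e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stack_inputs(*arrays) -> Tensor:
    """Column-concatenate constant numpy arrays into one input tensor."""
    return concat_cols([Tensor(np.atleast_2d(a)) for a in arrays])
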