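"""Minimal feedforward neural nets with manual backprop and Adam.

This provides just enough machinery for desk-scale mean-teacher experiments:
dense and valid-padding strided convolution layers over NHWC float arrays,
ReLU, global average pooling, softmax cross-entropy and probability-space
mean-squared-error losses with analytic gradients, and an Adam optimiser with
optional per-epoch exponential learning-rate decay.  Parameters live in plain
numpy arrays so teacher networks can be maintained as exponential moving
averages of student parameters with ordinary array arithmetic.

Backbones are constructed from a :class:`BackboneSpec`; the registry ships a
dense net ("mlp") and a two-convolution net ("tiny_cnn"), both sized so a
full training run takes CPU seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init for ReLU nets
        w = rng.normal(0.0, scale, size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.params[0].T


class Conv2D(Layer):
    """Valid-padding strided convolution on NHWC arrays."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, c_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel, self.stride = kernel, stride

    def forward(self, x):
        k, s = self.kernel, self.stride
        n, h, w_in, _ = x.shape
        oh, ow = (h - k) // s + 1, (w_in - k) // s + 1
        self._x = x
        self._oshape = (n, oh, ow)
        out = np.broadcast_to(self.params[1], (n, oh, ow, self.params[1].size)).copy()
        for ki in range(k):
            for kj in range(k):
                sl = x[:, ki:ki + oh * s:s, kj:kj + ow * s:s, :]
                out += sl @ self.params[0][ki, kj]
        return out

    def backward(self, g):
        k, s = self.kernel, self.stride
        x = self._x
        n, oh, ow = self._oshape
        dx = np.zeros_like(x)
        self.grads[1][...] = g.sum(axis=(0, 1, 2))
        for ki in range(k):
            for kj in range(k):
                sl = x[:, ki:ki + oh * s:s, kj:kj + ow * s:s, :]
                self.grads[0][ki, kj][...] = np.tensordot(
                    sl, g, axes=([0, 1, 2], [0, 1, 2]))
                dx[:, ki:ki + oh * s:s, kj:kj + ow * s:s, :] += (
                    g @ self.params[0][ki, kj].T)
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._shape).copy()


class Network:
    """A sequential stack with explicit parameter access for EMA teachers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def weight_matrices(self) -> list[np.ndarray]:
        """Weight arrays subject to L2 decay (biases excluded)."""
        return [layer.params[0] for layer in self.layers if layer.params]

    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_params(self, values: list[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(values):
            raise ValueError("parameter count mismatch")
        for p, v in zip(own, values):
            if p.shape != v.shape:
                raise ValueError(f"parameter shape mismatch {p.shape} vs {v.shape}")
            p[...] = v

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x))


@dataclass
class BackboneSpec:
    """Architecture recipe injected into the trainers.

    input_size is the square working resolution the preprocessing pipeline
    resizes patches to before they reach the network.
    """

    name: str = "mlp"
    input_size: int = 16
    hidden: int = 48
    channels: tuple[int, ...] = (8, 16)
    extra: dict = field(default_factory=dict)


def build_backbone(spec: BackboneSpec, n_classes: int,
                   rng: np.random.Generator) -> Network:
    if spec.name == "mlp":
        d = spec.input_size * spec.input_size * 3
        return Network([Flatten(),
                        Dense(d, spec.hidden, rng), ReLU(),
                        Dense(spec.hidden, n_classes, rng)])
    if spec.name == "tiny_cnn":
        c1, c2 = spec.channels
        return Network([Conv2D(3, c1, 3, 2, rng), ReLU(),
                        Conv2D(c1, c2, 3, 2, rng), ReLU(),
                        GlobalAvgPool(),
                        Dense(c2, n_classes, rng)])
    if spec.name == "logistic":
        d = spec.input_size * spec.input_size * 3
        return Network([Flatten(), Dense(d, n_classes, rng)])
    raise KeyError(f"unknown backbone {spec.name!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  ) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def mse_probs(student_logits: np.ndarray, teacher_probs: np.ndarray,
              ) -> tuple[float, np.ndarray]:
    """Probability-space MSE against fixed teacher targets.

    Averages over samples AND classes; the gradient flows through the
    student softmax only (teacher probabilities are constants).
    """
    if student_logits.shape != teacher_probs.shape:
        raise ValueError("student and teacher output shapes differ")
    n, c = student_logits.shape
    p = softmax(student_logits)
    diff = p - teacher_probs
    loss = float((diff ** 2).mean())
    dp = 2.0 * diff / (n * c)
    # softmax Jacobian-vector product
    grad = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, grad


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
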