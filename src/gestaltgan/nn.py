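"""Compact fully-connected network stack with explicit backpropagation.

All trainable components of the toolkit (phenotype classifier, mapping
network, generator, discriminator, face-confidence scorer) are built from
this module: dense layers with elementwise activations, softmax
cross-entropy, and Adam.  Forward passes return a cache that the matching
backward pass consumes, yielding both parameter gradients and the gradient
with respect to the input — the latter is what lets a frozen judge network
steer a generator.  Everything is deterministic given the initialization
seed; parameters live in flat ``{name: array}`` dicts that serialize to a
single ``.npz`` checkpoint with a versioned JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

CHECKPOINT_VERSION = 1

# ---------------------------------------------------------------------------
# activations


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "lrelu":
        return np.where(z > 0, z, 0.2 * z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(name: str, z: np.ndarray, a: np.ndarray, da: np.ndarray) -> np.ndarray:
    if name == "linear":
        return da
    if name == "lrelu":
        return da * np.where(z > 0, 1.0, 0.2)
    if name == "sigmoid":
        return da * a * (1.0 - a)
    if name == "tanh":
        return da * (1.0 - a * a)
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Dense multi-layer perceptron with named parameters.

    ``sizes`` gives the layer widths including input and output; hidden
    layers use ``activation``, the last layer uses ``out_activation``.
    """

    def __init__(self, sizes, activation="lrelu", out_activation="linear",
                 seed: int = 0, name: str = "mlp"):
        self.sizes = tuple(int(s) for s in sizes)
        self.activation = activation
        self.out_activation = out_activation
        self.name = name
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            scale = np.sqrt(2.0 / fan_in)  # He init, matches leaky-ReLU hidden units
            self.params[f"{name}.W{i}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
            self.params[f"{name}.b{i}"] = np.zeros(fan_out)

    @property
    def n_layers(self) -> int:
        return len(self.sizes) - 1

    def _acts(self):
        return [self.activation] * (self.n_layers - 1) + [self.out_activation]

    def forward(self, x: np.ndarray, params: dict | None = None):
        """Return (output, cache).  x is (batch, sizes[0])."""
        p = self.params if params is None else params
        a = np.asarray(x, dtype=float)
        cache = []
        for i, act in enumerate(self._acts()):
            z = a @ p[f"{self.name}.W{i}"] + p[f"{self.name}.b{i}"]
            out = _act_forward(act, z)
            cache.append((a, z, out))
            a = out
        return a, cache

    def backward(self, cache, dout: np.ndarray, params: dict | None = None):
        """Return (dinput, grads) for the upstream gradient ``dout``."""
        p = self.params if params is None else params
        grads: dict[str, np.ndarray] = {}
        da = np.asarray(dout, dtype=float)
        for i in reversed(range(self.n_layers)):
            a_in, z, a_out = cache[i]
            act = self._acts()[i]
            dz = _act_backward(act, z, a_out, da)
            grads[f"{self.name}.W{i}"] = a_in.T @ dz
            grads[f"{self.name}.b{i}"] = dz.sum(axis=0)
            da = dz @ p[f"{self.name}.W{i}"].T
        return da, grads

    def __call__(self, x, params=None):
        return self.forward(x, params)[0]


# ---------------------------------------------------------------------------
# losses


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    idx = (np.arange(n), np.asarray(labels, dtype=int))
    loss = float(-np.mean(np.log(np.maximum(p[idx], 1e-300))))
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    return loss, dlogits / n


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def binary_cross_entropy_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean BCE on logits and its gradient."""
    loss = float(np.mean(softplus(logits) - targets * logits))
    dlogits = (sigmoid(logits) - targets) / logits.size
    return loss, dlogits


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (np.sqrt(self.v[k] / corr2) + self.eps)


def merge_grads(*grad_dicts) -> dict:
    """Sum gradient dicts key-wise (missing keys treated as zero)."""
    out: dict[str, np.ndarray] = {}
    for g in grad_dicts:
        for k, v in g.items():
            out[k] = out[k] + v if k in out else v.copy()
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_params(path, params: dict, meta: dict) -> None:
    """Single-file checkpoint: arrays plus a versioned JSON header."""
    header = {"version": CHECKPOINT_VERSION, **meta}
    arrays = {k.replace("/", "_"): v for k, v in params.items()}
    np.savez(Path(path), __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_params(path) -> tuple[dict, dict]:
    with np.load(Path(path)) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        params = {k: data[k].copy() for k in data.files if k != "__header__"}
    return params, header
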