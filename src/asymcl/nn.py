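"""Minimal dense/convolutional building blocks with explicit backprop.

The training pipeline needs only small encoders (a tiny MLP for feature
vectors, a tiny CNN for small images), a two-layer projection head and a
one-layer classifier, so the layers here implement exactly the forward and
backward passes those require.  Parameters live in plain dicts of numpy
arrays, which makes freezing, hashing and snapshotting trivial.

Conventions: inputs are (n, ...) batches; ``forward`` caches what
``backward`` needs; ``backward(dout)`` fills ``self.grads`` (same keys as
``self.params``) and returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Sequential",
    "Flatten",
    "Conv3x3",
    "MeanPool2",
    "build_mlp_encoder",
    "build_cnn_encoder",
    "build_projection_head",
    "Adam",
    "parameter_hash",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map y = x W + b with He-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        # small random bias keeps post-ReLU projections off the exact origin
        self.params = {
            "W": rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in),
            "b": rng.standard_normal(n_out) * 0.01,
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Conv3x3(Layer):
    """Valid 3x3 convolution, single input channel -> ``n_filters`` maps."""

    def __init__(self, n_filters: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "K": rng.standard_normal((n_filters, 3, 3)) * np.sqrt(2.0 / 9.0),
            "b": np.zeros(n_filters),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (n, H, W) -> (n, F, H-2, W-2)
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
        self._win = win
        out = np.einsum("nijkl,fkl->nfij", win, self.params["K"])
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        K = self.params["K"]
        self.grads = {
            "K": np.einsum("nfij,nijkl->fkl", dout, self._win),
            "b": dout.sum(axis=(0, 2, 3)),
        }
        n, _, Ho, Wo = dout.shape
        dx = np.zeros((n, Ho + 2, Wo + 2))
        for di in range(3):
            for dj in range(3):
                dx[:, di : di + Ho, dj : dj + Wo] += np.einsum(
                    "nfij,f->nij", dout, K[:, di, dj]
                )
        return dx


class MeanPool2(Layer):
    """2x2 average pooling (truncates odd trailing rows/columns)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, f, H, W = x.shape
        self._in_shape = x.shape
        Hc, Wc = (H // 2) * 2, (W // 2) * 2
        v = x[:, :, :Hc, :Wc].reshape(n, f, Hc // 2, 2, Wc // 2, 2)
        return v.mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, H, W = self._in_shape
        dx = np.zeros(self._in_shape)
        up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class Sequential(Layer):
    """Chain of layers; parameters are exposed under ``<idx>.<name>`` keys."""

    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def params(self) -> dict:
        return {
            f"{i}.{k}": v
            for i, lay in enumerate(self.layers)
            for k, v in lay.params.items()
        }

    @params.setter
    def params(self, value: dict) -> None:
        if value:
            for key, arr in value.items():
                i, k = key.split(".", 1)
                self.layers[int(i)].params[k] = arr

    @property
    def grads(self) -> dict:
        return {
            f"{i}.{k}": v
            for i, lay in enumerate(self.layers)
            for k, v in lay.grads.items()
        }

    @grads.setter
    def grads(self, value: dict) -> None:
        pass  # populated by the child layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def build_mlp_encoder(
    n_in: int, hidden: tuple[int, ...], feature_dim: int, rng: np.random.Generator
) -> Sequential:
    """Tiny MLP: dense-ReLU blocks ending in a linear feature layer."""
    sizes = (n_in, *hidden)
    layers: list[Layer] = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        layers += [Dense(a, b, rng), ReLU()]
    layers.append(Dense(sizes[-1], feature_dim, rng))
    return Sequential(layers)


def build_cnn_encoder(
    image_hw: tuple[int, int],
    n_filters: int,
    feature_dim: int,
    rng: np.random.Generator,
) -> Sequential:
    """Tiny CNN: conv3x3 -> ReLU -> mean-pool -> flatten -> linear features."""
    H, W = image_hw
    flat = n_filters * ((H - 2) // 2) * ((W - 2) // 2)
    return Sequential(
        [Conv3x3(n_filters, rng), ReLU(), MeanPool2(), Flatten(), Dense(flat, feature_dim, rng)]
    )


def build_projection_head(
    feature_dim: int, hidden: int, out: int, rng: np.random.Generator
) -> Sequential:
    """Two-layer projection head (hidden, out); output is normalized by the caller."""
    return Sequential([Dense(feature_dim, hidden, rng), ReLU(), Dense(hidden, out, rng)])


class Adam:
    """Adam over a dict of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: dict,
        lr: float = 1e-2,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def parameter_hash(params: dict) -> str:
    """SHA-256 over parameter bytes; bit-identical params give equal hashes."""
    h = hashlib.sha256()
    for k in sorted(params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(params[k]).tobytes())
    return h.hexdigest()
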