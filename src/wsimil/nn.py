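"""A compact NumPy CNN engine for small-image binary classification.

Implements exactly the pieces the per-patch classifiers need — 2D "same"
convolution with an optional L1 kernel penalty, ELU, batch normalization,
2x2 max pooling, dropout, global max pooling, dense layers, a
sigmoid/binary-cross-entropy head and the Adam optimizer — with explicit
forward/backward passes.  Tensors are NHWC; convolutions are evaluated as
``kernel**2`` batched GEMMs over shifted views, which is fast enough for
the 24-128 px inputs this package trains on, and the hand-written backward
pass is what makes Grad-CAM (gradients at an intermediate activation map)
a one-liner in :mod:`wsimil.classifier`.

All randomness (weight init, dropout, shuffling) flows through
``numpy.random.Generator`` instances supplied by the caller, so training
is bit-reproducible under a fixed seed on one platform.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross entropy, computed from logits for stability."""
    z = z.astype(np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    # softplus(z) - z*y  ==  -[y log p + (1-y) log(1-p)]
    softplus = np.logaddexp(0.0, z)
    return float(np.mean(softplus - z * y))


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padded convolution, stride 1, NHWC."""

    def __init__(self, in_ch, out_ch, kernel=3, l1=0.0, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.l1 = float(l1)
        self.params["W"] = rng.normal(0.0, scale, (kernel, kernel, in_ch, out_ch)).astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x, training):
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        n, h, w, _ = x.shape
        W = self.params["W"]
        out = np.zeros((n, h, w, W.shape[3]), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ W[i, j]
        out += self.params["b"]
        self._xp, self._hw = xp, (h, w)
        return out

    def backward(self, g):
        k = self.kernel
        h, w = self._hw
        xp = self._xp
        W = self.params["W"]
        gW = np.empty_like(W)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, i : i + h, j : j + w, :]
                gW[i, j] = np.tensordot(sl, g, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, i : i + h, j : j + w, :] += g @ W[i, j].T
        if self.l1:
            gW += self.l1 * np.sign(W)
        self.grads["W"] = gW
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        pad = k // 2
        return gxp[:, pad : pad + h, pad : pad + w, :]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0)))
        self._x, self._y = x, y
        return y.astype(x.dtype)

    def backward(self, g):
        return g * np.where(self._x > 0, 1.0, self._y + self.alpha).astype(g.dtype)


class BatchNorm(Layer):
    """Per-channel batch normalization (applied after the activation)."""

    def __init__(self, channels, momentum=0.99, eps=1e-3, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, training):
        axes = self._axes(x)
        if training:
            mu = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.astype(x.dtype)) * ivar.astype(x.dtype)
        self._xhat, self._ivar, self._training = xhat, ivar, training
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, g):
        axes = self._axes(g)
        xhat, ivar = self._xhat, self._ivar.astype(g.dtype)
        self.grads["gamma"] = (g * xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gx = g * self.params["gamma"]
        if not self._training:
            return gx * ivar
        n = g.size // g.shape[-1]
        return (ivar / n) * (
            n * gx - gx.sum(axis=axes) - xhat * (gx * xhat).sum(axis=axes)
        ).astype(g.dtype)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, training):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        xr = xc.reshape(n, h2, 2, w2, 2, c)
        y = xr.max(axis=(2, 4))
        self._xr, self._y, self._shape = xr, y, x.shape
        return y

    def backward(self, g):
        xr, y = self._xr, self._y
        mask = xr == y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        gr = mask * (g[:, :, None, :, None, :] / counts)
        n, h, w, c = self._shape
        out = np.zeros(self._shape, dtype=g.dtype)
        h2, w2 = h // 2, w // 2
        out[:, : 2 * h2, : 2 * w2, :] = gr.reshape(n, 2 * h2, 2 * w2, c)
        return out


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng=None):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class GlobalMaxPool(Layer):
    def forward(self, x, training):
        y = x.max(axis=(1, 2))
        self._x, self._y = x, y
        return y

    def backward(self, g):
        mask = self._x == self._y[:, None, None, :]
        counts = mask.sum(axis=(1, 2), keepdims=True)
        return mask * (g[:, None, None, :] / counts)


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.normal(0.0, scale, (in_dim, out_dim)).astype(dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class Sequential:
    """Plain layer stack producing a single logit per sample."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._outputs = []
        for layer in self.layers:
            x = layer.forward(x, training)
            self._outputs.append(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def gradient_at(self, layer_index: int, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backpropagate ``g`` from the head down to ``layers[layer_index]``.

        Returns (activation, gradient) at that layer's *output*; requires a
        preceding :meth:`forward` call on the same inputs.
        """
        for layer in reversed(self.layers[layer_index + 1 :]):
            g = layer.backward(g)
        return self._outputs[layer_index], g

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0).ravel()

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        w = [layer.params[n].copy() for layer, n in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                w.append(layer.running_mean.copy())
                w.append(layer.running_var.copy())
        return w

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer, n in self.parameters():
            layer.params[n] = next(it).copy()
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()


class Adam:
    """Adam with Keras-style defaults (beta1=0.9, beta2=0.999, eps=1e-7)."""

    def __init__(self, model: Sequential, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for layer, name in self.model.parameters():
            key = (id(layer), name)
            g = layer.grads[name]
            m = self._m.get(key)
            if m is None:
                m = np.zeros_like(g)
                self._m[key] = m
                self._v[key] = np.zeros_like(g)
            v = self._v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            layer.params[name] -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                layer.params[name].dtype
            )
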