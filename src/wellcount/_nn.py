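"""Minimal numpy neural-network engine used to instantiate the counting CNN.

Layout is NHWC throughout.  Convolutions use "same" (ceil) padding and are
evaluated as GEMMs over an im2col expansion; the backward pass reuses the
cached columns, so every heavy operation is a single BLAS call.  All
arithmetic is float32 by default (float64 is available for gradient checks).

Only what the counting network needs is implemented: 5x5 convolutions with
ReLU, 2x2 max pooling, cross-channel local response normalization, fully
connected layers with inverted dropout, and a fused softmax / cross-entropy
head trained by plain SGD.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .network import LayerKind, NetworkSpec


def same_pad(in_size: int, kernel: int, stride: int) -> Tuple[int, int, int]:
    """Output side and (begin, end) padding for ceil-mode 'same' arithmetic."""
    out = -(-in_size // stride)
    total = max((out - 1) * stride + kernel - in_size, 0)
    beg = total // 2
    return out, beg, total - beg


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, OH, OW, k, k, C) patch tensor (copies)."""
    n, _, _, c = xp.shape
    cols = np.empty((n, oh, ow, k, k, c), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, :, i, j, :] = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
    return cols


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """5x5 (or kxk) same-padded convolution, optional fused ReLU.

    Weights are stored with shape (kh, kw, c_in, c_out) so that their element
    count matches the architecture table directly.
    """

    def __init__(self, weight: np.ndarray, bias: np.ndarray, stride: int, relu: bool = True):
        super().__init__()
        self.w, self.b, self.stride, self.relu = weight, bias, stride, relu
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        k = self.w.shape[0]
        n, h, wdt, cin = x.shape
        oh, pb, pe = same_pad(h, k, self.stride)
        ow, qb, qe = same_pad(wdt, k, self.stride)
        xp = np.pad(x, ((0, 0), (pb, pe), (qb, qe), (0, 0)))
        cols = _im2col(xp, k, self.stride, oh, ow)
        self._cols = cols.reshape(n * oh * ow, -1)
        self._in_shape, self._pad = x.shape, (pb, pe, qb, qe)
        cout = self.w.shape[3]
        out = self._cols @ self.w.reshape(-1, cout) + self.b
        out = out.reshape(n, oh, ow, cout)
        if self.relu:
            self._mask = out > 0
            np.maximum(out, 0, out=out)
        return out

    def backward(self, g):
        if self.relu:
            g = g * self._mask
        k = self.w.shape[0]
        n, h, wdt, cin = self._in_shape
        pb, pe, qb, qe = self._pad
        nb, oh, ow, cout = g.shape
        g2 = g.reshape(nb * oh * ow, cout)
        self.grads[0][...] = (self._cols.T @ g2).reshape(self.w.shape)
        self.grads[1][...] = g2.sum(axis=0)
        gcols = (g2 @ self.w.reshape(-1, cout).T).reshape(n, oh, ow, k, k, cin)
        gxp = np.zeros((n, h + pb + pe, wdt + qb + qe, cin), dtype=g.dtype)
        s = self.stride
        for i in range(k):
            for j in range(k):
                gxp[:, i : i + s * oh : s, j : j + s * ow : s, :] += gcols[:, :, :, i, j, :]
        self._cols = None
        return gxp[:, pb : pb + h, qb : qb + wdt, :]


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling with ceil-mode padding (pad value -inf)."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        oh, ow = -(-h // 2), -(-w // 2)
        ph, pw = 2 * oh - h, 2 * ow - w
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        windows = (
            x.reshape(n, oh, 2, ow, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, oh, ow, c, 4)
        )
        self._argmax = windows.argmax(axis=-1)
        self._in_hw = (h, w)
        out = np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]
        return out

    def backward(self, g):
        n, oh, ow, c = g.shape
        h, w = self._in_hw
        gw = np.zeros((n, oh, ow, c, 4), dtype=g.dtype)
        np.put_along_axis(gw, self._argmax[..., None], g[..., None], axis=-1)
        gx = gw.reshape(n, oh, ow, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * oh, 2 * ow, c)
        return gx[:, :h, :w, :]


class LRN(Layer):
    """Cross-channel local response normalization.

    ``b_c = a_c / (bias + alpha * sum_{|c'-c|<=r} a_{c'}^2)^beta``, the
    AlexNet-style form.  Applied even to the single-channel input image, where
    it reduces to a near-identity pointwise rescaling.
    """

    def __init__(self, depth_radius: int = 2, alpha: float = 1e-4, beta: float = 0.75, bias: float = 1.0):
        super().__init__()
        self.r, self.alpha, self.beta, self.bias = depth_radius, alpha, beta, bias

    def _window_sum(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[-1]
        cs = np.concatenate(
            [np.zeros_like(x[..., :1]), np.cumsum(x, axis=-1)], axis=-1
        )
        hi = np.minimum(np.arange(c) + self.r + 1, c)
        lo = np.maximum(np.arange(c) - self.r, 0)
        return cs[..., hi] - cs[..., lo]

    def forward(self, x, training, rng):
        d = self.bias + self.alpha * self._window_sum(x * x)
        scale = d ** (-self.beta)
        self._x, self._d, self._scale = x, d, scale
        return x * scale

    def backward(self, g):
        b_over_d = self._x * self._scale / self._d
        t = self._window_sum(g * b_over_d)
        gx = g * self._scale - 2.0 * self.alpha * self.beta * self._x * t
        self._x = self._d = self._scale = None
        return gx


class Dense(Layer):
    """Fully connected layer; optional ReLU and inverted dropout on its output."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray, relu: bool, dropout_rate: float = 0.0):
        super().__init__()
        self.w, self.b, self.relu, self.dropout_rate = weight, bias, relu, dropout_rate
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        x2 = x.reshape(x.shape[0], -1)
        self._x = x2
        out = x2 @ self.w.T + self.b
        if self.relu:
            self._mask = out > 0
            np.maximum(out, 0, out=out)
        if training and self.dropout_rate > 0.0:
            keep = 1.0 - self.dropout_rate
            self._drop = (rng.random(out.shape) < keep).astype(out.dtype) / keep
            out = out * self._drop
        else:
            self._drop = None
        return out

    def backward(self, g):
        if self._drop is not None:
            g = g * self._drop
        if self.relu:
            g = g * self._mask
        self.grads[0][...] = g.T @ self._x
        self.grads[1][...] = g.sum(axis=0)
        gx = g @ self.w
        self._x = None
        return gx.reshape(self._in_shape)


def init_params(spec: NetworkSpec, seed, dtype=np.float32) -> List[np.ndarray]:
    """He-initialized parameter list [w1, b1, w2, b2, ...] in layer order.

    Every weight is drawn i.i.d. N(0, 2 / fan_in); biases start at zero.
    """
    rng = np.random.default_rng(seed)
    params: List[np.ndarray] = []
    for layer in spec.layers:
        if layer.kind is LayerKind.CONV:
            shape: Tuple[int, ...] = layer.kernel
        elif layer.kind in (LayerKind.FULLY_CONNECTED, LayerKind.OUTPUT):
            shape = (layer.weight_shape[0], int(math.prod(layer.weight_shape[1:])))
        else:
            continue
        std = math.sqrt(2.0 / layer.fan_in)
        params.append(rng.normal(0.0, std, size=shape).astype(dtype))
        params.append(np.zeros(layer.out_channels, dtype=dtype))
    return params


class Sequential:
    """The counting network instantiated from a :class:`NetworkSpec`.

    Parameters are owned by the layer objects; ``parameters()`` returns live
    views so an SGD step mutates the model in place.
    """

    def __init__(self, spec: NetworkSpec, params: Optional[Sequence[np.ndarray]] = None,
                 seed=0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        if params is None:
            params = init_params(spec, seed, dtype=dtype)
        params = [np.asarray(p, dtype=dtype) for p in params]
        self.layers: List[Layer] = []
        self.layer_names: List[str] = []
        it = iter(params)
        for ls in spec.layers:
            if ls.kind is LayerKind.INPUT:
                continue
            if ls.kind is LayerKind.LRN:
                layer: Layer = LRN(spec.lrn_depth_radius, spec.lrn_alpha, spec.lrn_beta, spec.lrn_bias)
            elif ls.kind is LayerKind.MAX_POOL:
                layer = MaxPool2x2()
            elif ls.kind is LayerKind.CONV:
                layer = Conv2D(next(it), next(it), ls.stride, relu=True)
            elif ls.kind is LayerKind.FULLY_CONNECTED:
                layer = Dense(next(it), next(it), relu=True, dropout_rate=spec.dropout_rate)
            else:  # OUTPUT: linear logits; softmax lives in the loss / predict
                layer = Dense(next(it), next(it), relu=False)
            self.layers.append(layer)
            self.layer_names.append(ls.name)
        leftovers = sum(1 for _ in it)
        if leftovers:
            raise ValueError(f"{leftovers} unused parameter tensors for spec")

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                record_shapes: bool = False):
        """Logits for a batch ``x`` of shape (N, side, side) or (N, side, side, 1)."""
        if x.ndim == 3:
            x = x[..., None]
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if x.shape[1] != self.spec.input_side or x.shape[2] != self.spec.input_side:
            raise ValueError(
                f"input side {x.shape[1]}x{x.shape[2]} incompatible with spec "
                f"input {self.spec.input_side}x{self.spec.input_side}"
            )
        shapes = [("input", x.shape[1:])] if record_shapes else None
        for name, layer in zip(self.layer_names, self.layers):
            x = layer.forward(x, training, rng)
            if record_shapes:
                shapes.append((name, x.shape[1:]))
        return (x, shapes) if record_shapes else x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    # -- training ----------------------------------------------------------
    def loss_and_backward(self, x: np.ndarray, y: np.ndarray,
                          rng: np.random.Generator) -> Tuple[float, float]:
        """One forward/backward pass; fills layer gradients (mean over batch).

        Returns (cross-entropy loss, accuracy) on the batch.
        """
        logits = self.forward(x, training=True, rng=rng)
        probs = softmax(logits)
        n = logits.shape[0]
        loss = float(-np.mean(np.log(np.maximum(probs[np.arange(n), y], 1e-12))))
        acc = float(np.mean(probs.argmax(axis=1) == y))
        g = probs.astype(self.dtype)
        g[np.arange(n), y] -= 1.0
        g /= n
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return loss, acc

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for p, gr in zip(layer.params, layer.grads):
                p -= lr * gr

    # -- state -------------------------------------------------------------
    def parameters(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def state_dict(self) -> List[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(arrays):
            raise ValueError("parameter count mismatch")
        for p, a in zip(own, arrays):
            p[...] = a


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=-1, keepdims=True)).astype(np.float64)
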