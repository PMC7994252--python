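"""Minimal NumPy neural-network core used by :mod:`nirsbci.neural_models`.

Implements exactly the layers the two architectures need — 1D valid
convolution, 'same' temporal convolution, full-height depthwise and
separable convolutions, average pooling, batch normalization, EvoNorm-S0,
ELU/ReLU, dropout, dense — each with an analytic backward pass (verified by
finite-difference gradient checks in the test suite), plus the Adamax
optimizer with legacy per-update learning-rate decay.

Tensor layouts are channels-last throughout:

* 1D streams: ``(batch, time, channels)``;
* 2D maps: ``(batch, height, width, channels)`` where height indexes
  measurement channels and width indexes time.
"""

from __future__ import annotations

import copy

import numpy as np

__all__ = ["Layer", "Dense", "Conv1dValid", "EvoNormS0", "Dropout", "Flatten",
           "BatchNorm", "ELU", "ReLU", "TemporalConvSame", "DepthwiseFullHeight",
           "SeparableConvSame", "AvgPoolW", "Sequential", "Adamax",
           "softmax", "softmax_cross_entropy", "he_normal", "glorot_uniform"]


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def glorot_uniform(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameterized layers fill ``params``/``grads`` dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training, rng):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def apply_constraints(self):
        pass


class Dense(Layer):
    def __init__(self, n_in, n_out, rng, init="he"):
        super().__init__()
        if init == "he":
            W = he_normal(rng, (n_in, n_out), n_in)
        else:
            W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.params = {"W": W, "b": np.zeros(n_out)}

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"W": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["W"].T


def conv1d_out_len(n_in: int, kernel: int, stride: int) -> int:
    """Output length of a valid-padding 1D convolution: floor((n-k)/s) + 1."""
    if kernel < 1 or stride < 1:
        raise ValueError("kernel and stride must be >= 1")
    if kernel > n_in:
        raise ValueError(f"kernel {kernel} exceeds input length {n_in}")
    return (n_in - kernel) // stride + 1


class Conv1dValid(Layer):
    """Strided valid-padding convolution along time; input (N, T, C)."""

    def __init__(self, c_in, filters, kernel, stride, rng, init="he"):
        super().__init__()
        self.kernel, self.stride, self.c_in, self.filters = kernel, stride, c_in, filters
        fan_in = kernel * c_in
        if init == "he":
            W = he_normal(rng, (fan_in, filters), fan_in)
        else:
            W = glorot_uniform(rng, (fan_in, filters), fan_in, kernel * filters)
        self.params = {"W": W, "b": np.zeros(filters)}

    def _patches(self, x):
        # (N, T-K+1, C, K) -> strided -> (N, T_out, K*C)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        win = win[:, ::self.stride]
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            x.shape[0], -1, self.kernel * self.c_in)

    def forward(self, x, training, rng):
        self._x_shape = x.shape
        self._P = self._patches(x)
        return self._P @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        N, t_out, F = dy.shape
        KC = self.kernel * self.c_in
        self.grads = {"W": self._P.reshape(-1, KC).T @ dy.reshape(-1, F),
                      "b": dy.sum(axis=(0, 1))}
        dP = (dy @ self.params["W"].T).reshape(N, t_out, self.kernel, self.c_in)
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        for t in range(t_out):
            lo = t * self.stride
            dx[:, lo:lo + self.kernel] += dP[:, t]
        return dx


class EvoNormS0(Layer):
    """Sample-based evolved normalization-activation (S0 variant).

    ``y = x * sigmoid(v * x) / group_std(x) * gamma + beta`` with the group
    standard deviation computed per sample over time and the channels within
    each group.  Batch-size independent, so it behaves identically during
    training and inference.  With v=0, gamma=1, beta=0, groups=1 it reduces
    to ``0.5 * x / std(x)``.
    """

    def __init__(self, channels, groups=8, eps=1e-5):
        super().__init__()
        if channels % groups:
            raise ValueError(f"groups {groups} must divide channels {channels}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels),
                       "v": np.ones(channels)}

    def _grouped(self, a):
        n, t, c = a.shape
        return a.reshape(n, t, self.groups, c // self.groups)

    def forward(self, x, training, rng):
        self._x = x
        vx = x * self.params["v"]
        self._sig = sigmoid(vx)
        self._num = x * self._sig
        xg = self._grouped(x)
        var = xg.var(axis=(1, 3), keepdims=True)
        self._mu = xg.mean(axis=(1, 3), keepdims=True)
        self._s = np.sqrt(var + self.eps)          # (N,1,g,1)
        s_full = self._ungroup(np.broadcast_to(self._s, xg.shape))
        self._s_full = s_full
        self._u = self._num / s_full
        return self._u * self.params["gamma"] + self.params["beta"]

    def _ungroup(self, ag):
        n, t, g, cg = ag.shape
        return ag.reshape(n, t, g * cg)

    def backward(self, dy):
        x, sig, num = self._x, self._sig, self._num
        gamma, v = self.params["gamma"], self.params["v"]
        self.grads = {"gamma": (dy * self._u).sum(axis=(0, 1)),
                      "beta": dy.sum(axis=(0, 1))}
        du = dy * gamma
        # through the numerator x*sigmoid(vx)
        dsig = sig * (1.0 - sig)
        dnum_dx = sig + x * v * dsig
        dx = du * dnum_dx / self._s_full
        self.grads["v"] = (du * (x * x * dsig) / self._s_full).sum(axis=(0, 1))
        # through the group std
        m = self._grouped(x).shape[1] * self._grouped(x).shape[3]
        T_g = self._grouped(du * num).sum(axis=(1, 3), keepdims=True)  # (N,1,g,1)
        dmean = self._grouped(x) - self._mu
        dx_g = -T_g * dmean / (m * self._s ** 3)   # broadcasts to full group shape
        dx += self._ungroup(dx_g)
        return dx


class Dropout(Layer):
    """Inverted dropout: scales kept units by 1/(1-p) during training."""

    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        u = rng.random(x.shape, dtype=np.float32)
        self._mask = ((u < keep) / np.asarray(keep, dtype=x.dtype)).astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over all non-channel axes (channels last)."""

    def __init__(self, channels, momentum=0.99, eps=1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training, rng):
        c = x.shape[-1]
        x2 = np.ascontiguousarray(x).reshape(-1, c)
        m = x2.shape[0]
        if training:
            # single-pass sums avoid large temporaries
            mu = x2.sum(axis=0) / m
            ex2 = np.einsum("nc,nc->c", x2, x2) / m
            var = np.maximum(ex2 - mu * mu, 0.0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._mu = mu
        self._std = np.sqrt(var + self.eps)
        self._x2 = x2
        self._shape = x.shape
        self._training = training
        self._m = m
        # fused affine: y = x * a + b with a = gamma/std, b = beta - mu*a
        a = (self.params["gamma"] / self._std).astype(x.dtype)
        b = (self.params["beta"] - mu * a).astype(x.dtype)
        return (x2 * a + b).reshape(x.shape)

    def backward(self, dy):
        c = dy.shape[-1]
        dy2 = np.ascontiguousarray(dy).reshape(-1, c)
        x2, mu, std = self._x2, self._mu, self._std
        sum_dy = dy2.sum(axis=0)
        sum_dyx = np.einsum("nc,nc->c", dy2, x2)
        dgamma = (sum_dyx - mu * sum_dy) / std        # = sum(dy * xhat)
        self.grads = {"gamma": dgamma, "beta": sum_dy}
        g_over_std = self.params["gamma"] / std
        if not self._training:
            return (dy2 * g_over_std.astype(dy.dtype)).reshape(self._shape)
        m = self._m
        mean_dy = sum_dy / m
        mean_dyxhat = dgamma / m
        # dx = g/std * (dy - mean(dy) - xhat * mean(dy*xhat)), xhat expanded
        c1 = g_over_std.astype(dy.dtype)
        c2 = (g_over_std * mean_dyxhat / std).astype(dy.dtype)
        c0 = (-g_over_std * mean_dy + g_over_std * mean_dyxhat * mu / std).astype(dy.dtype)
        return (dy2 * c1 - x2 * c2 + c0).reshape(self._shape)


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training, rng):
        self._y = np.where(x > 0, x, self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0))
        self._pos = x > 0
        return self._y

    def backward(self, dy):
        return dy * np.where(self._pos, 1.0, self._y + self.alpha)


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._pos = x > 0
        return x * self._pos

    def backward(self, dy):
        return dy * self._pos


class TemporalConvSame(Layer):
    """Bias-free 'same'-padded convolution along the width (time) axis.

    Input (N, H, W, C); kernel spans ``kw`` time samples, producing F maps.
    """

    def __init__(self, c_in, filters, kw, rng):
        super().__init__()
        self.c_in, self.filters, self.kw = c_in, filters, kw
        fan_in = kw * c_in
        self.params = {"W": glorot_uniform(rng, (fan_in, filters), fan_in,
                                           kw * filters)}

    def _pad(self, x):
        pl, pr = (self.kw - 1) // 2, self.kw // 2
        self._pads = (pl, pr)
        return np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))

    def forward(self, x, training, rng):
        self._x_shape = x.shape
        xp = self._pad(x)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kw, axis=2)
        # (N,H,W,C,kw) -> (N,H,W,kw*C)
        self._P = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 3)).reshape(
            x.shape[0], x.shape[1], x.shape[2], self.kw * self.c_in)
        return self._P @ self.params["W"]

    def backward(self, dy):
        N, H, W, F = dy.shape
        KC = self.kw * self.c_in
        self.grads = {"W": self._P.reshape(-1, KC).T @ dy.reshape(-1, F)}
        dP = (dy @ self.params["W"].T).reshape(N, H, W, self.kw, self.c_in)
        pl, pr = self._pads
        dxp = np.zeros((N, H, W + pl + pr, self.c_in), dtype=dy.dtype)
        for k in range(self.kw):
            dxp[:, :, k:k + W] += dP[:, :, :, k]
        return dxp[:, :, pl:pl + W]


class DepthwiseFullHeight(Layer):
    """Depthwise convolution whose kernel spans the full height axis.

    Input (N, H, W, C) -> output (N, 1, W, C*D): for each input map c, D
    spatial filters of shape (H, 1) collapse the height axis.  Bias-free;
    each filter is constrained to unit maximum L2 norm.
    """

    def __init__(self, height, c_in, depth, rng, max_norm=1.0):
        super().__init__()
        self.height, self.c_in, self.depth = height, c_in, depth
        self.max_norm = max_norm
        self.params = {"K": glorot_uniform(rng, (height, c_in, depth), height,
                                           depth)}

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        # batched matmul over input maps: (c, n*w, h) @ (c, h, d)
        self._xt = np.ascontiguousarray(x.transpose(3, 0, 2, 1)).reshape(c, n * w, h)
        K = self.params["K"].astype(x.dtype)
        y = self._xt @ K.transpose(1, 0, 2)               # (c, n*w, d)
        self._shape = (n, h, w, c)
        y = y.reshape(c, n, w, self.depth).transpose(1, 2, 0, 3)
        return np.ascontiguousarray(y).reshape(n, 1, w, c * self.depth)

    def backward(self, dy):
        n, h, w, c = self._shape
        dy4 = dy.reshape(n, w, c, self.depth)
        dyt = np.ascontiguousarray(dy4.transpose(2, 0, 1, 3)).reshape(c, n * w,
                                                                      self.depth)
        K = self.params["K"]
        # dK: (c, h, n*w) @ (c, n*w, d) -> (c, h, d)
        self.grads = {"K": (self._xt.transpose(0, 2, 1) @ dyt).transpose(1, 0, 2)
                      .astype(K.dtype)}
        dxt = dyt @ K.transpose(1, 2, 0).astype(dy.dtype)  # (c, n*w, h)
        return np.ascontiguousarray(
            dxt.reshape(c, n, w, h).transpose(1, 3, 2, 0))

    def apply_constraints(self):
        if self.max_norm is None:
            return
        K = self.params["K"]
        norms = np.sqrt((K ** 2).sum(axis=0, keepdims=True))
        np.multiply(K, np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12)),
                    out=K)


class SeparableConvSame(Layer):
    """Depthwise (1, kw) 'same' convolution along width + 1x1 pointwise mix."""

    def __init__(self, c_in, filters, kw, rng):
        super().__init__()
        self.c_in, self.filters, self.kw = c_in, filters, kw
        self.params = {"Kd": glorot_uniform(rng, (kw, c_in), kw, 1),
                       "Wp": glorot_uniform(rng, (c_in, filters), c_in, filters)}

    def forward(self, x, training, rng):
        pl, pr = (self.kw - 1) // 2, self.kw // 2
        self._pads = (pl, pr)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        self._xp = xp
        w = x.shape[2]
        Kd = self.params["Kd"].astype(x.dtype)
        # depthwise along width as a sum of shifted scaled slices
        mid = xp[:, :, 0:w] * Kd[0]
        for k in range(1, self.kw):
            mid += xp[:, :, k:k + w] * Kd[k]
        self._mid = mid
        return mid @ self.params["Wp"].astype(x.dtype)

    def backward(self, dy):
        self.grads = {"Wp": (self._mid.reshape(-1, self.c_in).T
                             @ dy.reshape(-1, self.filters)).astype(
                                 self.params["Wp"].dtype)}
        dmid = dy @ self.params["Wp"].T.astype(dy.dtype)
        n, h, wp, c = self._xp.shape
        pl, pr = self._pads
        w = wp - pl - pr
        self.grads["Kd"] = np.stack(
            [(self._xp[:, :, k:k + w] * dmid).sum(axis=(0, 1, 2))
             for k in range(self.kw)]).astype(self.params["Kd"].dtype)
        dxp = np.zeros((n, h, wp, c), dtype=dy.dtype)
        Kd = self.params["Kd"].astype(dy.dtype)
        for k in range(self.kw):
            dxp[:, :, k:k + w] += dmid * Kd[k]
        return dxp[:, :, pl:pl + w]


class AvgPoolW(Layer):
    """Non-overlapping average pooling along width; valid (floor) semantics."""

    def __init__(self, k):
        super().__init__()
        self.k = k

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        self._w_in = w
        w_out = w // self.k
        self._w_used = w_out * self.k
        return x[:, :, :self._w_used].reshape(n, h, w_out, self.k, c).mean(axis=3)

    def backward(self, dy):
        n, h, w_out, c = dy.shape
        dx = np.zeros((n, h, self._w_in, c), dtype=dy.dtype)
        dx[:, :, :self._w_used] = np.repeat(dy / self.k, self.k, axis=2)
        return dx


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean categorical cross-entropy and gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.maximum(p[np.arange(n), labels], 1e-30)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Sequential:
    """Plain feed-forward stack with a seeded generator for dropout masks."""

    def __init__(self, layers, rng_seed=0):
        self.layers = list(layers)
        self.rng = np.random.default_rng(rng_seed)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training, self.rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[n].size for layer, n in self.parameters())

    def get_weights(self):
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_weights(self, weights):
        for layer, w in zip(self.layers, weights):
            layer.params = copy.deepcopy(w)

    def apply_constraints(self):
        for layer in self.layers:
            layer.apply_constraints()

    def astype(self, dtype):
        """Cast all parameters and buffers (e.g. for float32 training)."""
        self.dtype = np.dtype(dtype)
        for layer in self.layers:
            layer.params = {k: v.astype(self.dtype) for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm):
                layer.running_mean = layer.running_mean.astype(self.dtype)
                layer.running_var = layer.running_var.astype(self.dtype)
        return self

    def shape_trace(self, input_shape):
        """Per-layer output shapes (batch axis stripped) for a dummy input."""
        x = np.zeros((1, *input_shape))
        trace = []
        for layer in self.layers:
            x = layer.forward(x, False, self.rng)
            trace.append(tuple(x.shape[1:]) if x.ndim > 2 else (x.shape[1],))
        return trace


class Adamax:
    """Adamax with legacy per-update learning-rate decay lr/(1 + decay*t)."""

    def __init__(self, model: Sequential, lr=5e-4, decay=5e-8, beta1=0.9,
                 beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.decay = lr, decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.u = {}
        for layer, name in model.parameters():
            key = (id(layer), name)
            self.m[key] = np.zeros_like(layer.params[name])
            self.u[key] = np.zeros_like(layer.params[name])

    def step(self):
        lr_t = self.lr / (1.0 + self.decay * self.t)
        self.t += 1
        denom = 1.0 - self.beta1 ** self.t
        for layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            self.m[key] = self.beta1 * self.m[key] + (1.0 - self.beta1) * g
            self.u[key] = np.maximum(self.beta2 * self.u[key], np.abs(g))
            layer.params[name] -= (lr_t / denom) * self.m[key] / (self.u[key] + self.eps)
        self.model.apply_constraints()
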