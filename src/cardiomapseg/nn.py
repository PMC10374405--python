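"""Minimal CPU neural-network layers with explicit forward/backward passes.

Everything is float32 NumPy. Each layer caches what its backward pass needs,
accumulates parameter gradients in ``grads`` and returns the gradient with
respect to its input. Composite blocks (sequential chains, residual blocks)
recurse. This is deliberately a small, fully deterministic engine sized for
desk-scale segmentation experiments, not a general autograd framework.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base layer: parameter/grad registries plus the forward/backward pair."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sublayers(self) -> list[tuple[str, "Layer"]]:
        return []

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.params.items()}
        for name, sub in self.sublayers():
            out.update(sub.named_params(f"{prefix}{name}."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self.grads.items()}
        for name, sub in self.sublayers():
            out.update(sub.named_grads(f"{prefix}{name}."))
        return out

    def zero_grads(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0
        for _, sub in self.sublayers():
            sub.zero_grads()

    def num_params(self) -> int:
        return sum(int(p.size) for p in self.named_params().values())


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv2d(Layer):
    """2D convolution with 'same'-style zero padding, via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        self.params["w"] = he_init(rng, (cout, cin * k * k), cin * k * k)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.has_bias = bias
        if bias:
            self.params["b"] = np.zeros(cout, dtype=F32)
            self.grads["b"] = np.zeros(cout, dtype=F32)
        self._cache = None

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        k, s = self.k, self.stride
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, OH, OW, k, k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            -1, self.cin * k * k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, oh, ow)
        y = cols @ self.params["w"].T
        if self.has_bias:
            y += self.params["b"]
        if train:
            self._cache = (cols, x.shape, oh, ow)
        return y.reshape(n, oh, ow, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape, oh, ow = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.grads["w"] += dyf.T @ cols
        if self.has_bias:
            self.grads["b"] += dyf.sum(axis=0)
        dcols = (dyf @ self.params["w"]).reshape(n, oh, ow, self.cin, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += dcols[
                    :, :, :, :, ki, kj
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2x2(Layer):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.params["w"] = he_init(rng, (cin, cout, 2, 2), cin * 4)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self.grads["w"] = np.zeros_like(self.params["w"])
        self.grads["b"] = np.zeros(cout, dtype=F32)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._x = x
        y = np.einsum("ncij,cdab->ndiajb", x, self.params["w"], optimize=True)
        y = y.reshape(n, self.cout, 2 * h, 2 * w)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n, c, h, w = x.shape
        blocks = dy.reshape(n, self.cout, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5)
        # blocks: (n, d, i, j, a, b)
        self.grads["w"] += np.einsum("ncij,ndijab->cdab", x, blocks, optimize=True)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        return np.einsum("ndijab,cdab->ncij", blocks, self.params["w"], optimize=True).astype(F32)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=F32)
        self.params["beta"] = np.zeros(channels, dtype=F32)
        self.grads["gamma"] = np.zeros(channels, dtype=F32)
        self.grads["beta"] = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv, x.shape)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grads["gamma"] += np.sum(dy * xhat, axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        xb = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xb.max(axis=(3, 5))
        if train:
            self._mask = xb == y[:, :, :, None, :, None]
            self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        db = self._mask * dy[:, :, :, None, :, None]
        return db.reshape(n, c, h, w).astype(F32)


def _bilinear_matrix(out_len: int, in_len: int) -> np.ndarray:
    """Dense (out_len, in_len) bilinear resize operator, align_corners=False."""
    a = np.zeros((out_len, in_len), dtype=F32)
    scale = in_len / out_len
    for o in range(out_len):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        w1 = src - i0
        a[o, np.clip(i0, 0, in_len - 1)] += 1.0 - w1
        a[o, np.clip(i0 + 1, 0, in_len - 1)] += w1
    return a


class BilinearUp2x(Layer):
    """Exact 2x bilinear upsampling as a fixed linear operator per axis."""

    def __init__(self):
        super().__init__()
        self._mats: dict[int, np.ndarray] = {}

    def _mat(self, n: int) -> np.ndarray:
        if n not in self._mats:
            self._mats[n] = _bilinear_matrix(2 * n, n)
        return self._mats[n]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._shape = (h, w)
        ah, aw = self._mat(h), self._mat(w)
        return np.matmul(np.matmul(ah, x), aw.T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._shape
        ah, aw = self._mat(h), self._mat(w)
        return np.matmul(np.matmul(ah.T, dy), aw).astype(F32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def sublayers(self):
        return [(str(i), l) for i, l in enumerate(self.layers)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def conv_bn_relu(cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, k=k, stride=stride, bias=False, rng=rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class BasicBlock(Layer):
    """Two-conv residual block (3x3 + 3x3) with optional strided projection."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.main = Sequential(
            Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng),
            BatchNorm2d(cout),
            ReLU(),
            Conv2d(cout, cout, 3, bias=False, rng=rng),
            BatchNorm2d(cout),
        )
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(cout),
            )
        self.relu = ReLU()

    def sublayers(self):
        subs = [("main", self.main), ("relu", self.relu)]
        if self.proj is not None:
            subs.append(("proj", self.proj))
        return subs

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        m = self.main.forward(x, train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        return self.relu.forward(m + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        dx = self.main.backward(d)
        if self.proj is not None:
            dx = dx + self.proj.backward(d)
        else:
            dx = dx + d
        return dx


class Bottleneck(Layer):
    """ResNet bottleneck: 1x1 reduce, 3x3 (strided), 1x1 expand, residual add."""

    def __init__(self, cin: int, mid: int, cout: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.main = Sequential(
            Conv2d(cin, mid, 1, bias=False, rng=rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, mid, 3, stride=stride, bias=False, rng=rng),
            BatchNorm2d(mid),
            ReLU(),
            Conv2d(mid, cout, 1, bias=False, rng=rng),
            BatchNorm2d(cout),
        )
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                BatchNorm2d(cout),
            )
        self.relu = ReLU()

    sublayers = BasicBlock.sublayers
    forward = BasicBlock.forward
    backward = BasicBlock.backward


class Adam:
    """Adam over a layer tree's named parameters, updating in place."""

    def __init__(self, root: Layer, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.root = root
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        params = root.named_params()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        params = self.root.named_params()
        grads = self.root.named_grads()
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= (lr * (self.m[k] / bc1)
                  / (np.sqrt(self.v[k] / bc2) + self.eps)).astype(p.dtype)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
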