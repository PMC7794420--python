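"""Minimal 3-D neural-network layers with explicit backward passes.

Everything is float32 numpy; convolutions run as a single BLAS GEMM per
pass over a column buffer.  The activation layout is channels-last
``(N, D, H, W, C)``: an in-plane (height, width) offset slice of the padded
input is then a strided view whose innermost W·C run is contiguous, which
keeps the column-buffer fills close to memory bandwidth.  The 3×3×3 kernel
is decomposed into its 9 in-plane offsets (gathered into the buffer) times
3 depth-plane shifts (mere slices of the GEMM result), so the buffer is a
third of the full im2col size and is built once per layer per pass.

Each layer caches what its backward pass needs during ``forward`` and
honours the train/eval mode of the most recent forward (batch statistics vs
running statistics for batch normalization).
"""

from __future__ import annotations

import numpy as np

from ._kernels import (
    bn_backward_dx,
    bn_transform,
    colscatter9,
    conv_out3,
    im2col9,
    im2col27,
    maxpool_bwd,
    maxpool_fwd,
    relu_fwd,
)

F32 = np.float32


class Layer:
    """Base class: parameterised layers expose ``params``/``grads`` lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3×3×3 convolution, stride 1, same padding.

    Weights are stored as ``(3, 9·c_in, c_out)``: depth-plane shift ``a``
    major, then the in-plane offset/input-channel column index matching the
    buffer layout.  With the output written as

        out[i] = Σ_a cols[i + a] @ w[a] + b

    (``cols[p]`` the buffer row for padded depth plane ``p``), forward,
    weight gradient and input gradient each reduce to one concatenated GEMM.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 init_sd: float = 0.1, need_input_grad: bool = True):
        self.c_in, self.c_out = c_in, c_out
        self.need_input_grad = need_input_grad
        self.w = rng.normal(0.0, init_sd, (3, 9 * c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _w_cat(self) -> np.ndarray:
        # (9c, 3f): the three depth-shift blocks side by side
        return np.ascontiguousarray(self.w.transpose(1, 0, 2)).reshape(
            9 * self.c_in, 3 * self.c_out
        )

    @property
    def _narrow(self) -> bool:
        # with 1-2 input channels the full 27-offset buffer is tiny and one
        # plain GEMM beats the plane-shift scheme (whose concatenated output
        # is 3·c_out wide on the full-resolution grid)
        return self.c_in <= 2

    def forward(self, x, train=True):
        n, d, h, w, c = x.shape
        assert c == self.c_in
        f = self.c_out
        xp = np.zeros((n, d + 2, h + 2, w + 2, c), dtype=F32)
        xp[:, 1:-1, 1:-1, 1:-1, :] = x
        if self._narrow:
            cols = np.empty((n, d, h, w, 27 * c), dtype=F32)
            im2col27(xp, cols)
            # weight rows are already (depth-shift, in-plane offset, channel)
            wfull = self.w.reshape(27 * c, f)
            out = (cols.reshape(-1, 27 * c) @ wfull).reshape(n, d, h, w, f)
            out += self.b
            self._cols, self._shape = cols, (n, d, h, w)
            return out
        cols = np.empty((n, d + 2, h, w, 9 * c), dtype=F32)
        im2col9(xp, cols)
        y = (cols.reshape(-1, 9 * c) @ self._w_cat()).reshape(
            n, d + 2, h, w, 3, f
        )
        out = np.empty((n, d, h, w, f), dtype=F32)
        conv_out3(y, self.b, out)
        self._cols, self._shape = cols, (n, d, h, w)
        return out

    def backward(self, dy):
        n, d, h, w = self._shape
        c, f = self.c_in, self.c_out
        cols = self._cols
        self.db[...] = dy.sum(axis=(0, 1, 2, 3))
        if self._narrow:
            if self.need_input_grad:
                raise NotImplementedError(
                    "narrow-channel convolutions sit on the network input"
                )
            dyf = dy.reshape(-1, f)
            self.dw[...] = (cols.reshape(-1, 27 * c).T @ dyf).reshape(
                3, 9 * c, f
            )
            self._cols = None
            return None
        if not self.need_input_grad:
            # weight gradients only, via per-plane batched GEMMs — avoids the
            # shifted-dy buffer, which is huge when c_out >> c_in (first layer)
            colsv = cols.reshape(n, d + 2, h * w, 9 * c)
            dyv = dy.reshape(n, d, h * w, f)
            for a in range(3):
                prod = np.matmul(
                    colsv[:, a:a + d].transpose(0, 1, 3, 2), dyv
                )
                self.dw[a][...] = prod.sum(axis=(0, 1))
            self._cols = None
            return None
        # D[..., a, :] holds dy shifted to padded depth plane p = i + a
        D = np.zeros((n, d + 2, h, w, 3, f), dtype=F32)
        for a in range(3):
            D[:, a:a + d, :, :, a, :] = dy
        Dflat = D.reshape(-1, 3 * f)
        cflat = cols.reshape(-1, 9 * c)
        dw_cat = cflat.T @ Dflat  # (9c, 3f)
        self.dw[...] = dw_cat.reshape(9 * c, 3, f).transpose(1, 0, 2)
        dcols = (Dflat @ self._w_cat().T).reshape(n, d + 2, h, w, 9 * c)
        dxp = np.zeros((n, d + 2, h + 2, w + 2, c), dtype=F32)
        colscatter9(dcols, dxp)
        self._cols = None
        return np.ascontiguousarray(dxp[:, 1:-1, 1:-1, 1:-1, :])


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Running statistics are accumulated with momentum 0.9 during training and
    used verbatim in eval mode.  Reductions go through einsum and the
    backward pass reuses its buffers in place — these layers sit on the
    widest activations in the network.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None
        self._collect: list | None = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train=True):
        m_count = x.size // x.shape[-1]
        if train:
            mean = np.einsum("ndhwc->c", x) / F32(m_count)
            sq = np.einsum("ndhwc,ndhwc->c", x, x) / F32(m_count)
            var = np.maximum(sq - mean**2, 0.0)
            mom = self.momentum
            self.running_mean[...] = mom * self.running_mean + (1 - mom) * mean
            self.running_var[...] = mom * self.running_var + (1 - mom) * var
            if self._collect is not None:
                self._collect.append((mean, var))
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = np.empty_like(x)
        out = np.empty_like(x)
        c = x.shape[-1]
        bn_transform(x.reshape(-1, c), self.gamma, self.beta,
                     np.asarray(mean, dtype=F32), inv,
                     xhat.reshape(-1, c), out.reshape(-1, c))
        self._cache = (xhat, inv, train, m_count)
        return out

    def backward(self, dy):
        xhat, inv, train, m = self._cache
        self.dgamma[...] = np.einsum("ndhwc,ndhwc->c", dy, xhat)
        self.dbeta[...] = np.einsum("ndhwc->c", dy)
        if not train:
            return dy * (self.gamma * inv)
        # dx = γ·inv·(dy − Σdy/m − x̂·Σ(dy·x̂)/m), written into the (disposable)
        # upstream buffer
        c = dy.shape[-1]
        bn_backward_dx(dy.reshape(-1, c), xhat.reshape(-1, c), self.gamma,
                       inv, self.dgamma, self.dbeta, F32(m))
        self._cache = None
        return dy


class ReLU(Layer):
    """In-place rectifier: the incoming buffer is always this layer's own
    upstream scratch, so it is clipped where it stands."""

    def forward(self, x, train=True):
        mask = np.empty(x.shape, dtype=np.bool_)
        relu_fwd(x.reshape(-1), mask.reshape(-1))
        self._mask = mask
        return x

    def backward(self, dy):
        dy *= self._mask
        return dy


class MaxPool3d(Layer):
    """2×2×2 max pooling, stride 2.

    The backward pass routes gradient to the first maximal element of each
    block (ties broken by scan order, like the mainstream frameworks).
    """

    def forward(self, x, train=True):
        n, d, h, w, c = x.shape
        out = np.empty((n, d // 2, h // 2, w // 2, c), dtype=F32)
        arg = np.empty(out.shape, dtype=np.uint8)
        maxpool_fwd(x, out, arg)
        self._arg = arg
        self._inshape = x.shape
        return out

    def backward(self, dy):
        dx = np.zeros(self._inshape, dtype=F32)
        maxpool_bwd(dy, self._arg, dx)
        self._arg = None
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_sd: float = 0.1):
        self.w = rng.normal(0.0, init_sd, (n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy on the two-class softmax output."""
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.mean(np.log(p)))


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
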