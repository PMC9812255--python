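"""Minimal trainable layers for the spatial-temporal graph networks.

Implemented directly on numpy with hand-derived backward passes: the
networks are small (23 nodes, 25 time steps, two blocks) so explicit
einsum-based gradients are fast, dependency-free and bit-reproducible on a
single thread.  Tensors are laid out as [batch, time, node, channel].
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=float)
        self.g = np.zeros_like(self.v)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class TemporalConv:
    """Valid 1-D convolution along time, the same kernel at every node.

    Input [B, M, n, Ci] -> output [B, M - Kt + 1, n, Co].
    """

    def __init__(self, Kt: int, c_in: int, c_out: int,
                 rng: np.random.Generator):
        if Kt < 1:
            raise ValueError("Kt must be >= 1")
        self.Kt = Kt
        self.G = Param(glorot_uniform(rng, (Kt, c_in, c_out),
                                      Kt * c_in, Kt * c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.G, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, M, n, Ci = x.shape
        if M < self.Kt:
            raise ValueError(f"time length {M} shorter than kernel {self.Kt}")
        Mo = M - self.Kt + 1
        self._x = x
        y = np.zeros((B, Mo, n, self.G.v.shape[2]))
        for k in range(self.Kt):
            y += np.einsum("btvi,io->btvo", x[:, k:k + Mo], self.G.v[k])
        return y + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        Mo = dy.shape[1]
        dx = np.zeros_like(x)
        for k in range(self.Kt):
            self.G.g[k] += np.einsum("btvi,btvo->io", x[:, k:k + Mo], dy)
            dx[:, k:k + Mo] += np.einsum("btvo,io->btvi", dy, self.G.v[k])
        self.b.g += dy.sum(axis=(0, 1, 2))
        return dx


class GraphConv:
    """First-order graph convolution with a per-sample propagation matrix.

    ``y[b, t] = S[b] @ x[b, t] @ Theta``; the same spectral kernel Theta is
    imposed on every time frame in parallel.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.Theta = Param(glorot_uniform(rng, (c_in, c_out), c_in, c_out))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.Theta, self.b]

    def forward(self, x: np.ndarray, S: np.ndarray) -> np.ndarray:
        self._x, self._S = x, S
        self._Sx = np.einsum("buv,btvi->btui", S, x)
        return np.einsum("btui,io->btuo", self._Sx, self.Theta.v) + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.Theta.g += np.einsum("btui,btuo->io", self._Sx, dy)
        self.b.g += dy.sum(axis=(0, 1, 2))
        dSx = np.einsum("btuo,io->btui", dy, self.Theta.v)
        # S is symmetric per construction, but use S^T for correctness
        return np.einsum("bvu,btui->btvi", self._S.transpose(0, 2, 1), dSx)


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class LayerNorm:
    """Layer normalisation over the full (time, node, channel) feature map
    of each sample, with a learned per-channel affine.

    Normalising jointly over nodes (rather than per node) preserves the
    relative amplitude structure between nodes that the graph convolution
    induces, which is often the discriminative signal.
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma.v * self._xhat + self.beta.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.gamma.g += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.g += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.v
        m = dxhat.mean(axis=(1, 2, 3), keepdims=True)
        mx = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        return inv * (dxhat - m - xhat * mx)


class Dense:
    """Flatten to a vector and map to a single logit."""

    def __init__(self, n_features: int, rng: np.random.Generator):
        self.w = Param(glorot_uniform(rng, (n_features,), n_features, 1))
        self.b = Param(np.zeros(1))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B = x.shape[0]
        self._z = x.reshape(B, -1)
        return self._z @ self.w.v + self.b.v[0]

    def backward(self, dlogit: np.ndarray, x_shape) -> np.ndarray:
        self.w.g += self._z.T @ dlogit
        self.b.g += dlogit.sum(keepdims=True)
        return np.outer(dlogit, self.w.v).reshape(x_shape)


class STConvBlock:
    """Temporal conv -> graph conv -> ReLU -> temporal conv -> layer norm.

    With ``use_graph=False`` the spatial unit is skipped (the purely
    temporal baseline); the ReLU then follows the first temporal conv.
    Output time length is M - 2 (Kt - 1).
    """

    def __init__(self, Kt: int, c_in: int, c_out: int,
                 rng: np.random.Generator, use_graph: bool = True):
        self.use_graph = use_graph
        self.gamma0 = TemporalConv(Kt, c_in, c_out, rng)
        self.theta = GraphConv(c_out, c_out, rng) if use_graph else None
        self.relu = ReLU()
        self.gamma1 = TemporalConv(Kt, c_out, c_out, rng)
        self.norm = LayerNorm(c_out)

    def params(self):
        ps = self.gamma0.params()
        if self.theta is not None:
            ps += self.theta.params()
        return ps + self.gamma1.params() + self.norm.params()

    def forward(self, x: np.ndarray, S: np.ndarray | None) -> np.ndarray:
        h = self.gamma0.forward(x)
        if self.theta is not None:
            h = self.theta.forward(h, S)
        h = self.relu.forward(h)
        h = self.gamma1.forward(h)
        if h.shape[1] < 1:
            raise ValueError("block output has no time steps left")
        return self.norm.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.norm.backward(dy)
        d = self.gamma1.backward(d)
        d = self.relu.backward(d)
        if self.theta is not None:
            d = self.theta.backward(d)
        return self.gamma0.backward(d)


class Network:
    """Stacked ST-Conv blocks, flatten, dense head, sigmoid output."""

    def __init__(self, Kt: int, n_blocks: int, channels, n_nodes: int,
                 in_len: int, seed: int, use_graph: bool = True):
        out_len = in_len - n_blocks * 2 * (Kt - 1)
        if out_len < 1:
            raise ValueError(
                f"config leaves no time steps: in_len {in_len}, "
                f"{n_blocks} blocks of Kt={Kt}"
            )
        if len(channels) != n_blocks:
            raise ValueError("need one channel width per block")
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = 1
        for c_out in channels:
            self.blocks.append(STConvBlock(Kt, c_in, c_out, rng, use_graph))
            c_in = c_out
        self.flat_dim = out_len * n_nodes * channels[-1]
        self.head = Dense(self.flat_dim, rng)
        self.use_graph = use_graph

    def params(self) -> list[Param]:
        ps = []
        for b in self.blocks:
            ps += b.params()
        return ps + self.head.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def forward_logits(self, X: np.ndarray, S: np.ndarray | None) -> np.ndarray:
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in network input")
        if self.use_graph and S is None:
            raise ValueError("graph variant requires propagation matrices S")
        h = X
        for b in self.blocks:
            h = b.forward(h, S)
        self._trunk_shape = h.shape
        return self.head.forward(h)

    def backward(self, dlogit: np.ndarray) -> None:
        d = self.head.backward(dlogit, self._trunk_shape)
        for b in reversed(self.blocks):
            d = b.backward(d)

    def get_state(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state, strict=True):
            p.v[...] = v


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    y = np.asarray(y, dtype=float)
    # log(1 + exp(-|z|)) formulation for numerical stability
    loss = np.mean(np.maximum(logits, 0) - logits * y
                   + np.log1p(np.exp(-np.abs(logits))))
    grad = (sigmoid(logits) - y) / y.size
    return float(loss), grad


class Adam:
    """Adam with optional decoupled weight decay."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = self.b1 * m + (1 - self.b1) * p.g
            s[...] = self.b2 * s + (1 - self.b2) * p.g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            shat = s / (1 - self.b2 ** self.t)
            p.v -= self.lr * (mhat / (np.sqrt(shat) + self.eps)
                              + self.wd * p.v)


def temporal_conv(Y: np.ndarray, Gamma: np.ndarray,
                  bias: np.ndarray | None = None) -> np.ndarray:
    """Functional valid temporal convolution of [M, n, Ci] (or batched
    [B, M, n, Ci]) with kernel [Kt, Ci, Co] — the operation the
    :class:`TemporalConv` layer trains."""
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 3
    if single:
        Y = Y[None]
    Kt = Gamma.shape[0]
    Mo = Y.shape[1] - Kt + 1
    if Mo < 1:
        raise ValueError("sequence shorter than the kernel")
    out = np.zeros((Y.shape[0], Mo, Y.shape[2], Gamma.shape[2]))
    for k in range(Kt):
        out += np.einsum("btvi,io->btvo", Y[:, k:k + Mo], Gamma[k])
    if bias is not None:
        out += bias
    return out[0] if single else out
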