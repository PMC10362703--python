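"""Minimal numpy neural-network core with hand-written backpropagation.

Implements exactly the layers the graph-generation policy needs: linear
maps, layer normalization, multi-head self-attention, position-wise
feedforward blocks, and the Adam update rule.  Every layer caches its
forward activations and exposes ``backward`` returning the gradient with
respect to its input while accumulating parameter gradients in place.

Shapes follow the convention that the first axis indexes variables (the
"sequence" axis) and the last axis is the feature width.
"""

from __future__ import annotations

import numpy as np

_LN_EPS = 1e-5


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def xavier_uniform(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out))


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(xavier_uniform(rng, d_in, d_out))
        self.b = Param(np.zeros(d_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class LayerNorm:
    """Normalization over the last axis with learned gain and bias."""

    def __init__(self, width: int):
        self.g = Param(np.ones(width))
        self.b = Param(np.zeros(width))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g.value * xhat + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.g.grad += (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * self.g.value
        # per-row backward through the standardization
        mean_d = dxhat.mean(axis=-1, keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - mean_d - xhat * mean_dx)

    def params(self):
        return [self.g, self.b]


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention:
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        d, _ = x.shape
        return x.reshape(d, self.n_heads, self.d_k).transpose(1, 0, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        d = x.shape[0]
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 2, 1) / np.sqrt(self.d_k)
        attn = _softmax(scores)
        ctx = attn @ v                       # (h, d, d_k)
        merged = ctx.transpose(1, 0, 2).reshape(d, -1)
        self._cache = (q, k, v, attn)
        return self.wo.forward(merged)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        d = dy.shape[0]
        dctx = self.wo.backward(dy).reshape(d, self.n_heads, self.d_k).transpose(1, 0, 2)
        dattn = dctx @ v.transpose(0, 2, 1)
        dv = attn.transpose(0, 2, 1) @ dctx
        # softmax backward (rows of attn sum to 1)
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.d_k)
        dq = dscores @ k
        dk = dscores.transpose(0, 2, 1) @ q
        merge = lambda h: h.transpose(1, 0, 2).reshape(d, -1)
        dx = self.wq.backward(merge(dq))
        dx += self.wk.backward(merge(dk))
        dx += self.wv.backward(merge(dv))
        return dx

    def params(self):
        return self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()


class FeedForward:
    """Position-wise two-layer ReLU network."""

    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.lin1.forward(x)
        self._mask = h > 0
        return self.lin2.forward(h * self._mask)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.lin2.backward(dy) * self._mask
        return self.lin1.backward(dh)

    def params(self):
        return self.lin1.params() + self.lin2.params()


class EncoderLayer:
    """One residual block: LayerNorm(x + Attention(x)), then
    LayerNorm(x + FeedForward(x))."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x1 = self.ln1.forward(x + self.attn.forward(x))
        return self.ln2.forward(x1 + self.ffn.forward(x1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d1 = self.ln2.backward(dy)
        dx1 = d1 + self.ffn.backward(d1)
        d0 = self.ln1.backward(dx1)
        return d0 + self.attn.backward(d0)

    def params(self):
        return (self.attn.params() + self.ffn.params()
                + self.ln1.params() + self.ln2.params())


class PairwiseDecoder:
    """Single-layer decoder producing one logit per ordered variable pair.

    ``logit[i, j] = u^T tanh(W1 @ enc_i + W2 @ enc_j)`` with trainable
    W1, W2 of shape (d_h, d_n) and u of shape (d_h,).
    """

    def __init__(self, d_n: int, d_h: int, rng: np.random.Generator):
        self.W1 = Param(xavier_uniform(rng, d_h, d_n))
        self.W2 = Param(xavier_uniform(rng, d_h, d_n))
        self.u = Param(rng.uniform(-np.sqrt(3.0 / d_h), np.sqrt(3.0 / d_h), size=d_h))
        self._cache = None

    def forward(self, enc: np.ndarray) -> np.ndarray:
        a = enc @ self.W1.value.T                    # (d, d_h), row i -> W1 enc_i
        b = enc @ self.W2.value.T
        t = np.tanh(a[:, None, :] + b[None, :, :])   # (d, d, d_h)
        self._cache = (enc, t)
        return t @ self.u.value                      # (d, d)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        enc, t = self._cache
        self.u.grad += np.einsum("ijh,ij->h", t, dlogits)
        dh = dlogits[:, :, None] * self.u.value * (1.0 - t * t)
        da = dh.sum(axis=1)                          # (d, d_h)
        db = dh.sum(axis=0)
        self.W1.grad += da.T @ enc
        self.W2.grad += db.T @ enc
        return da @ self.W1.value + db @ self.W2.value

    def params(self):
        return [self.W1, self.W2, self.u]


class Critic:
    """Two-layer tanh feedforward reward predictor.

    Mean-pools the d encoder vectors to a single d_n vector and maps it
    to a scalar predicted reward.
    """

    def __init__(self, d_n: int, hidden: int, rng: np.random.Generator):
        self.lin1 = Linear(d_n, hidden, rng)
        self.lin2 = Linear(hidden, 1, rng)
        self._cache = None

    def forward(self, enc: np.ndarray) -> float:
        x = enc.mean(axis=0, keepdims=True)          # (1, d_n)
        h = np.tanh(self.lin1.forward(x))
        self._cache = (h, enc.shape[0])
        return float(self.lin2.forward(h)[0, 0])

    def backward(self, dy: float) -> None:
        h, _ = self._cache
        dh = self.lin2.backward(np.array([[dy]])) * (1.0 - h * h)
        self.lin1.backward(dh)

    def params(self):
        return self.lin1.params() + self.lin2.params()


class Adam:
    """The Adam update rule."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
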