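"""Minimal reverse-mode automatic differentiation and transformer layers.

Everything is built on numpy arrays. A :class:`Tensor` records the operation
graph; :meth:`Tensor.backward` runs reverse-mode accumulation in topological
order. Only the operations the sequencing model needs are provided: broadcast
add/multiply, (batched) matmul, relu, reshape/transpose, embedding lookup,
layer normalization, softmax, and a fused softmax cross-entropy loss with an
ignore index for padding.

Gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sum_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    n_extra = grad.ndim - len(shape)
    if n_extra > 0:
        grad = grad.sum(axis=tuple(range(n_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(
            np.ones_like(self.data) if grad is None else np.asarray(grad)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_sum_to(g, a.data.shape))
        b._accumulate(_sum_to(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_sum_to(g * b.data, a.data.shape))
        b._accumulate(_sum_to(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(_sum_to(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        b._accumulate(_sum_to(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    return _make(data, (a, b), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat_seq(a, b) -> Tensor:
    """Concatenate two tensors along axis 1 (sequence dimension)."""
    a, b = as_tensor(a), as_tensor(b)
    na = a.data.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accumulate(g[:, :na])
        b._accumulate(g[:, na:])

    return _make(data, (a, b), backward)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    ids = np.asarray(ids)

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(full)

    return _make(table.data[ids], (table,), backward)


def layer_norm(x, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    x = as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    data = gamma.data * xhat + beta.data

    def backward(g):
        reduce_axes = tuple(range(g.ndim - 1))
        gamma._accumulate((g * xhat).sum(axis=reduce_axes))
        beta._accumulate(g.sum(axis=reduce_axes))
        dxhat = g * gamma.data
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        x._accumulate(inv_std * (dxhat - m1 - xhat * m2))

    return _make(data, (x, gamma, beta), backward)


def softmax(x, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))

    return _make(s, (x,), backward)


def log_softmax_data(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain-ndarray log-softmax (inference paths, no gradient)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def cross_entropy(logits, labels: np.ndarray, ignore_index: int = -1) -> Tensor:
    """Mean cross-entropy over non-ignored positions.

    ``logits``: (..., V); ``labels``: integer array matching the leading
    shape, with ``ignore_index`` marking padding positions.
    """
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    flat = logits.data.reshape(-1, logits.data.shape[-1])
    lab = labels.reshape(-1)
    valid = lab != ignore_index
    n_valid = max(int(valid.sum()), 1)
    safe_lab = np.where(valid, lab, 0)

    logp = log_softmax_data(flat)
    nll = -logp[np.arange(flat.shape[0]), safe_lab]
    loss = float((nll * valid).sum() / n_valid)

    def backward(g):
        p = np.exp(logp)
        p[np.arange(flat.shape[0]), safe_lab] -= 1.0
        p *= (valid / n_valid)[:, None] * g
        logits._accumulate(p.reshape(logits.data.shape).astype(logits.data.dtype))

    return _make(np.asarray(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Layers


class Module:
    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]


def _xavier(rng: np.random.Generator, d_in: int, d_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out)).astype(dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Tensor(_xavier(rng, d_in, d_out, dtype), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return add(matmul(x, self.W), self.b)


class EmbeddingTable(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = Tensor(
            (0.02 * rng.standard_normal((n, d))).astype(dtype), requires_grad=True
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, dtype=np.float32):
        self.gamma = Tensor(np.ones(d, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=dtype), requires_grad=True)

    def __call__(self, x) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class MultiHeadAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator, dtype=np.float32):
        if d % n_heads:
            raise ValueError("embedding dimension must be divisible by head count")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.wq = Linear(d, d, rng, dtype)
        self.wk = Linear(d, d, rng, dtype)
        self.wv = Linear(d, d, rng, dtype)
        self.wo = Linear(d, d, rng, dtype)

    def __call__(self, q_in, kv_in, mask: np.ndarray | None = None) -> Tensor:
        B, Tq, d = q_in.shape
        Tk = kv_in.shape[1]
        h, dh = self.n_heads, self.d_head

        def split(x, T):
            return transpose(reshape(x, (B, T, h, dh)), (0, 2, 1, 3))

        q = split(self.wq(q_in), Tq)
        k = split(self.wk(kv_in), Tk)
        v = split(self.wv(kv_in), Tk)
        scores = scale(matmul(q, transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        if mask is not None:
            scores = add(scores, Tensor(mask))
        attn = softmax(scores, axis=-1)
        ctx = matmul(attn, v)  # (B, h, Tq, dh)
        ctx = reshape(transpose(ctx, (0, 2, 1, 3)), (B, Tq, d))
        return self.wo(ctx)


class FeedForward(Module):
    def __init__(self, d: int, d_ff: int, rng: np.random.Generator, dtype=np.float32):
        self.lin1 = Linear(d, d_ff, rng, dtype)
        self.lin2 = Linear(d_ff, d, rng, dtype)

    def __call__(self, x) -> Tensor:
        return self.lin2(relu(self.lin1(x)))


class EncoderLayer(Module):
    """Transformer encoder layer (self-attention + feed-forward).

    ``norm_first`` selects the pre-norm residual arrangement, which trains
    stably at higher learning rates; the default is the classic post-norm
    layout."""

    def __init__(self, d, n_heads, d_ff, rng, dtype=np.float32, norm_first=False):
        self.attn = MultiHeadAttention(d, n_heads, rng, dtype)
        self.norm1 = LayerNorm(d, dtype)
        self.ffn = FeedForward(d, d_ff, rng, dtype)
        self.norm2 = LayerNorm(d, dtype)
        self.norm_first = norm_first

    def __call__(self, x, key_mask: np.ndarray | None = None) -> Tensor:
        if self.norm_first:
            h = self.norm1(x)
            x = add(x, self.attn(h, h, key_mask))
            return add(x, self.ffn(self.norm2(x)))
        x = self.norm1(add(x, self.attn(x, x, key_mask)))
        return self.norm2(add(x, self.ffn(x)))


class DecoderLayer(Module):
    """Decoder layer: causal self-attention, cross-attention, feed-forward;
    pre- or post-norm residuals as for :class:`EncoderLayer`."""

    def __init__(self, d, n_heads, d_ff, rng, dtype=np.float32, norm_first=False):
        self.self_attn = MultiHeadAttention(d, n_heads, rng, dtype)
        self.norm1 = LayerNorm(d, dtype)
        self.cross_attn = MultiHeadAttention(d, n_heads, rng, dtype)
        self.norm2 = LayerNorm(d, dtype)
        self.ffn = FeedForward(d, d_ff, rng, dtype)
        self.norm3 = LayerNorm(d, dtype)
        self.norm_first = norm_first

    def __call__(self, x, memory, causal_mask, memory_mask) -> Tensor:
        if self.norm_first:
            h = self.norm1(x)
            x = add(x, self.self_attn(h, h, causal_mask))
            x = add(x, self.cross_attn(self.norm2(x), memory, memory_mask))
            return add(x, self.ffn(self.norm3(x)))
        x = self.norm1(add(x, self.self_attn(x, x, causal_mask)))
        x = self.norm2(add(x, self.cross_attn(x, memory, memory_mask)))
        return self.norm3(add(x, self.ffn(x)))


class AdamW:
    """Adam with decoupled weight decay; the learning rate is set per step
    by the external schedule."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.98), eps=1e-9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
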