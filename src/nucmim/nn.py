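"""Minimal numpy neural-network layers with explicit forward/backward passes.

Everything downstream (the masked autoencoder, fine-tuning heads) is built
from these pieces: Linear, LayerNorm, GELU, multi-head self-attention,
pre-norm transformer blocks, and an AdamW optimizer. Each layer caches what
its backward pass needs during forward; ``backward(dout)`` accumulates
parameter gradients in ``p.grad`` and returns the gradient w.r.t. the input.

Shapes follow the (batch, tokens, features) convention throughout.
"""

from __future__ import annotations

import numpy as np

# Compute dtype for all layers. float32 keeps desk-scale training fast;
# switch to float64 (before constructing a model) for finite-difference
# gradient verification.
DTYPE = np.float32

_TANH_C = np.sqrt(2.0 / np.pi)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """y = x @ W.T + b over the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str = "linear"):
        # truncated-normal-free init: scaled Gaussian, as in common ViT code
        std = (2.0 / (d_in + d_out)) ** 0.5
        self.W = Param(rng.normal(0.0, std, size=(d_out, d_in)), f"{name}.W")
        self.b = Param(np.zeros(d_out), f"{name}.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        d_in = self.W.value.shape[1]
        y = x.reshape(-1, d_in) @ self.W.value.T + self.b.value
        return y.reshape(*x.shape[:-1], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        d_in, d_out = self.W.value.shape[1], self.W.value.shape[0]
        x2 = x.reshape(-1, d_in)
        g2 = dout.reshape(-1, d_out)
        self.W.grad += g2.T @ x2
        self.b.grad += g2.sum(axis=0)
        return (g2 @ self.W.value).reshape(x.shape)


class LayerNorm(Module):
    """Layer normalization over the last axis with learnable scale/shift."""

    def __init__(self, d: int, eps: float = 1e-6, name: str = "ln"):
        self.gamma = Param(np.ones(d), f"{name}.gamma")
        self.beta = Param(np.zeros(d), f"{name}.beta")
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        d = xhat.shape[-1]
        self.gamma.grad += (dout * xhat).reshape(-1, d).sum(axis=0)
        self.beta.grad += dout.reshape(-1, d).sum(axis=0)
        dxhat = dout * self.gamma.value
        # standard layernorm backward
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


def _gelu_tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(_TANH_C * (x + 0.044715 * (x * x * x)))


def gelu(x: np.ndarray) -> np.ndarray:
    """GELU, tanh approximation (the form common in ViT implementations)."""
    return 0.5 * x * (1.0 + _gelu_tanh(x))


def gelu_grad(x: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """d gelu/dx; pass the cached tanh term ``t`` to avoid recomputing it."""
    if t is None:
        t = _gelu_tanh(x)
    sech2 = 1.0 - t * t
    return 0.5 * (1.0 + t) + 0.5 * x * sech2 * _TANH_C * (1.0 + 0.134145 * (x * x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard multi-head self-attention; retains attention probabilities
    (averaged over nothing — per head) for interpretability rollout."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator, name: str = "attn"):
        if d % heads != 0:
            raise ValueError(f"hidden size {d} not divisible by heads {heads}")
        self.d = d
        self.heads = heads
        self.dh = d // heads
        self.qkv = Linear(d, 3 * d, rng, f"{name}.qkv")
        self.proj = Linear(d, d, rng, f"{name}.proj")
        self.attn_probs: np.ndarray | None = None  # (B, heads, T, T)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, d = x.shape
        h, dh = self.heads, self.dh
        qkv = self.qkv.forward(x)  # (B, T, 3d)
        qkv = qkv.reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)  # (B, h, T, T)
        P = softmax(scores, axis=-1)
        self.attn_probs = P
        out = P @ v  # (B, h, T, dh)
        out2 = out.transpose(0, 2, 1, 3).reshape(B, T, d)
        y = self.proj.forward(out2)
        self._cache = (q, k, v, P)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, P = self._cache
        B, h, T, dh = q.shape
        d = self.d
        dout2 = self.proj.backward(dout)  # (B, T, d)
        dattn_out = dout2.reshape(B, T, h, dh).transpose(0, 2, 1, 3)  # (B, h, T, dh)
        dP = dattn_out @ v.transpose(0, 1, 3, 2)  # (B, h, T, T)
        dv = P.transpose(0, 1, 3, 2) @ dattn_out
        # softmax backward (rows)
        dscores = P * (dP - (dP * P).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.stack([dq, dk, dv])  # (3, B, h, T, dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(B, T, 3 * d)
        return self.qkv.backward(dqkv)


class MLP(Module):
    """Two-layer feed-forward block with GELU, hidden width mult*d."""

    def __init__(self, d: int, rng: np.random.Generator, mult: int = 4, name: str = "mlp"):
        self.fc1 = Linear(d, mult * d, rng, f"{name}.fc1")
        self.fc2 = Linear(mult * d, d, rng, f"{name}.fc2")
        self._pre: np.ndarray | None = None
        self._tanh: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pre = self.fc1.forward(x)
        t = _gelu_tanh(pre)
        self._pre, self._tanh = pre, t
        return self.fc2.forward(0.5 * pre * (1.0 + t))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dout)
        return self.fc1.backward(dh * gelu_grad(self._pre, self._tanh))


class TransformerBlock(Module):
    """Pre-norm block: x + attn(ln1(x)); then x + mlp(ln2(x))."""

    def __init__(self, d: int, heads: int, rng: np.random.Generator, name: str = "block"):
        self.ln1 = LayerNorm(d, name=f"{name}.ln1")
        self.attn = MultiHeadSelfAttention(d, heads, rng, f"{name}.attn")
        self.ln2 = LayerNorm(d, name=f"{name}.ln2")
        self.mlp = MLP(d, rng, name=f"{name}.mlp")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x + self.attn.forward(self.ln1.forward(x))
        x = x + self.mlp.forward(self.ln2.forward(x))
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout + self.ln2.backward(self.mlp.backward(dout))
        dx = dx + self.ln1.backward(self.attn.backward(dx))
        return dx


class Transformer(Module):
    """A stack of pre-norm blocks followed by a final LayerNorm."""

    def __init__(self, d: int, depth: int, heads: int, rng: np.random.Generator, name: str = "tf"):
        self.blocks = [TransformerBlock(d, heads, rng, f"{name}.b{i}") for i in range(depth)]
        self.norm = LayerNorm(d, name=f"{name}.norm")

    def forward(self, x: np.ndarray) -> np.ndarray:
        for blk in self.blocks:
            x = blk.forward(x)
        return self.norm.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.norm.backward(dout)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        return dx

    @property
    def attention_stack(self) -> list[np.ndarray]:
        """Per-layer attention probabilities from the last forward pass."""
        return [blk.attn.attn_probs for blk in self.blocks]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / b1t
            vhat = v / b2t
            p.value -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.value)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
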