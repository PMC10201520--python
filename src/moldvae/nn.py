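"""Neural-network layers and the Adam optimizer on top of `moldvae.autograd`.

Transformer layers use the pre-norm layout (LayerNorm before each
attention/FF sublayer, residual around it) with GeLU activations; pre-norm
stacks stay stable at larger learning rates, which matters for the small
CPU-scale runs this package targets.
All parameter initialization is driven by an explicit `numpy.random.Generator`
so model construction is fully reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, embedding

NEG_INF = -1e9  # additive attention-mask value


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            full = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{full}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng, d_in, d_out)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), (n_tokens, d)),
                             requires_grad=True)

    def forward(self, ids) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return self.gamma * (centered / (var + self.eps).sqrt()) + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * keep


class Conv1d(Module):
    """1-D convolution over (batch, length, channels) sequences.

    `causal=True` pads on the left only, so output position i never sees
    input positions > i — required on the autoregressive decoder path.
    `causal=False` uses symmetric same-padding.  Kernel size must be odd.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, causal: bool = False):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        self.causal = causal
        self.weight = _param(rng, kernel, c_in, c_out,
                             scale=1.0 / np.sqrt(kernel * c_in))
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        k = self.kernel
        if self.causal:
            pads = (k - 1, 0)
        else:
            pads = (k // 2, k // 2)
        xp = x.pad(((0, 0), pads, (0, 0)))
        out = None
        for j in range(k):
            term = xp[:, j:j + L, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class Highway(Module):
    """Gated skip layer: y = t * gelu(H x) + (1 - t) * x, t = sigmoid(T x).

    The transform-gate bias starts negative so the layer is near-identity at
    initialization, the standard trick that keeps early training stable.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        super().__init__()
        self.transform = Linear(d, d, rng)
        self.gate = Linear(d, d, rng)
        self.gate.bias.data[:] = -1.0

    def forward(self, x: Tensor) -> Tensor:
        t = self.gate(x).sigmoid()
        return t * self.transform(x).gelu() + (1.0 - t) * x


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

    def forward(self, q_in: Tensor, k_in: Tensor, v_in: Tensor,
                mask: np.ndarray | None = None) -> Tensor:
        B, Lq, _ = q_in.shape
        Lk = k_in.shape[1]
        q = self._split(self.wq(q_in), B, Lq)
        k = self._split(self.wk(k_in), B, Lk)
        v = self._split(self.wv(v_in), B, Lk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        if mask is not None:
            scores = scores + mask  # additive: 0 keep, NEG_INF drop
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Lq, self.h * self.dh)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lin2(self.drop(self.lin1(x).gelu()))


class TransformerEncoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng, dropout)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        y = self.norm1(x)
        x = x + self.drop1(self.attn(y, y, y, mask))
        return x + self.drop2(self.ff(self.norm2(x)))


class TransformerDecoderLayer(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 dropout: float, rng: np.random.Generator):
        super().__init__()
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff = FeedForward(d_model, d_ff, rng, dropout)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)
        self.drop3 = Dropout(dropout, rng)

    def forward(self, x: Tensor, memory: Tensor,
                self_mask: np.ndarray | None = None,
                cross_mask: np.ndarray | None = None) -> Tensor:
        y = self.norm1(x)
        x = x + self.drop1(self.self_attn(y, y, y, self_mask))
        x = x + self.drop2(self.cross_attn(self.norm2(x), memory, memory,
                                           cross_mask))
        return x + self.drop3(self.ff(self.norm3(x)))


def causal_mask(L: int) -> np.ndarray:
    """(L, L) additive mask forbidding attention to future positions."""
    return np.where(np.tril(np.ones((L, L), dtype=bool)), 0.0, NEG_INF)


def padding_mask(valid: np.ndarray) -> np.ndarray:
    """(B, 1, 1, L) additive mask from per-position validity flags."""
    return np.where(valid[:, None, None, :], 0.0, NEG_INF)


class Adam:
    """Adam with a mutable learning rate (for MultiStep schedules)."""

    def __init__(self, params, lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
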