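"""Sequence frontend: embedding with rescaled positional encoding, a
convolution + highway preprocessing block, and fixed-length pooling.

The embedding combination is

    x_tilde = sqrt(d_emb) * x_emb + pe / sqrt(d_emb),

which rebalances a trainable embedding against the fixed sinusoidal
positional code.  The pooling step compresses a variable-length encoder
output u (length L, width D) into exactly 16 vectors: u_0, the global mean,
and the means over the remainder classes S^m_n = {u_i : i == m (mod n)} for
n = 2..5 — a fixed-size summary that preserves coarse positional structure.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import Conv1d, Highway, Module

N_POOL_VECTORS = 16  # index-0 + global mean + (2+3+4+5) remainder classes
POOL_CLASSES = [(n, m) for n in range(2, 6) for m in range(n)]


def sinusoidal_pe(max_len: int, d: int) -> np.ndarray:
    """Standard transformer sinusoidal positional encoding, shape (max_len, d)."""
    pos = np.arange(max_len)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.empty((max_len, d))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


class Frontend(Module):
    """Embedding + positional rescaling, then causal-or-same conv + highway."""

    def __init__(self, vocab_size: int, d_emb: int, d_model: int,
                 kernel: int, max_len: int, rng: np.random.Generator,
                 causal: bool = False):
        super().__init__()
        self.d_emb = d_emb
        self.max_len = max_len
        self.emb = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_emb),
                                     (vocab_size, d_emb)), requires_grad=True)
        self.pe = sinusoidal_pe(max_len, d_emb)  # fixed, not trained
        self.conv = Conv1d(d_emb, d_model, kernel, rng, causal=causal)
        self.highway = Highway(d_model, rng)

    def embed_and_position(self, ids: np.ndarray) -> Tensor:
        """sqrt(d_emb) * embedding + pe / sqrt(d_emb), shape (B, L, d_emb)."""
        ids = np.asarray(ids, dtype=np.int64)
        if ids.max(initial=0) >= self.emb.shape[0] or ids.min(initial=0) < 0:
            raise IndexError("token id out of vocabulary range")
        if ids.shape[-1] > self.max_len:
            raise ValueError(f"sequence length {ids.shape[-1]} exceeds "
                             f"max_len {self.max_len}")
        from .autograd import embedding
        scale = np.sqrt(self.d_emb)
        return embedding(self.emb, ids) * scale + self.pe[: ids.shape[-1]] / scale

    def forward(self, ids: np.ndarray) -> Tensor:
        return self.highway(self.conv(self.embed_and_position(ids)))


def pool_weights(valid: np.ndarray) -> np.ndarray:
    """(B, 16, L) averaging weights implementing the fixed-length pooling.

    Row 0 selects u_0, row 1 is the mean over valid positions, rows 2..15 are
    means over remainder classes restricted to valid positions.  A class with
    no valid member falls back to the global mean.
    """
    valid = np.asarray(valid, dtype=bool)
    B, L = valid.shape
    if L < 1 or not valid[:, 0].all():
        raise ValueError("every sequence must have at least one valid position")
    W = np.zeros((B, N_POOL_VECTORS, L))
    W[:, 0, 0] = 1.0
    counts = valid.sum(axis=1)  # >= 1 by the check above
    gmean = valid / counts[:, None]
    W[:, 1, :] = gmean
    idx = np.arange(L)
    for row, (n, m) in enumerate(POOL_CLASSES, start=2):
        member = valid & (idx[None, :] % n == m)
        c = member.sum(axis=1)
        nonempty = c > 0
        W[nonempty, row, :] = member[nonempty] / c[nonempty, None]
        W[~nonempty, row, :] = gmean[~nonempty]
    return W


def fixed_length_pool(u: Tensor, valid: np.ndarray | None = None) -> Tensor:
    """Pool (B, L, D) [or (L, D)] encoder output into (B, 16, D)."""
    single = u.ndim == 2
    if single:
        u = u.reshape(1, *u.shape)
    B, L, _ = u.shape
    if L == 0:
        raise ValueError("cannot pool an empty sequence")
    if valid is None:
        valid = np.ones((B, L), dtype=bool)
    out = Tensor(pool_weights(valid)) @ u
    return out[0] if single else out
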