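"""The discrete variational autoencoder over SMILES sequences.

Encoder: frontend (embedding -> same-padded conv -> highway) -> transformer
encoder stack -> fixed-length pooling -> posterior head producing 256
Bernoulli probabilities q.

Decoder: the relaxed latent zeta is projected to 16 memory vectors that the
transformer decoder stack cross-attends to; decoder-side tokens pass through
a *causally* padded frontend so that, both teacher-forced and autoregressive,
position i never sees tokens > i.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import seeding
from .autograd import Tensor
from .frontend import N_POOL_VECTORS, Frontend, fixed_length_pool
from .nn import (LayerNorm, Linear, Module, TransformerDecoderLayer,
                 TransformerEncoderLayer, causal_mask, padding_mask)
from .rbm import RBM, PosteriorHead, _spike_exp_icdf
from .smiles import Vocabulary


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults: the full-scale model)."""

    vocab_size: int
    d_emb: int = 32
    d_model: int = 160
    d_ff: int = 320
    n_heads: int = 10
    n_encoder_layers: int = 5
    n_decoder_layers: int = 5
    kernel: int = 5
    dropout: float = 0.1
    latent_a: int = 128
    latent_b: int = 128
    n_memory: int = 16
    max_len: int = 200
    beta_se: float = 8.0
    latent_type: str = "rbm"          # "rbm" | "gaussian"
    posterior_gain: float = 1.0       # pre-sigmoid logit gain of the posterior head
    latent_broadcast: bool = False    # also add a zeta projection to every decoder position
    gaussian_units: int = 64          # 32+32 for the continuous baseline

    @property
    def n_latent(self) -> int:
        if self.latent_type == "gaussian":
            return self.gaussian_units
        return self.latent_a + self.latent_b

    @classmethod
    def reduced(cls, vocab_size: int, **overrides) -> "ModelConfig":
        """Desk-scale preset: 16+16 RBM, 2+2 transformer layers, no dropout.

        Used for overfit/memorization experiments on fixture corpora where
        the model must fit tens of molecules on a single CPU.
        """
        base = cls(vocab_size=vocab_size, d_emb=16, d_model=64, d_ff=128,
                   n_heads=4, n_encoder_layers=2, n_decoder_layers=2,
                   dropout=0.0, latent_a=16, latent_b=16, beta_se=24.0,
                   posterior_gain=8.0, latent_broadcast=True)
        return replace(base, **overrides)

    @classmethod
    def continuous(cls, vocab_size: int, **overrides) -> "ModelConfig":
        """The smaller continuous-latent baseline (32+32 Gaussian units)."""
        base = cls(vocab_size=vocab_size, d_model=100, d_ff=200,
                   n_heads=10, n_encoder_layers=2, n_decoder_layers=2,
                   latent_type="gaussian", gaussian_units=64)
        return replace(base, **overrides)


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.frontend = Frontend(cfg.vocab_size, cfg.d_emb, cfg.d_model,
                                 cfg.kernel, cfg.max_len, rng, causal=False)
        self.layers = [TransformerEncoderLayer(cfg.d_model, cfg.n_heads,
                                               cfg.d_ff, cfg.dropout, rng)
                       for _ in range(cfg.n_encoder_layers)]
        self.final_norm = LayerNorm(cfg.d_model)
        d_pool = N_POOL_VECTORS * cfg.d_model
        if cfg.latent_type == "gaussian":
            self.head = Linear(d_pool, 2 * cfg.gaussian_units, rng)
        else:
            self.head = PosteriorHead(d_pool, cfg.n_latent, rng,
                                      gain=cfg.posterior_gain)

    def forward(self, ids: np.ndarray, valid: np.ndarray) -> Tensor:
        x = self.frontend(ids)
        mask = padding_mask(valid)
        for layer in self.layers:
            x = layer(x, mask)
        x = self.final_norm(x)
        pooled = fixed_length_pool(x, valid)
        B = pooled.shape[0]
        return self.head(pooled.reshape(B, -1))


class Decoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.frontend = Frontend(cfg.vocab_size, cfg.d_emb, cfg.d_model,
                                 cfg.kernel, cfg.max_len + 2, rng, causal=True)
        self.latent_proj = Linear(cfg.n_latent, cfg.n_memory * cfg.d_model, rng)
        self.broadcast_proj = (Linear(cfg.n_latent, cfg.d_model, rng)
                               if cfg.latent_broadcast else None)
        self.layers = [TransformerDecoderLayer(cfg.d_model, cfg.n_heads,
                                               cfg.d_ff, cfg.dropout, rng)
                       for _ in range(cfg.n_decoder_layers)]
        self.final_norm = LayerNorm(cfg.d_model)
        self.out = Linear(cfg.d_model, cfg.vocab_size, rng)

    def memory(self, zeta: Tensor) -> Tensor:
        B = zeta.shape[0]
        return self.latent_proj(zeta).reshape(
            B, self.cfg.n_memory, self.cfg.d_model)

    def forward(self, zeta: Tensor, ids: np.ndarray,
                valid: np.ndarray | None = None) -> Tensor:
        """Teacher-forced logits: (B, L, vocab); position i sees ids[:, :i+1]."""
        B, L = np.asarray(ids).shape
        mem = self.memory(zeta)
        x = self.frontend(ids)
        if self.broadcast_proj is not None:
            x = x + self.broadcast_proj(zeta).reshape(B, 1, self.cfg.d_model)
        mask = causal_mask(L)[None, None]
        if valid is not None:
            mask = mask + padding_mask(valid)
        for layer in self.layers:
            x = layer(x, mem, self_mask=mask)
        return self.out(self.final_norm(x))


class DVAE(Module):
    """Full model: encoder, RBM (or Gaussian) latent, decoder."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.vocab = vocab
        if cfg.vocab_size != len(vocab):
            raise ValueError("config vocab_size disagrees with vocabulary")
        rng = seeding.stream(seed, "model_init")
        self.encoder = Encoder(cfg, rng)
        self.decoder = Decoder(cfg, rng)
        self.rbm = (RBM(cfg.latent_a, cfg.latent_b, rng)
                    if cfg.latent_type == "rbm" else None)

    # ---- encoding --------------------------------------------------------
    def encode(self, ids: np.ndarray, valid: np.ndarray) -> Tensor:
        """Posterior parameters: Bernoulli q (rbm) or [mu | logvar] (gaussian)."""
        return self.encoder(ids, valid)

    def encode_smiles(self, smiles: str) -> Tensor:
        ids = np.array([self.vocab.encode(smiles, add_special=False)])
        return self.encode(ids, np.ones(ids.shape, dtype=bool))

    # ---- decoding --------------------------------------------------------
    def decode_train(self, zeta: Tensor, ids: np.ndarray,
                     valid: np.ndarray | None = None) -> Tensor:
        return self.decoder(zeta, ids, valid)

    def decode_generate(self, zeta, rng: np.random.Generator | None = None,
                        mode: str = "sample",
                        max_len: int | None = None) -> list[int]:
        """Autoregressive decoding from BOS; returns token ids (EOS included
        when produced).  `mode` is "sample" (softmax, T=1) or "greedy"."""
        if mode not in ("sample", "greedy"):
            raise ValueError(f"unknown decoding mode {mode!r}")
        if mode == "sample" and rng is None:
            raise ValueError("sample mode needs an rng")
        if max_len is None:
            max_len = self.cfg.max_len
        zeta = zeta if isinstance(zeta, Tensor) else Tensor(zeta)
        if zeta.ndim == 1:
            zeta = zeta.reshape(1, -1)
        was_training = self.training
        self.eval()
        try:
            ids = [self.vocab.bos_id]
            out: list[int] = []
            while len(out) < max_len:
                logits = self.decoder(zeta, np.array([ids]))
                p = logits[0, -1, :].softmax().data
                if mode == "greedy":
                    nxt = int(np.argmax(p))
                else:
                    nxt = int(rng.choice(len(p), p=p / p.sum()))
                out.append(nxt)
                if nxt == self.vocab.eos_id:
                    break
                ids.append(nxt)
            return out
        finally:
            self.train(was_training)

    # ---- latent sampling helpers ----------------------------------------
    def sample_z(self, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return (rng.random(q.shape) < q).astype(np.float64)

    def zeta_from_z(self, z: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
        """Relaxed code for a fixed binary z: spike-exp with q = z."""
        rho = rng.random(z.shape)
        return _spike_exp_icdf(np.asarray(z, dtype=np.float64), rho,
                               self.cfg.beta_se)

    # ---- persistence -----------------------------------------------------
    def save(self, path):
        meta = {"config": asdict(self.cfg), "vocab": list(self.vocab.tokens),
                "format_version": 1}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.state_dict())

    @classmethod
    def load(cls, path) -> "DVAE":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode())
            state = {k: npz[k] for k in npz.files if k != "__meta__"}
        cfg = ModelConfig(**meta["config"])
        model = cls(cfg, Vocabulary(tuple(meta["vocab"])))
        model.load_state_dict(state)
        return model


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Padded id arrays for one training batch.

    enc_ids / enc_valid: chemical tokens only (encoder input).
    dec_in: BOS-shifted ids, dec_target: ids followed by EOS; dec_valid masks
    real target positions (loss and attention ignore padding).
    """

    enc_ids: np.ndarray
    enc_valid: np.ndarray
    dec_in: np.ndarray
    dec_target: np.ndarray
    dec_valid: np.ndarray
    smiles: list[str] = field(default_factory=list)


def make_batch(molecules: list[str], vocab: Vocabulary) -> Batch:
    seqs = [vocab.encode(s, add_special=False) for s in molecules]
    B = len(seqs)
    L = max(len(s) for s in seqs)
    enc_ids = np.full((B, L), vocab.pad_id, dtype=np.int64)
    enc_valid = np.zeros((B, L), dtype=bool)
    dec_in = np.full((B, L + 1), vocab.pad_id, dtype=np.int64)
    dec_target = np.full((B, L + 1), vocab.pad_id, dtype=np.int64)
    dec_valid = np.zeros((B, L + 1), dtype=bool)
    for i, s in enumerate(seqs):
        n = len(s)
        enc_ids[i, :n] = s
        enc_valid[i, :n] = True
        dec_in[i, 0] = vocab.bos_id
        dec_in[i, 1:n + 1] = s
        dec_target[i, :n] = s
        dec_target[i, n] = vocab.eos_id
        dec_valid[i, :n + 1] = True
    return Batch(enc_ids, enc_valid, dec_in, dec_target, dec_valid,
                 smiles=list(molecules))
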