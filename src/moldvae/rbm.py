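"""Restricted Boltzmann Machine latent prior and its training machinery.

The RBM is bipartite: two layers of binary units with biases h over all
units and couplings W only between layers.  With energy

    E(z) = sum_l z_l h_l + sum_{l<m} W_lm z_l z_m,   p(z) = exp(-E(z)) / Z,

each layer is conditionally independent given the other, so block Gibbs
sampling alternates  a ~ Bernoulli(sigmoid(-(h_a + W b)))  and symmetrically
for b.  The effective temperature is fixed at 1.

Provided here:

* exact log-partition by enumeration (small models; the test oracle),
* block Gibbs / persistent contrastive divergence (PCD) sampling,
* annealed importance sampling (AIS) for log Z at evaluation time,
* the spike-and-exponential relaxation that turns binary latents into
  reparameterizable continuous ones,
* the posterior head (pooled code -> Bernoulli probabilities q),
* the KL value/gradient split used by the ELBO, and
* a pluggable prior-sampler backend registry (classical Gibbs by default,
  with a stub obeying the same contract an annealer adapter would).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, where
from .nn import Linear, Module

ENUM_LIMIT = 24  # max total units for exact enumeration


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class RBM(Module):
    """Bipartite RBM over n_a + n_b binary units."""

    def __init__(self, n_a: int, n_b: int, rng: np.random.Generator,
                 init_scale: float = 0.01):
        super().__init__()
        self.n_a, self.n_b = n_a, n_b
        self.h = Tensor(np.zeros(n_a + n_b), requires_grad=True)
        self.W = Tensor(rng.normal(0.0, init_scale, (n_a, n_b)),
                        requires_grad=True)

    @property
    def n_units(self) -> int:
        return self.n_a + self.n_b

    # ---- energy ----------------------------------------------------------
    def energy(self, z: np.ndarray) -> np.ndarray:
        """E(z) for binary (or relaxed) states, shape (..., N) -> (...,)."""
        z = np.asarray(z, dtype=np.float64)
        if z.shape[-1] != self.n_units:
            raise ValueError(f"state dimension {z.shape[-1]} != {self.n_units}")
        za, zb = z[..., : self.n_a], z[..., self.n_a:]
        return z @ self.h.data + np.einsum("...i,ij,...j->...",
                                           za, self.W.data, zb)

    def energy_t(self, zeta: Tensor) -> Tensor:
        """Differentiable energy of relaxed states, shape (B, N) -> (B,)."""
        za = zeta[:, : self.n_a]
        zb = zeta[:, self.n_a:]
        return (zeta * self.h).sum(axis=-1) + ((za @ self.W) * zb).sum(axis=-1)

    # ---- exact partition function ---------------------------------------
    def log_partition_exact(self) -> float:
        """log Z by summing exp(-E) over all 2^N states (N <= 24 only)."""
        if self.n_units > ENUM_LIMIT:
            raise ValueError(
                f"{self.n_units} units is too large for enumeration; "
                "use ais_log_partition instead")
        ha, hb = self.h.data[: self.n_a], self.h.data[self.n_a:]
        states_a = enumerate_states(self.n_a)
        # sum over the b layer analytically given each a state
        field_b = hb + states_a @ self.W.data           # (2^n_a, n_b)
        log_terms = -states_a @ ha + np.sum(
            np.logaddexp(0.0, -field_b), axis=1)
        from scipy.special import logsumexp
        return float(logsumexp(log_terms))

    # ---- sampling --------------------------------------------------------
    def gibbs_block_update(self, z: np.ndarray, rng: np.random.Generator,
                           beta: float = 1.0) -> np.ndarray:
        """One block sweep: resample layer a given b, then b given the new a."""
        z = np.asarray(z, dtype=np.float64)
        ha, hb = self.h.data[: self.n_a], self.h.data[self.n_a:]
        zb = z[..., self.n_a:]
        pa = _sigmoid(-beta * (ha + zb @ self.W.data.T))
        za = (rng.random(pa.shape) < pa).astype(np.float64)
        pb = _sigmoid(-beta * (hb + za @ self.W.data))
        zb = (rng.random(pb.shape) < pb).astype(np.float64)
        return np.concatenate([za, zb], axis=-1)


def enumerate_states(n: int) -> np.ndarray:
    """All 2^n binary vectors, shape (2^n, n), lexicographic in bit order."""
    if n > ENUM_LIMIT:
        raise ValueError("too many units to enumerate")
    ints = np.arange(2 ** n)[:, None]
    return ((ints >> np.arange(n)[None, :]) & 1).astype(np.float64)


def exact_distribution(rbm: RBM) -> tuple[np.ndarray, np.ndarray]:
    """(states, probabilities) over the full state space of a small RBM."""
    states = enumerate_states(rbm.n_units)
    e = rbm.energy(states)
    w = np.exp(-(e - e.min()))
    return states, w / w.sum()


# ---------------------------------------------------------------------------
# Persistent contrastive divergence
# ---------------------------------------------------------------------------

@dataclass
class PCDState:
    """Persistent Gibbs chains for the negative phase."""

    chains: np.ndarray
    rng: np.random.Generator

    @classmethod
    def initialize(cls, rbm: RBM, n_chains: int,
                   rng: np.random.Generator) -> "PCDState":
        chains = (rng.random((n_chains, rbm.n_units)) < 0.5).astype(np.float64)
        return cls(chains=chains, rng=rng)


def pcd_sample(state: PCDState, rbm: RBM, k: int = 30) -> np.ndarray:
    """Advance the persistent chains k block-Gibbs steps; return the samples."""
    z = state.chains
    for _ in range(k):
        z = rbm.gibbs_block_update(z, state.rng)
    state.chains = z
    return z.copy()


# ---------------------------------------------------------------------------
# Annealed importance sampling
# ---------------------------------------------------------------------------

@dataclass
class AISResult:
    log_z: float
    log_weights: np.ndarray
    std_err: float


def ais_log_partition(rbm: RBM, rng: np.random.Generator,
                      n_intermediate: int = 10,
                      n_samples: int = 500) -> AISResult:
    """AIS estimate of log Z along a linear inverse-temperature path.

    The path interpolates p_beta(z) ~ exp(-beta E(z)) from the uniform base
    (beta = 0, log Z_0 = N log 2) to the target (beta = 1) through
    `n_intermediate` strictly intermediate distributions; the transition at
    each level is one block-Gibbs sweep at that beta.
    """
    N = rbm.n_units
    betas = np.linspace(0.0, 1.0, n_intermediate + 2)
    z = (rng.random((n_samples, N)) < 0.5).astype(np.float64)
    log_w = np.zeros(n_samples)
    for k in range(1, len(betas)):
        log_w += -(betas[k] - betas[k - 1]) * rbm.energy(z)
        z = rbm.gibbs_block_update(z, rng, beta=betas[k])
    m = log_w.max()
    w = np.exp(log_w - m)
    mean_w = w.mean()
    log_z = N * np.log(2.0) + m + np.log(mean_w)
    # delta-method standard error of log(mean w)
    std_err = float(w.std(ddof=1) / (mean_w * np.sqrt(n_samples)))
    return AISResult(log_z=float(log_z), log_weights=log_w, std_err=std_err)


# ---------------------------------------------------------------------------
# Spike-and-exponential relaxation
# ---------------------------------------------------------------------------

def spike_exp_sample(q: np.ndarray, beta_se: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample zeta ~ r(zeta | q): spike at 0 with mass 1-q, else a truncated
    exponential on [0, 1] with sharpness beta_se (non-differentiable form)."""
    if beta_se <= 0:
        raise ValueError("beta_se must be positive")
    q = np.asarray(q, dtype=np.float64)
    rho = rng.random(q.shape)
    return _spike_exp_icdf(q, rho, beta_se)


def _spike_exp_icdf(q: np.ndarray, rho: np.ndarray,
                    beta_se: float) -> np.ndarray:
    on = rho >= 1.0 - q
    qs = np.where(q > 0, q, 1.0)  # avoid 0/0 on the spike branch
    t = (rho - (1.0 - q)) / qs
    zeta = np.log1p(np.clip(t, 0.0, 1.0) * np.expm1(beta_se)) / beta_se
    return np.where(on, zeta, 0.0)


def spike_exp_reparam(q: Tensor, rho: np.ndarray, beta_se: float) -> Tensor:
    """Differentiable inverse-CDF transform of fixed uniforms rho.

    The spike indicator is treated as locally constant in q (the standard
    reparameterization of a mixed discrete-continuous distribution), so
    gradients flow only through the exponential branch.
    """
    eps = 1e-9  # keep the division well-defined when q saturates to 0/1
    qc = q * (1.0 - 2.0 * eps) + eps
    on = rho >= 1.0 - qc.data
    t = (Tensor(rho) - 1.0 + qc) / qc
    arg = 1.0 + where(on, t, 0.0) * float(np.expm1(beta_se))
    return where(on, arg.log() * (1.0 / beta_se), Tensor(np.zeros(q.shape)))


# ---------------------------------------------------------------------------
# Posterior head and KL machinery
# ---------------------------------------------------------------------------

class PosteriorHead(Module):
    """Affine map from the flattened pooled code to Bernoulli probabilities.

    `gain` scales the pre-sigmoid logits (weights are initialized 1/gain
    smaller, so initial outputs are unchanged).  A gain > 1 lets the head
    reach saturated probabilities in fewer Adam steps, which small-corpus
    overfit runs need for a reliable discrete code.
    """

    def __init__(self, d_in: int, n_latent: int, rng: np.random.Generator,
                 gain: float = 1.0):
        super().__init__()
        self.proj = Linear(d_in, n_latent, rng)
        self.proj.weight.data /= gain
        self.gain = float(gain)

    def forward(self, pooled_flat: Tensor) -> Tensor:
        return (self.proj(pooled_flat) * self.gain).sigmoid()


def bernoulli_entropy(q: Tensor, eps: float = 1e-12) -> Tensor:
    """Closed-form factorial Bernoulli entropy per batch row, shape (B,)."""
    # log factors use clipped constants: the value is exact to within eps and
    # the resulting gradient, logit(q), is the exact d(-H)/dq
    qc = Tensor(np.clip(q.data, eps, 1.0 - eps))
    h = -(q * qc.log() + (1.0 - q) * (1.0 - qc).log())
    return h.sum(axis=-1)


@dataclass
class KLTerm:
    """Sampled KL estimate plus the differentiable surrogate for gradients."""

    value: float                 # -H[q] + E_q[E] + log Z   (log Z from AIS)
    grad_objective: Tensor       # -H[q] + E(zeta) - mean E(z_PCD)
    positive_energy: float
    negative_energy: float
    entropy: float


def kl_term(q: Tensor, zeta: Tensor, rbm: RBM,
            pcd_samples: np.ndarray,
            log_z: float | None = None) -> KLTerm:
    """KL(q(z|x) || p(z)) estimate and its gradient surrogate.

    The reported value is  -H[q] + E_q[E_theta] + log Z, with E_q estimated
    on the relaxed samples zeta and log Z supplied by AIS (or exact
    enumeration); log Z never contributes gradients.  The gradient surrogate
    realizes the positive-phase-minus-negative-phase rule: the positive
    phase differentiates E(zeta) (gradients reach the encoder through the
    reparameterization), the negative phase differentiates the mean energy
    of the PCD samples, which are constants, so only RBM parameters feel it.
    """
    neg_entropy = -bernoulli_entropy(q).mean()
    pos = rbm.energy_t(zeta).mean()
    neg = rbm.energy_t(Tensor(pcd_samples)).mean()
    grad_obj = neg_entropy + pos - neg
    value = float(neg_entropy.data + pos.data)
    if log_z is not None:
        value += float(log_z)
    return KLTerm(value=value, grad_objective=grad_obj,
                  positive_energy=float(pos.data),
                  negative_energy=float(neg.data),
                  entropy=float(-neg_entropy.data))


# ---------------------------------------------------------------------------
# Prior-sampler backends
# ---------------------------------------------------------------------------

def gibbs_prior_sample(rbm: RBM, n: int, rng: np.random.Generator,
                       burn_in: int = 1000, thin: int = 10) -> np.ndarray:
    """Burn-in + thinned block-Gibbs chain; returns (n, N) binary samples."""
    z = (rng.random((1, rbm.n_units)) < 0.5).astype(np.float64)
    for _ in range(burn_in):
        z = rbm.gibbs_block_update(z, rng)
    out = np.empty((n, rbm.n_units))
    for i in range(n):
        for _ in range(thin):
            z = rbm.gibbs_block_update(z, rng)
        out[i] = z[0]
    return out


class AnnealerStub:
    """Prior-sampler obeying the hardware-adapter contract (params in,
    binary samples out) with an injectable sample source, so an actual
    annealer client can be slotted in without touching the model code."""

    def __init__(self, source=None):
        self.source = source

    def prime(self, samples: np.ndarray):
        self.source = np.asarray(samples, dtype=np.float64)
        return self

    def __call__(self, rbm: RBM, n: int,
                 rng: np.random.Generator) -> np.ndarray:
        if self.source is None:
            raise RuntimeError("annealer_stub backend has not been primed "
                               "with a sample source")
        if callable(self.source):
            return np.asarray(self.source(rbm, n, rng), dtype=np.float64)
        if len(self.source) < n:
            raise ValueError("annealer_stub primed with too few samples")
        return self.source[:n].copy()


SAMPLER_BACKENDS: dict[str, object] = {
    "gibbs": gibbs_prior_sample,
    "annealer_stub": AnnealerStub(),
}


def register_backend(name: str, fn) -> None:
    SAMPLER_BACKENDS[name] = fn


def prior_sample(rbm: RBM, n: int, rng: np.random.Generator,
                 backend: str = "gibbs", **kwargs) -> np.ndarray:
    """Draw n binary latent vectors from the RBM prior via a named backend."""
    try:
        fn = SAMPLER_BACKENDS[backend]
    except KeyError:
        raise KeyError(f"unknown sampler backend {backend!r}; "
                       f"registered: {sorted(SAMPLER_BACKENDS)}") from None
    return fn(rbm, n, rng, **kwargs)


# ---------------------------------------------------------------------------
# Continuous-latent baseline
# ---------------------------------------------------------------------------

def gaussian_latent(mu: Tensor, logvar: Tensor,
                    rng: np.random.Generator) -> tuple[Tensor, Tensor]:
    """Standard Gaussian reparameterization and closed-form KL to N(0, I).

    Returns (zeta, kl) with kl of shape (B,):
    KL = 0.5 * sum(mu^2 + exp(logvar) - 1 - logvar).
    """
    eps = rng.standard_normal(mu.shape)
    zeta = mu + (logvar * 0.5).exp() * Tensor(eps)
    kl = 0.5 * (mu * mu + logvar.exp() - 1.0 - logvar).sum(axis=-1)
    return zeta, kl
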