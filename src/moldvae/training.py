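"""Training engine: the beta-weighted ELBO, the MultiStep learning-rate
schedule, the epoch loop with per-epoch AIS evaluation, and the
reconstruction workflow.

The objective maximized is

    L = E_q[log p(x | zeta)] - beta * KL(q(z|x) || p(z)),   beta = 0.1,

minimized as  total = -reconstruction + beta * KL.  The reconstruction term
is token-level cross-entropy summed over non-pad positions and averaged over
molecules.  The KL gradient uses the positive-phase (relaxed samples) minus
negative-phase (PCD samples) rule; log Z enters the *reported* KL only,
estimated by AIS once per epoch.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import seeding
from .autograd import Tensor
from .model import DVAE, Batch, ModelConfig, make_batch
from .nn import Adam
from .rbm import (PCDState, ais_log_partition, gaussian_latent, kl_term,
                  pcd_sample, spike_exp_reparam)

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    `latent_warmup` is an optional curriculum for small-corpus runs: before
    the window the relaxed code is fed deterministically (zeta = q, beta = 0);
    across the window (given as fractions of the run) the stochastic
    spike-and-exponential samples and the KL weight are blended in linearly.
    Without it (the full-scale default) training is fully stochastic with
    beta applied from the first step.  `latent_draws` averages the loss over
    several relaxation draws per step to cut gradient variance;
    `ema_start_frac` switches on Polyak averaging of the weights for the
    tail of the run.
    """

    epochs: int = 300
    lr: float = 6e-5
    milestones: tuple[float, ...] = (0.5, 0.75, 0.95)
    lr_factor: float = 0.5
    constant_lr: bool = False
    batch_size: int = 32
    beta: float = 0.1
    pcd_steps: int = 30
    seed: int = 0
    backend: str = "gibbs"
    ais_intermediate: int = 10
    ais_samples: int = 500
    grad_clip: float | None = None
    checkpoint_epochs: tuple[int, ...] = ()
    eval_every: int = 1
    latent_warmup: tuple[float, float] | None = None
    latent_draws: int = 1
    ema_start_frac: float | None = None
    ema_decay: float = 0.995

    def __post_init__(self):
        if list(self.milestones) != sorted(set(self.milestones)) or any(
                not 0.0 < m < 1.0 for m in self.milestones):
            raise ValueError("milestones must be strictly increasing in (0,1)")
        if self.latent_warmup is not None:
            a, b = self.latent_warmup
            if not 0.0 <= a < b <= 1.0:
                raise ValueError("latent_warmup must satisfy 0 <= start < end <= 1")

    @classmethod
    def overfit(cls, epochs: int = 200, seed: int = 0,
                **overrides) -> "TrainConfig":
        """Desk-scale memorization preset (pairs with ModelConfig.reduced)."""
        base = dict(epochs=epochs, lr=1e-3, batch_size=4,
                    milestones=(0.55, 0.75, 0.9), seed=seed,
                    latent_warmup=(0.4, 0.7), latent_draws=2,
                    ema_start_frac=0.75)
        base.update(overrides)
        return cls(**base)

    def ramp_at(self, epoch: int) -> float:
        """Stochasticity/KL blend-in factor alpha in [0, 1] at `epoch`."""
        if self.latent_warmup is None:
            return 1.0
        a, b = (f * self.epochs for f in self.latent_warmup)
        return float(min(max((epoch - a) / max(b - a, 1e-9), 0.0), 1.0))


def lr_at(epoch: int, config: TrainConfig) -> float:
    """MultiStep schedule: lr0 * factor^(#milestones passed at `epoch`)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.constant_lr:
        return config.lr
    passed = sum(epoch >= math.floor(m * config.epochs)
                 for m in config.milestones)
    return config.lr * config.lr_factor ** passed


@dataclass
class ELBOComponents:
    reconstruction: float      # E_q[log p(x|zeta)]  (<= 0)
    kl: float                  # KL estimate (with log Z when supplied)
    beta: float
    total: float               # -reconstruction + beta * kl

    @staticmethod
    def make(reconstruction: float, kl: float, beta: float):
        return ELBOComponents(reconstruction, kl, beta,
                              -reconstruction + beta * kl)


@dataclass
class EpochMetrics:
    epoch: int
    lr: float
    train_total: float
    train_reconstruction: float
    train_kl: float
    val_total: float
    val_reconstruction: float
    val_kl: float
    ais_log_z: float
    ais_std_err: float


def _recon_logprob(logits: Tensor, targets: np.ndarray,
                   valid: np.ndarray) -> Tensor:
    """Mean over molecules of sum over non-pad tokens of log p(target)."""
    logp = logits.log_softmax(axis=-1)
    onehot = np.zeros(logits.shape)
    B, L = targets.shape
    onehot[np.arange(B)[:, None], np.arange(L)[None, :], targets] = 1.0
    onehot *= valid[:, :, None]
    return (logp * Tensor(onehot)).sum(axis=(1, 2)).mean()


def elbo_loss(model: DVAE, batch: Batch, beta: float,
              pcd_state: PCDState | None, rngs: dict,
              pcd_steps: int = 30,
              log_z: float | None = None,
              alpha: float = 1.0,
              n_draws: int = 1) -> tuple[ELBOComponents, Tensor]:
    """ELBO components plus the differentiable surrogate to minimize.

    `alpha` blends the relaxed code between its mean-field value q
    (alpha = 0) and a full spike-and-exponential sample (alpha = 1);
    `n_draws` averages the objective over several relaxation draws.
    """
    post = model.encode(batch.enc_ids, batch.enc_valid)
    if model.cfg.latent_type == "gaussian":
        n = model.cfg.gaussian_units
        mu, logvar = post[:, :n], post[:, n:]
        zeta, kl_rows = gaussian_latent(mu, logvar, rngs["latent"])
        if alpha < 1.0:
            zeta = (1.0 - alpha) * mu + alpha * zeta
        kl_mean = kl_rows.mean()
        kl_value = float(kl_mean.data)
        logits = model.decode_train(zeta, batch.dec_in, batch.dec_valid)
        recon = _recon_logprob(logits, batch.dec_target, batch.dec_valid)
        surrogate = -recon + beta * kl_mean
        comps = ELBOComponents.make(float(recon.data), kl_value, beta)
        return comps, surrogate
    q = post
    neg = pcd_sample(pcd_state, model.rbm, k=pcd_steps)
    surrogate = None
    for _ in range(max(n_draws, 1)):
        zeta = spike_exp_reparam(q, rngs["latent"].random(q.shape),
                                 model.cfg.beta_se)
        if alpha < 1.0:
            zeta = (1.0 - alpha) * q + alpha * zeta
        klt = kl_term(q, zeta, model.rbm, neg, log_z=log_z)
        logits = model.decode_train(zeta, batch.dec_in, batch.dec_valid)
        recon = _recon_logprob(logits, batch.dec_target, batch.dec_valid)
        part = -recon + beta * klt.grad_objective
        surrogate = part if surrogate is None else surrogate + part
    surrogate = surrogate * (1.0 / max(n_draws, 1))
    comps = ELBOComponents.make(float(recon.data), klt.value, beta)
    return comps, surrogate


def _clip_grads(params, max_norm: float):
    total = math.sqrt(sum(float((p.grad ** 2).sum())
                          for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


@dataclass
class TrainResult:
    model: DVAE
    metrics: list[EpochMetrics]
    checkpoints: dict[int, dict] = field(default_factory=dict)


def train(config: TrainConfig, model: DVAE, train_set: list[str],
          val_set: list[str] | None = None,
          metrics_path=None, progress: bool = False) -> TrainResult:
    """Adam optimization of the beta-ELBO with per-epoch AIS evaluation."""
    if not train_set:
        raise ValueError("empty training corpus")
    if val_set is None:
        val_set = train_set
    rngs = {name: seeding.stream(config.seed, name)
            for name in ("shuffle", "latent", "pcd", "ais", "val_latent")}
    pcd_state = (PCDState.initialize(model.rbm, config.batch_size,
                                     rngs["pcd"])
                 if model.cfg.latent_type == "rbm" else None)
    opt = Adam(model.parameters(), lr=config.lr)
    params = opt.params
    ema: list[np.ndarray] | None = None
    ema_from = (None if config.ema_start_frac is None
                else int(config.ema_start_frac * config.epochs))
    metrics: list[EpochMetrics] = []
    checkpoints: dict[int, dict] = {}
    n = len(train_set)
    for epoch in range(config.epochs):
        lr = lr_at(epoch, config)
        opt.lr = lr
        model.train()
        alpha = config.ramp_at(epoch)
        beta_eff = config.beta * alpha
        n_draws = 1 if alpha == 0.0 else config.latent_draws
        order = rngs["shuffle"].permutation(n)
        tr_tot = tr_rec = tr_kl = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = make_batch([train_set[i] for i in idx], model.vocab)
            opt.zero_grad()
            comps, surrogate = elbo_loss(model, batch, beta_eff,
                                         pcd_state, rngs,
                                         pcd_steps=config.pcd_steps,
                                         alpha=alpha, n_draws=n_draws)
            surrogate.backward()
            if config.grad_clip is not None:
                _clip_grads(opt.params, config.grad_clip)
            opt.step()
            if ema_from is not None and epoch >= ema_from:
                if ema is None:
                    ema = [p.data.copy() for p in params]
                else:
                    for e_, p in zip(ema, params):
                        e_ *= config.ema_decay
                        e_ += (1.0 - config.ema_decay) * p.data
            tr_tot += comps.total
            tr_rec += comps.reconstruction
            tr_kl += comps.kl
            n_batches += 1
        tr_tot, tr_rec, tr_kl = (x / n_batches for x in
                                 (tr_tot, tr_rec, tr_kl))
        # ---- end-of-epoch evaluation ------------------------------------
        model.eval()
        if model.cfg.latent_type == "rbm":
            ais = ais_log_partition(model.rbm, rngs["ais"],
                                    n_intermediate=config.ais_intermediate,
                                    n_samples=config.ais_samples)
            log_z, ais_se = ais.log_z, ais.std_err
        else:
            log_z, ais_se = 0.0, 0.0
        val_batch = make_batch(val_set[: max(config.batch_size, 1) * 4],
                               model.vocab)
        val_pcd = (PCDState.initialize(model.rbm, len(val_batch.smiles),
                                       rngs["val_latent"])
                   if model.cfg.latent_type == "rbm" else None)
        vcomps, _ = elbo_loss(model, val_batch, config.beta, val_pcd,
                              {"latent": rngs["val_latent"]},
                              pcd_steps=config.pcd_steps, log_z=log_z)
        rec = EpochMetrics(
            epoch=epoch, lr=lr, train_total=tr_tot,
            train_reconstruction=tr_rec, train_kl=tr_kl,
            val_total=vcomps.total, val_reconstruction=vcomps.reconstruction,
            val_kl=vcomps.kl, ais_log_z=log_z, ais_std_err=ais_se)
        metrics.append(rec)
        if progress:
            print(f"epoch {epoch:4d}  lr {lr:.2e}  "
                  f"train {tr_tot:9.3f}  val {vcomps.total:9.3f}")
        if epoch in config.checkpoint_epochs:
            checkpoints[epoch] = model.state_dict()
    if ema is not None:
        for e_, p in zip(ema, params):
            p.data = e_.copy()
    if metrics_path is not None:
        write_metrics_csv(metrics_path, metrics)
    return TrainResult(model=model, metrics=metrics, checkpoints=checkpoints)


def write_metrics_csv(path, metrics: list[EpochMetrics]):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(asdict(metrics[0])))
        writer.writeheader()
        for m in metrics:
            writer.writerow(asdict(m))


# ---------------------------------------------------------------------------
# Reconstruction workflow
# ---------------------------------------------------------------------------

@dataclass
class Reconstruction:
    smiles: str
    frequency: float
    tanimoto: float | None  # None when the output does not parse


def reconstruct(model: DVAE, smiles: str, n_runs: int,
                rng: np.random.Generator,
                mode: str = "greedy") -> list[Reconstruction]:
    """Encode, sample z ~ q, relax, decode — n_runs times; aggregate the
    distinct outputs with empirical frequencies and Tanimoto to the input.

    The reported frequencies estimate the distribution induced by the
    *latent* sampling (z and its relaxation); the default readout is the
    argmax decode, so token-level sampling noise does not blur them.  Pass
    mode="sample" for fully stochastic decoding.
    """
    from .evaluate import fingerprint, tanimoto
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    model.eval()
    q = model.encode_smiles(smiles).data[0]
    counts: dict[str, int] = {}
    for _ in range(n_runs):
        z = model.sample_z(q, rng)
        zeta = model.zeta_from_z(z, rng)
        ids = model.decode_generate(zeta, rng, mode=mode)
        out = model.vocab.decode(ids)
        counts[out] = counts.get(out, 0) + 1
    ref_fp = fingerprint(smiles)
    results = []
    for out, c in sorted(counts.items(), key=lambda kv: -kv[1]):
        fp = fingerprint(out)
        t = tanimoto(ref_fp, fp) if fp is not None else None
        results.append(Reconstruction(out, c / n_runs, t))
    return results
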