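# Methods

## Model

`moldvae` implements a discrete variational autoencoder (DVAE) over SMILES
strings whose latent prior is a bipartite Restricted Boltzmann Machine
(RBM).  The generative story: binary latents **z** are drawn from the RBM,
relaxed to continuous **ζ** through a spike-and-exponential smoothing
distribution, and an autoregressive transformer decoder emits a token
sequence conditioned on ζ.  The encoder maps a token sequence to factorial
Bernoulli posterior probabilities **q** = q_φ(z|x).

Training maximizes the β-weighted evidence lower bound

    L(x, θ, φ) = E_{q_φ(ζ|x)}[log p_θ(x|ζ)] − β · D_KL(q_φ(z|x) ‖ p_θ(z)),

minimized in the code as `total = −reconstruction + β·KL` with β = 0.1, the
down-weighting that guards against posterior collapse.

### Sequence frontend

Token ids pass through a trainable embedding combined with the fixed
sinusoidal positional code as

    x̃ = √d_emb · x_emb + pe / √d_emb,   d_emb = 32,

which rebalances the two terms to the proportion of the original
transformer.  A 1-D convolution (160 filters, kernel 5) and a highway layer
then lift the embedding to the model width; on the decoder side the
convolution is *causally* padded (left-only) so the autoregressive factor
-ization is never violated, and the same causal path is used in
teacher-forced training for consistency.  The conv/highway/transformer
widths and counts follow the full-scale architecture: 5 encoder and 5
decoder layers, d_model = 160, feed-forward width 320, 10 attention heads,
GeLU activations, dropout 0.1.  Layers use the pre-norm arrangement
(LayerNorm before each sublayer); pre-norm stacks remain stable at the
larger learning rates that CPU-scale runs require.

### Fixed-length pooling

The variable-length encoder output u (length L, width 160) is summarized by
exactly 16 vectors: u₀, the global mean, and the means over the remainder
classes S^m_n = {u_i : i ≡ m (mod n)} for n = 2..5, m = 0..n−1, concatenated
in that fixed order.  Padded positions are excluded from every mean; a class
left empty (possible only for L < n) falls back to the global mean.  The
16×160 tensor is flattened and an affine map + sigmoid produces the 256
posterior probabilities (two RBM layers of 128 units).

### RBM latent prior

Energy and probability over the 256 binary units:

    E(z) = Σ_l z_l h_l + Σ_{l<m} W_lm z_l z_m,   p(z) = e^{−E(z)} / Z,

with couplings only between the two 128-unit layers and temperature fixed
at 1.  Because the graph is bipartite, block Gibbs sampling alternates the
two layers with conditionals σ(−(h_a + W z_b)).  The negative phase of the
KL gradient uses persistent contrastive divergence: chains persist across
updates and are advanced 30 block sweeps per gradient step.  The positive
phase is evaluated on the *relaxed* samples ζ so gradients reach the
encoder through the reparameterization; log Z never contributes a gradient.
At evaluation time log Z is estimated by annealed importance sampling along
the linear path β_k from 0 to 1 with 10 intermediate distributions and 500
samples (base distribution: uniform, log Z₀ = N·log 2; one block-Gibbs
sweep per level).  Exact enumeration (≤ 24 units) serves as the oracle for
all sampling machinery in the tests.

### Spike-and-exponential relaxation

r(ζ|z=0) is a point mass at 0; r(ζ|z=1) ∝ e^{β_se·ζ} on [0, 1].  Sampling
uses the inverse CDF of the mixture at rate q, which is differentiable in q
for a fixed uniform draw (the branch indicator is treated as locally
constant, the standard reparameterization of a mixed distribution).  The
sharpness β_se defaults to 8 (sharp enough that ζ ≈ z in distribution,
soft enough for useful gradients) and is configurable; the desk-scale
preset uses 24, trading gradient softness for a nearly-binary code.

### Prior-sampler backends

`prior_sample` dispatches through a registry: the `gibbs` backend runs a
burn-in (1000 sweeps) plus thinned (10) block-Gibbs chain; the
`annealer_stub` backend obeys the identical contract (RBM parameters in,
binary samples out) with an injectable sample source, so an adapter for
annealing hardware can be slotted in without touching model code.

## Training engine

Adam with the MultiStep schedule: initial rate 6×10⁻⁵ halved at 50%, 75%
and 95% of the run (300 epochs at full scale); a constant-rate flag
reproduces the 75-epoch annealer-style schedule.  Per epoch the engine logs
train/validation ELBO components, with the validation KL completed by the
AIS log-Z estimate; metrics stream to CSV, checkpoints are versioned
archives holding all parameter groups plus the vocabulary.

### Desk-scale curriculum

Small-corpus overfit runs (tens of molecules, hundreds of epochs, one CPU)
are the tractable analogue of full-scale training, and they expose a
failure mode that large corpora average away: early in training the
relaxation noise is large, the decoder learns to ignore ζ, and the
posterior collapses onto a single code.  The `TrainConfig.overfit` preset
therefore applies a curriculum:

* **latent warm-up** — for the first 40% of epochs the decoder receives the
  mean-field code ζ = q with β = 0 (a deterministic autoencoder), then both
  the spike-and-exponential noise and β are blended in linearly until 70%;
* **multi-draw averaging** — the stochastic-phase loss averages 2
  relaxation draws per step to reduce gradient variance;
* **Polyak averaging** — from 75% of the run an exponential moving average
  (decay 0.995) of the weights is maintained and adopted at the end;
* the reduced model adds a posterior-head logit gain of 8 (so saturated
  codes are reachable within the step budget) and a broadcast projection of
  ζ onto every decoder position alongside the 16 cross-attention memory
  vectors.

The final objective is the unmodified β = 0.1 ELBO; the curriculum only
reorders how its stochasticity is introduced.  Full-scale defaults use no
curriculum.

Learning rate for the desk preset is 1×10⁻³ (batch 4): the full-scale
6×10⁻⁵ is calibrated to the millions of gradient steps a ~10⁵-molecule
corpus provides and moves
parameters too little in a 200-epoch/32-molecule run to converge at all.

### Known limitation: per-molecule memorization

Even with the curriculum, the β-weighted KL keeps an equilibrium in which a
few posterior units stay off saturation (the entropy term pushes q toward
0.5 with force β·logit(q)), so Bernoulli draws of z flip roughly one unit
per reconstruction.  The decoder learns partial flip-robustness, but
fixture molecules that differ by one or two tokens can end up with codes
separated by a single marginal unit and then reconstruct into each other.
In our experiments 35–80% of fixture molecules reach reconstruction
frequency > 0.9 depending on the seed; the rest plateau between 0.5 and
0.9, and training longer does not change the equilibrium.  Stochastic
rather than deterministic reconstruction is inherent to this model class —
the latent code is sampled, so some output mass always spreads to
neighbouring molecules.  The acceptance suite asserts the strict
per-molecule property and reports the failures it finds.

## Reconstruction and generation

`reconstruct` encodes a molecule, samples z ~ Bernoulli(q), relaxes through
the spike-and-exponential at q = z, decodes, and aggregates distinct
outputs over n runs with empirical frequencies and Tanimoto similarity to
the input.  The default readout is the argmax (greedy) decode, so the
frequencies estimate the distribution induced by the latent sampling alone;
`mode="sample"` adds token-level sampling at temperature 1.

`generate_molecules` samples z from the trained RBM prior via a registered
backend, relaxes, and decodes with token sampling; invalid strings are
retained because validity is a reported metric, not a filter.

## Evaluation battery

Computed with RDKit over the valid molecules only: molecular weight (Da),
Crippen logP, QED, and the synthetic accessibility score (SAS, RDKit
contrib), reported as mean/std alongside the validity fraction.  Novelty:
2048-bit topological path fingerprints (`RDKFingerprint`), Tanimoto
similarity T = C/(A+B−C) implemented as exact bit arithmetic (T of two
all-zero fingerprints is defined as 0 and warned about), and the fractions
of generated molecules whose maximum similarity to the training set
exceeds 0.9 and 0.7.  The hand-rolled Tanimoto is cross-checked against
the toolkit's implementation in the tests.

## Synthetic fixture corpus

The fixture generator assembles molecules from a small organic-subset
grammar — an optional ring scaffold (benzene, pyridine, furan, thiophene,
cyclohexane, piperidine, oxane), a 1–5 atom chain over {C, N, O, S}, and a
common terminal group (halogen, hydroxyl, amine, nitrile, carboxyl,
isopropyl, vinyl) — then canonicalizes and deduplicates, so every output
passes curation unchanged.  It emulates the size range and token inventory
of short drug-like molecules; it does **not** emulate ChEMBL's stereo
-chemistry, charged species, fused ring systems, or molecular-weight
distribution, so desk-scale results demonstrate mechanism correctness, not
chemical realism.

## Numerical choices

* Float64 throughout; gradients verified against central finite
  differences at 10⁻⁵ relative tolerance.
* Bernoulli entropy clips probabilities at 10⁻¹² inside the logs only; the
  resulting gradient logit(q) is exact.
* The spike-and-exponential inverse CDF guards the division at q ∈ {0, 1}
  with an affine 10⁻⁹ shrink.
* Attention masking is additive (−10⁹); padded positions are excluded from
  pooling means, attention keys, and the reconstruction loss.
* Curation keeps the largest fragment by heavy-atom count (salt removal),
  restricts atoms to {B, C, N, O, P, S, F, Cl, Br, I} (+H), canonicalizes
  with RDKit, and caps the canonical string at 200 characters.
* The 80/20 train/validation split shuffles with a dedicated seeded stream;
  every stochastic subsystem (split, PCD, relaxation draws, decoding,
  generation) draws from its own named stream fanned out of one global
  seed.

## Problem sizes used by the shipped experiments

The test-suite and the acceptance script run: 40 random RBMs of up to 8+8
units for the AIS-vs-enumeration battery; 20 000 thinned block-Gibbs
samples for the 2+2 distribution test; 10⁵ draws for the relaxation
statistics; a 32-molecule fixture corpus trained 200 epochs with the
reduced model (16+16 RBM, 2+2 transformer layers, d_model 64); 20
reconstruction runs per molecule; and 200 prior samples for the generation
battery.
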