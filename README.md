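# moldvae

A discrete variational autoencoder (DVAE) for generative chemistry: a
character-level SMILES transformer autoencoder whose latent space is a
compact bipartite Restricted Boltzmann Machine (RBM), trainable with
classical block-Gibbs / persistent-contrastive-divergence sampling and
evaluated with annealed importance sampling (AIS).  The RBM prior is small
enough (two layers of 128 binary units) that its sampler is pluggable: the
classical Gibbs backend ships here, and a stub with the identical contract
marks the seam where a quantum-annealer adapter would plug in.

The package is aimed at researchers prototyping latent-variable generative
models for drug-like molecules who need the full loop on one CPU: corpus
curation, training with the β-weighted ELBO, molecule generation from the
prior, and the standard evaluation battery (validity, MW, logP, QED, SAS,
fingerprint-Tanimoto novelty).

## The model

Training maximizes the evidence lower bound with a down-weighted KL term,

    L(x, θ, φ) = E_{q_φ(ζ|x)}[log p_θ(x|ζ)] − β · D_KL(q_φ(z|x) ‖ p_θ(z)),  β = 0.1,

where the prior p_θ(z) ∝ exp(−Σ_l z_l h_l − Σ_{l<m} W_lm z_l z_m) is an RBM
over binary latents z, relaxed to continuous ζ by a spike-and-exponential
distribution so the reparameterization trick applies.  The encoder is a
conv/highway frontend plus 5 transformer layers pooled to a fixed 16×160
tensor; the decoder is a latent-conditioned 5-layer transformer with causal
preprocessing.  See `docs/methods.md` for the complete description and all
numerical choices.

## Worked example

```python
>>> from moldvae import tokenize, curate, ais_log_partition, tanimoto
>>> tokenize("CC(=O)Oc1ccccc1C(=O)O")        # aspirin, lossless lexing
['C', 'C', '(', '=', 'O', ')', 'O', 'c', '1', 'c', 'c', 'c', 'c', 'c',
 '1', 'C', '(', '=', 'O', ')', 'O']

>>> c = curate(["CCO.Cl", "C[Si](C)C", "c1ccccc1N"])
>>> c.molecules                               # salt-stripped + canonical
['CCO', 'Nc1ccccc1']
>>> [(r.smiles, r.reason) for r in c.records if not r.accepted]
[('C[Si](C)C', 'non-organic-subset atom: Si')]
```

The first list is aspirin cut into SMILES lexical units — two-letter atoms
and bracket atoms are single tokens, so concatenation restores the exact
input.  Curation kept ethanol (dropping the HCl counter-ion) and aniline,
and rejected the silane because Si is outside the organic atom subset.

```python
>>> import numpy as np
>>> from moldvae.rbm import RBM
>>> rng = np.random.default_rng(0)
>>> rbm = RBM(8, 8, rng)
>>> rbm.h.data = rng.normal(size=16); rbm.W.data = rng.normal(size=(8, 8))
>>> res = ais_log_partition(rbm, np.random.default_rng(1))
>>> print(f"AIS log Z = {res.log_z:.3f} ± {res.std_err:.3f}")
AIS log Z = 15.214 ± 0.074
>>> rbm.log_partition_exact()                 # enumeration oracle
15.155...
```

AIS with 10 intermediate distributions and 500 samples estimates the RBM
log-partition within its reported standard error of the exact enumerated
value — the same machinery that completes the KL term in the per-epoch
evaluation.

A complete run from the shell (synthetic corpus, reduced model):

```bash
moldvae fixture  --n 200 --seed 1 --out run/fx
moldvae prepare  --corpus run/fx/fixture.smi --seed 1 --out run/prep
moldvae train    --corpus run/prep/train.smi --valid-corpus run/prep/valid.smi \
                 --preset reduced --epochs 50 --seed 1 --out run/model
moldvae generate --checkpoint run/model/checkpoint.npz --n 100 --seed 2 --out run/gen
moldvae evaluate --generated run/gen/generated.smi \
                 --train-corpus run/prep/train.smi --out run/eval
```

`evaluate` prints a property table (mean/std of MW, logP, QED, SAS over the
valid molecules, plus the validity fraction) and the fractions of generated
molecules within Tanimoto 0.9 / 0.7 of the training set.

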