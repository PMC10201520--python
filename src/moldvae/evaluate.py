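"""Generation from the prior and the property-evaluation battery.

Properties tracked for generated molecules (computed with RDKit, over valid
molecules only): molecular weight (MW, Da), Crippen logP, quantitative
estimate of drug-likeness (QED, in [0,1]) and the synthetic accessibility
score (SAS, ~1 easy to ~10 hard).  Novelty is measured as the fraction of
generated molecules whose maximum Tanimoto similarity to the training set
exceeds 0.9 (near-duplicates) and 0.7 (close analogues), on 2048-bit
topological path fingerprints.
"""

from __future__ import annotations

import json
import os
import sys
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

from .model import DVAE  # noqa: E402
from .rbm import prior_sample, _spike_exp_icdf  # noqa: E402

FP_BITS = 2048


def fingerprint(smiles: str) -> np.ndarray | None:
    """2048-bit topological path fingerprint; None if the string is invalid."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    fp = Chem.RDKFingerprint(mol, fpSize=FP_BITS)
    arr = np.zeros(FP_BITS, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """T(a, b) = C / (A + B - C) on bit vectors; defined as 0 for two
    all-zero fingerprints (the formula is 0/0 there)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    c = int(np.count_nonzero(a & b))
    denom = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - c
    if denom == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints; defining T=0")
        return 0.0
    return c / denom


def validity(smiles_list: list[str]) -> float:
    """Fraction of strings RDKit can parse into a molecular graph."""
    if not smiles_list:
        raise ValueError("validity of an empty list is undefined")
    ok = sum(Chem.MolFromSmiles(s) is not None for s in smiles_list)
    return ok / len(smiles_list)


@dataclass
class PropertyReport:
    n_samples: int
    validity: float
    mw_mean: float
    mw_std: float
    logp_mean: float
    logp_std: float
    qed_mean: float
    qed_std: float
    sas_mean: float
    sas_std: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PropertyReport":
        return cls(**json.loads(text))

    def table(self):
        """Table-1-shaped single-column DataFrame (mean/std strings)."""
        import pandas as pd
        rows = {
            "Number of samples": f"{self.n_samples}",
            "MW": f"{self.mw_mean:.2f}/{self.mw_std:.2f}",
            "LogP": f"{self.logp_mean:.2f}/{self.logp_std:.2f}",
            "QED": f"{self.qed_mean:.2f}/{self.qed_std:.2f}",
            "SAS": f"{self.sas_mean:.2f}/{self.sas_std:.2f}",
            "Validity": f"{self.validity:.2f}",
        }
        return pd.DataFrame({"value": rows})


def property_report(smiles_list: list[str]) -> PropertyReport:
    """Mean/std of MW, logP, QED, SAS over the valid molecules in the list."""
    if not smiles_list:
        raise ValueError("empty molecule list")
    mols = [(s, Chem.MolFromSmiles(s)) for s in smiles_list]
    valid = [m for _, m in mols if m is not None]
    if not valid:
        raise ValueError("no valid molecules to evaluate")
    mw = np.array([Descriptors.MolWt(m) for m in valid])
    logp = np.array([Crippen.MolLogP(m) for m in valid])
    qed = np.array([QED.qed(m) for m in valid])
    sas = np.array([sascorer.calculateScore(m) for m in valid])
    return PropertyReport(
        n_samples=len(smiles_list),
        validity=len(valid) / len(smiles_list),
        mw_mean=float(mw.mean()), mw_std=float(mw.std()),
        logp_mean=float(logp.mean()), logp_std=float(logp.std()),
        qed_mean=float(qed.mean()), qed_std=float(qed.std()),
        sas_mean=float(sas.mean()), sas_std=float(sas.std()))


@dataclass
class NoveltyReport:
    frac_above_09: float
    frac_above_07: float
    n_generated: int
    n_training: int

    def to_dict(self) -> dict:
        return asdict(self)


def novelty_stats(generated: list[str], training: list[str],
                  thresholds: tuple[float, float] = (0.9, 0.7)
                  ) -> NoveltyReport:
    """Fractions of valid generated molecules whose max Tanimoto similarity
    to any training molecule exceeds each threshold."""
    if not generated or not training:
        raise ValueError("both molecule sets must be non-empty")
    gen_fps = [fp for fp in (fingerprint(s) for s in generated)
               if fp is not None]
    if not gen_fps:
        raise ValueError("no valid generated molecules")
    train_fps = [fp for fp in (fingerprint(s) for s in training)
                 if fp is not None]
    if not train_fps:
        raise ValueError("no valid training molecules")
    G = np.array(gen_fps)              # (g, bits)
    T = np.array(train_fps)            # (t, bits)
    inter = G.astype(np.int32) @ T.T.astype(np.int32)
    a = G.sum(axis=1)[:, None]
    b = T.sum(axis=1)[None, :]
    denom = a + b - inter
    sim = np.divide(inter, denom, out=np.zeros_like(denom, dtype=np.float64),
                    where=denom > 0)
    max_sim = sim.max(axis=1)
    hi, lo = max(thresholds), min(thresholds)
    return NoveltyReport(
        frac_above_09=float((max_sim > hi).mean()),
        frac_above_07=float((max_sim > lo).mean()),
        n_generated=len(gen_fps), n_training=len(train_fps))


def generate_molecules(model: DVAE, n: int, rng: np.random.Generator,
                       backend: str = "gibbs",
                       mode: str = "sample", **backend_kwargs) -> list[str]:
    """Sample z from the RBM prior, relax to zeta, decode, detokenize.

    Invalid strings are retained: validity is a metric, not a filter.
    """
    if n == 0:
        return []
    model.eval()
    z = prior_sample(model.rbm, n, rng, backend=backend, **backend_kwargs)
    out = []
    for i in range(n):
        zeta = _spike_exp_icdf(z[i], rng.random(z[i].shape),
                               model.cfg.beta_se)
        ids = model.decode_generate(zeta, rng, mode=mode)
        out.append(model.vocab.decode(ids))
    return out
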