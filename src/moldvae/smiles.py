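"""SMILES tokenization, vocabulary construction, corpus curation and splitting.

Tokenization is character-level in the chemical sense: multi-character atoms
(Cl, Br), bracket atoms ([nH], [O-]) and two-digit ring closures (%12) are
single tokens, so detokenization is plain concatenation and is lossless.

Curation mirrors standard generative-chemistry practice: strip salt residuals
by keeping the largest fragment, restrict to the organic atom subset
(B, C, N, O, P, S, F, Cl, Br, I, plus hydrogens), canonicalize with RDKit and
cap the canonical string at 200 characters.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # curation handles invalid input itself

# One alternative per SMILES lexical unit; bracket atoms and two-letter
# halogens must precede single letters so the longest unit wins.
SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFI]|[bcnops]|\d"
    r"|[()=#\-+.\\/:~@?>*$])"
)

ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"}
MAX_SMILES_LEN = 200

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)


class TokenizationError(ValueError):
    """Raised when a string contains a character no token alternative matches."""

    def __init__(self, smiles: str, offset: int):
        self.offset = offset
        super().__init__(
            f"cannot tokenize {smiles!r}: no token matches at offset {offset} "
            f"({smiles[offset]!r})")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into lexical tokens (lossless)."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens = []
    pos = 0
    for m in SMILES_TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group())
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(smiles, pos)
    return tokens


def detokenize(tokens: list[str]) -> str:
    """Concatenate tokens back into a string, dropping special markers."""
    return "".join(t for t in tokens if t not in SPECIALS)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token inventory: specials first, then sorted chemical tokens."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if self.tokens[: len(SPECIALS)] != SPECIALS:
            raise ValueError("vocabulary must start with the special tokens")
        object.__setattr__(self, "_index",
                           {t: i for i, t in enumerate(self.tokens)})

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def eos_id(self) -> int:
        return 2

    @property
    def unk_id(self) -> int:
        return 3

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, token: str) -> int:
        return self._index[token]

    def encode(self, smiles: str, add_special: bool = True) -> list[int]:
        ids = [self._index.get(t, self.unk_id) for t in tokenize(smiles)]
        if add_special:
            return [self.bos_id] + ids + [self.eos_id]
        return ids

    def decode(self, ids) -> str:
        return detokenize([self.tokens[int(i)] for i in ids])

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)}, indent=0)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        return cls(tuple(json.loads(text)["tokens"]))


def build_vocab(molecules: list[str]) -> Vocabulary:
    """Corpus-derived vocabulary; chemical tokens in lexicographic order."""
    if not molecules:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    chem = sorted({t for s in molecules for t in tokenize(s)})
    return Vocabulary(SPECIALS + tuple(chem))


@dataclass
class CurationRecord:
    smiles: str
    accepted: bool
    reason: str  # "" when accepted
    canonical: str | None = None


@dataclass
class CuratedCorpus:
    molecules: list[str] = field(default_factory=list)
    records: list[CurationRecord] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(not r.accepted for r in self.records)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda f: f.GetNumHeavyAtoms())


def curate_one(smiles: str) -> CurationRecord:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return CurationRecord(smiles, False, "unparsable")
    mol = _largest_fragment(mol)
    bad = {a.GetSymbol() for a in mol.GetAtoms()} - ORGANIC_SUBSET
    if bad:
        return CurationRecord(
            smiles, False, f"non-organic-subset atom: {','.join(sorted(bad))}")
    canonical = Chem.MolToSmiles(mol)
    if len(canonical) > MAX_SMILES_LEN:
        return CurationRecord(smiles, False,
                              f"length {len(canonical)} > {MAX_SMILES_LEN}")
    try:
        tokenize(canonical)
    except TokenizationError as exc:  # pragma: no cover - defensive
        return CurationRecord(smiles, False, f"untokenizable: {exc}")
    return CurationRecord(smiles, True, "", canonical)


def curate(raw: list[str]) -> CuratedCorpus:
    """Salt-strip, filter and canonicalize; rejections recorded, never raised."""
    corpus = CuratedCorpus()
    for s in raw:
        rec = curate_one(s.strip())
        corpus.records.append(rec)
        if rec.accepted:
            corpus.molecules.append(rec.canonical)
    return corpus


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(molecules: list[str],
                  spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Deterministic shuffled train/validation split."""
    if not molecules:
        raise ValueError("cannot split an empty corpus")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(molecules))
    n_train = round(spec.train_fraction * len(molecules))
    train = [molecules[i] for i in order[:n_train]]
    val = [molecules[i] for i in order[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# Synthetic fixture corpus
# ---------------------------------------------------------------------------

_SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "C1CCCCC1", "C1CCNCC1",
    "C1CCOCC1", "",
)
_CHAIN_ATOMS = ("C", "C", "C", "C", "N", "O", "S")
_TERMINALS = ("", "O", "N", "F", "Cl", "Br", "C(=O)O", "C(C)C", "C#N", "C=C")


def _assemble(rng: np.random.Generator) -> str:
    scaffold = _SCAFFOLDS[rng.integers(len(_SCAFFOLDS))]
    chain = "".join(_CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]
                    for _ in range(rng.integers(1, 6)))
    terminal = _TERMINALS[rng.integers(len(_TERMINALS))]
    return scaffold + chain + terminal


def generate_fixture_corpus(n: int, seed: int,
                            unique: bool = True) -> list[str]:
    """Small valid organic-subset molecules from a fragment grammar.

    Every output is canonical and passes `curate` unchanged; the list is
    deterministic given (n, seed).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A17]))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        candidate = _assemble(rng)
        mol = Chem.MolFromSmiles(candidate)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if unique and canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out


def read_smiles_file(path) -> list[str]:
    """Plain-text corpus: one SMILES per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smiles_file(path, molecules: list[str]):
    with open(path, "w") as fh:
        for s in molecules:
            fh.write(s + "\n")
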