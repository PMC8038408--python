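"""SMILES corpora: records, canonicalization, enumeration, tokenization.

Augmentation follows the SMILES-enumeration idea: the same molecular
graph admits many valid SMILES strings, obtained here by randomly
permuting atom indices before writing a non-canonical string.  Two
independent enumerations of one parent form the positive pair for
contrastive training.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

LABELS = ("drug", "metabolite", "fluorophore", "natural_product", "other")

# Atomwise SMILES tokenization: bracket atoms, two-letter organic-subset
# halogens, %nn ring closures and single structural characters.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFIbcnosp]|[0-9]|[()=#\-+\\/.:~@?>*$])"
)

PAD, START, END, UNK = "<pad>", "<start>", "<end>", "<unk>"
SPECIALS = (PAD, START, END, UNK)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A molecule of the corpus: id, canonical SMILES and class label."""

    id: str
    canonical_smiles: str
    label: str = "other"

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class AugmentedPair:
    """Two independently enumerated SMILES views of one parent molecule."""

    parent_id: str
    x_i: str
    x_j: str


def _mol(smiles: str) -> Chem.Mol:
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical SMILES; idempotent on its own output."""
    return Chem.MolToSmiles(_mol(smiles))


def enumerate_smiles(canonical: str, rng: np.random.Generator) -> str:
    """Draw a random-atom-order SMILES of the same molecule.

    The atom indices are shuffled with ``rng`` and a non-canonical string
    is written from the permuted graph, so every call is an independent
    restart; the result always canonicalizes back to ``canonical``.
    """
    mol = _mol(canonical)
    n = mol.GetNumAtoms()
    if n <= 1:
        return Chem.MolToSmiles(mol)
    perm = rng.permutation(n).tolist()
    shuffled = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


def sample_positive_pair(record: MoleculeRecord,
                         rng: np.random.Generator,
                         max_retry: int = 10) -> AugmentedPair:
    """Two independent enumeration draws from one parent.

    Retries a few times to obtain distinct strings; symmetric or tiny
    molecules may still yield identical views, which is accepted.
    """
    x_i = enumerate_smiles(record.canonical_smiles, rng)
    x_j = enumerate_smiles(record.canonical_smiles, rng)
    for _ in range(max_retry):
        if x_i != x_j:
            break
        x_j = enumerate_smiles(record.canonical_smiles, rng)
    return AugmentedPair(parent_id=record.id, x_i=x_i, x_j=x_j)


def tokenize(smiles: str) -> list[str]:
    """Atomwise tokenization; concatenating the tokens restores the input.

    Characters outside the token table fall back to single-character
    tokens and are logged, never dropped.
    """
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(smiles):
        if m.start() > pos:
            for ch in smiles[pos:m.start()]:
                logger.warning("unknown SMILES character %r in %r", ch, smiles)
                tokens.append(ch)
        tokens.append(m.group())
        pos = m.end()
    for ch in smiles[pos:]:
        logger.warning("unknown SMILES character %r in %r", ch, smiles)
        tokens.append(ch)
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Token <-> index map with fixed special slots pad=0,start=1,end=2,unk=3."""

    token_to_index: dict

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    @property
    def pad(self) -> int:
        return 0

    @property
    def start(self) -> int:
        return 1

    @property
    def end(self) -> int:
        return 2

    @property
    def unk(self) -> int:
        return 3

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, self.unk)

    def tokens(self) -> list[str]:
        inv = sorted(self.token_to_index.items(), key=lambda kv: kv[1])
        return [t for t, _ in inv]

    def content_hash(self) -> str:
        import hashlib
        blob = json.dumps(self.token_to_index, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.token_to_index, indent=0, sort_keys=False) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TokenVocabulary":
        return cls(token_to_index=json.loads(Path(path).read_text()))


def build_vocabulary(corpus: list[MoleculeRecord],
                     enumeration_passes: int = 10,
                     seed: int = 0) -> TokenVocabulary:
    """Collect tokens from canonical strings plus enumeration restarts.

    Enumeration can surface tokens absent from every canonical string
    (e.g. explicit ring-closure digits in a different order), so a few
    randomized passes per molecule are scanned as well.  Ordering is
    deterministic: specials first, then lexicographic.
    """
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    for rec in corpus:
        seen.update(tokenize(rec.canonical_smiles))
        for _ in range(enumeration_passes):
            seen.update(tokenize(enumerate_smiles(rec.canonical_smiles, rng)))
    mapping = {tok: i for i, tok in enumerate(SPECIALS)}
    for tok in sorted(seen):
        mapping[tok] = len(mapping)
    return TokenVocabulary(token_to_index=mapping)


@dataclass(frozen=True)
class EncodedSequence:
    """Fixed-length token-id encoding with start/end framing and pad mask."""

    token_ids: np.ndarray       # (max_len,) int64
    true_length: int            # including start and end tokens
    pad_mask: np.ndarray        # (max_len,) bool, True where padded


def encode_sequence(smiles: str, vocab: TokenVocabulary,
                    max_len: int) -> EncodedSequence:
    """[start] + tokens + [end] + pads; errors instead of truncating."""
    tokens = tokenize(smiles)
    needed = len(tokens) + 2
    if needed > max_len:
        raise ValueError(
            f"SMILES {smiles!r} needs {needed} positions but max_len={max_len}")
    ids = np.full(max_len, vocab.pad, dtype=np.int64)
    ids[0] = vocab.start
    for i, tok in enumerate(tokens, start=1):
        ids[i] = vocab.index(tok)
    ids[needed - 1] = vocab.end
    mask = np.zeros(max_len, dtype=bool)
    mask[needed:] = True
    return EncodedSequence(token_ids=ids, true_length=needed, pad_mask=mask)


def decode_sequence(seq: EncodedSequence, vocab: TokenVocabulary) -> str:
    """Inverse of encode_sequence for in-vocabulary token sequences."""
    inv = {i: t for t, i in vocab.token_to_index.items()}
    out = []
    for idx in seq.token_ids[1:seq.true_length - 1]:
        out.append(inv[int(idx)])
    return "".join(out)


def read_corpus(path: str | Path) -> list[MoleculeRecord]:
    """Read a .smi file (SMILES [id] per line) or a smiles,label[,id] CSV."""
    path = Path(path)
    records: list[MoleculeRecord] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ValueError(f"{path}: CSV must have a 'smiles' column")
            for i, row in enumerate(reader):
                records.append(MoleculeRecord(
                    id=row.get("id") or f"mol{i}",
                    canonical_smiles=canonicalize(row["smiles"]),
                    label=row.get("label") or "other"))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            records.append(MoleculeRecord(
                id=parts[1] if len(parts) > 1 else f"mol{i}",
                canonical_smiles=canonicalize(parts[0])))
    return records


def write_corpus(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write a smiles,label,id CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "label", "id"])
        for rec in records:
            writer.writerow([rec.canonical_smiles, rec.label, rec.id])
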