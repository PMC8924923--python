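"""SMILES corpus handling: standardization, tokenization, encoding.

Corpora are lists of :class:`SmilesRecord`. Strings are canonicalized with
RDKit, desalted (largest fragment kept), deduplicated, and filtered to
20-90 canonical characters before any model ever sees them. Tokenization is
character-level except that the two-letter organic-subset halogens ``Cl``
and ``Br`` are single tokens, so every string round-trips exactly.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

MIN_LENGTH = 20
MAX_LENGTH = 90

_TOKEN_RE = re.compile(r"Cl|Br|.")

PAD = "<pad>"
START = "<s>"
END = "</s>"


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens.

    Character-level, with ``Cl`` and ``Br`` merged into single tokens;
    bracket atoms are emitted as individual characters. The split is
    lossless: ``"".join(tokenize(s)) == s``.
    """
    return _TOKEN_RE.findall(smiles)


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class SmilesRecord:
    """A standardized molecule: raw input, canonical SMILES, optional activity."""

    raw: str
    canonical: str
    activity: float | None = None

    @property
    def length(self) -> int:
        return len(self.canonical)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered token set with pad/start/end specials fixing the one-hot dimension V.

    Specials come first (pad=0, start=1, end=2), corpus tokens follow in
    sorted order, so vocabulary construction is deterministic.
    """

    tokens: tuple[str, ...]
    pad_token: str = PAD
    start_token: str = START
    end_token: str = END
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for special in (self.pad_token, self.start_token, self.end_token):
            if special not in self.tokens:
                raise ValueError(f"special token {special!r} missing from tokens")
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.tokens)})

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return self._index[self.pad_token]

    @property
    def start_index(self) -> int:
        return self._index[self.start_token]

    @property
    def end_index(self) -> int:
        return self._index[self.end_token]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def to_json(self) -> str:
        return json.dumps(
            {
                "tokens": list(self.tokens),
                "pad_token": self.pad_token,
                "start_token": self.start_token,
                "end_token": self.end_token,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(
            tokens=tuple(d["tokens"]),
            pad_token=d["pad_token"],
            start_token=d["start_token"],
            end_token=d["end_token"],
        )


@dataclass(frozen=True)
class EncodedSequence:
    """Token indices of a SMILES string followed by the end token.

    ``n_steps`` is the number of prediction steps N: all tokens of the
    string plus the terminating end token (the implicit start token is
    input only, never predicted).
    """

    token_indices: tuple[int, ...]

    @property
    def n_steps(self) -> int:
        return len(self.token_indices)


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES of the largest fragment, or None if unparseable.

    Fragment choice: most heavy atoms, ties broken by lexicographically
    smallest canonical string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        best = min(
            (Chem.MolToSmiles(f) for f in frags),
            key=lambda s: (-Chem.MolFromSmiles(s).GetNumAtoms(), s),
        )
        return best
    return Chem.MolToSmiles(mol)


def standardize_corpus(
    raw_smiles: Sequence[str],
    activities: Sequence[float | None] | None = None,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> list[SmilesRecord]:
    """Parse, desalt, canonicalize, deduplicate and length-filter a corpus.

    Only parseable strings whose canonical form (largest fragment) has
    ``min_length``-``max_length`` characters survive; duplicates (by
    canonical SMILES) keep their first occurrence. Unparseable entries are
    dropped and counted in the log. An empty result is legal.
    """
    if activities is None:
        activities = [None] * len(raw_smiles)
    seen: set[str] = set()
    out: list[SmilesRecord] = []
    n_unparseable = 0
    for raw, act in zip(raw_smiles, activities):
        canonical = canonicalize(raw)
        if canonical is None:
            n_unparseable += 1
            continue
        if not (min_length <= len(canonical) <= max_length):
            continue
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(SmilesRecord(raw=raw, canonical=canonical, activity=act))
    if n_unparseable:
        logger.info("standardize_corpus: dropped %d unparseable strings", n_unparseable)
    return out


def build_vocabulary(records: Sequence[SmilesRecord]) -> Vocabulary:
    """Vocabulary over every token occurring in the corpus, specials first."""
    if not records:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    corpus_tokens: set[str] = set()
    for rec in records:
        corpus_tokens.update(tokenize(rec.canonical))
    ordered = (PAD, START, END) + tuple(sorted(corpus_tokens))
    return Vocabulary(tokens=ordered)


def encode(smiles_or_record: str | SmilesRecord, vocab: Vocabulary) -> EncodedSequence:
    """Token indices of the string plus the end token; N = token count + 1."""
    smiles = (
        smiles_or_record.canonical
        if isinstance(smiles_or_record, SmilesRecord)
        else smiles_or_record
    )
    if not smiles:
        raise ValueError("cannot encode an empty string")
    idx = [vocab.index(t) for t in tokenize(smiles)]
    idx.append(vocab.end_index)
    return EncodedSequence(token_indices=tuple(idx))


def decode(seq: EncodedSequence, vocab: Vocabulary) -> str:
    """Inverse of :func:`encode`: drop the end token, map indices back."""
    toks = []
    for i in seq.token_indices:
        if i == vocab.end_index:
            break
        toks.append(vocab.tokens[i])
    return detokenize(toks)


def build_finetuning_sets(
    records: Sequence[SmilesRecord],
    sizes: Sequence[int] = (5, 10, 20, 40),
    threshold: float = 6.0,
    seed: int = 0,
) -> dict[int, list[SmilesRecord]]:
    """Random fine-tuning sets of molecules with activity strictly above threshold.

    Emulates compiling target-specific sets from an activity table: rows
    with pChEMBL-like activity > ``threshold`` are eligible and each
    requested size is drawn uniformly without replacement, reproducibly
    for a given ``seed``.
    """
    eligible = [r for r in records if r.activity is not None and r.activity > threshold]
    out: dict[int, list[SmilesRecord]] = {}
    for size in sizes:
        if size > len(eligible):
            raise ValueError(
                f"requested fine-tuning set of size {size} but only "
                f"{len(eligible)} records have activity > {threshold} "
                f"(short by {size - len(eligible)})"
            )
        rng = np.random.default_rng([seed, size])
        picks = rng.choice(len(eligible), size=size, replace=False)
        out[size] = [eligible[i] for i in sorted(picks)]
    return out


def train_validation_split(
    records: Sequence[SmilesRecord], validation_fraction: float = 0.05, seed: int = 0
) -> tuple[list[SmilesRecord], list[SmilesRecord]]:
    """Random split for pretraining, 95/5 by default."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_val = int(round(validation_fraction * len(records)))
    val_idx = set(order[:n_val].tolist())
    train = [r for i, r in enumerate(records) if i not in val_idx]
    val = [r for i, r in enumerate(records) if i in val_idx]
    return train, val


def read_smiles_file(path: str) -> tuple[list[str], list[float | None]]:
    """Read one-SMILES-per-line text or a CSV with `smiles`[, `activity`] columns."""
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: CSV must have a 'smiles' column")
        smiles = df["smiles"].astype(str).tolist()
        if "activity" in df.columns:
            acts = [None if pd.isna(a) else float(a) for a in df["activity"]]
        else:
            acts = [None] * len(smiles)
        return smiles, acts
    with open(path) as fh:
        smiles = [line.strip() for line in fh if line.strip()]
    return smiles, [None] * len(smiles)


def write_smiles_file(records: Sequence[SmilesRecord], path: str) -> None:
    if path.endswith(".csv"):
        pd.DataFrame(
            {"smiles": [r.canonical for r in records], "activity": [r.activity for r in records]}
        ).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for r in records:
                fh.write(r.canonical + "\n")
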