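"""Seeded synthetic data: SMILES corpora and enumerable probability models.

The corpus generators build guaranteed-valid SMILES by grammar-level
construction (no rejection on validity), emulating the statistical setting
transfer learning assumes: a broad "pretraining" mixture of structural
families versus narrow single-family "fine-tuning" sets, optionally
annotated with pChEMBL-like activities. They make no attempt to mimic real
screening-library property distributions.

:class:`MarkovCharModel` is a first-order character model whose full
string distribution is exhaustively enumerable, serving as the analytic
oracle for sampling and perplexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .smiles_data import (
    END,
    PAD,
    START,
    SmilesRecord,
    Vocabulary,
    tokenize,
)

FAMILIES = ("alkane", "ether", "aromatic")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: family (or 'mix'), size, length range, seed.

    When ``activity_base`` is set, each record gets a pChEMBL-like value
    ``base + family_offset + N(0, activity_sd)``, so one family can be
    made predominantly "active" (activity > 6) for fine-tuning-set tests.
    """

    family: str = "mix"
    n: int = 100
    length_range: tuple[int, int] = (20, 40)
    seed: int = 0
    activity_base: float | None = None
    activity_offsets: dict = field(
        default_factory=lambda: {"alkane": 0.0, "ether": 2.0, "aromatic": -1.0}
    )
    activity_sd: float = 0.5

    def __post_init__(self):
        if self.family not in FAMILIES + ("mix",):
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.length_range
        if lo > hi or hi < 12:
            raise ValueError(f"infeasible length range {self.length_range}")


def _raw_alkane(rng: np.random.Generator, target: int) -> str:
    """Branched alkane of roughly ``target`` characters."""
    out = ["C", "C"]
    while len("".join(out)) < target:
        if rng.random() < 0.18 and len("".join(out)) + 4 <= target:
            out.append("(" + "C" * int(rng.integers(1, 3)) + ")")
            out.append("C")
        else:
            out.append("C")
    return "".join(out)


def _raw_ether(rng: np.random.Generator, target: int) -> str:
    """Linear polyether chain: C/O with no O-O adjacency by construction."""
    out = ["CC"]
    while len("".join(out)) < target:
        out.append(str(rng.choice(["OCC", "CC", "OC", "CCC"])))
    return "".join(out)


def _raw_aromatic(rng: np.random.Generator, target: int) -> str:
    """Para-substituted benzene with one or two alkyl chains."""
    budget = max(target - 13, 2)
    a = int(rng.integers(1, budget + 1))
    b = budget - a
    left = "C" * a
    right = "C" * b if b > 0 else ""
    if right:
        return f"{left}c1ccc({right})cc1"
    return f"{left}c1ccccc1"


_BUILDERS = {"alkane": _raw_alkane, "ether": _raw_ether, "aromatic": _raw_aromatic}


def generate_corpus(spec: FixtureSpec) -> list[SmilesRecord]:
    """Generate ``spec.n`` distinct, valid, canonical, in-range SMILES records.

    Deterministic for a given seed; every record passes corpus
    standardization unchanged (single fragment, canonical, unique,
    canonical length within the requested range).
    """
    rng = np.random.default_rng([spec.seed, 11])
    lo, hi = spec.length_range
    seen: set[str] = set()
    out: list[SmilesRecord] = []
    attempts = 0
    max_attempts = 500 * spec.n + 1000
    while len(out) < spec.n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not generate {spec.n} distinct in-range strings for "
                f"family {spec.family!r} and length range {spec.length_range}"
            )
        family = (
            str(rng.choice(FAMILIES)) if spec.family == "mix" else spec.family
        )
        target = int(rng.integers(lo, hi + 1))
        raw = _BUILDERS[family](rng, target)
        mol = Chem.MolFromSmiles(raw)
        if mol is None:  # construction guarantees validity; guard anyway
            continue
        canonical = Chem.MolToSmiles(mol)
        if not (lo <= len(canonical) <= hi) or canonical in seen:
            continue
        seen.add(canonical)
        activity = None
        if spec.activity_base is not None:
            activity = float(
                spec.activity_base
                + spec.activity_offsets.get(family, 0.0)
                + rng.normal(0.0, spec.activity_sd)
            )
        out.append(SmilesRecord(raw=raw, canonical=canonical, activity=activity))
    return out


class MarkovCharModel:
    """First-order token model with an exhaustively enumerable distribution.

    Rows of the transition table condition on the previous token (or the
    start state) and give probabilities over corpus tokens plus the end
    token. Exposes the same stepwise interface as the LSTM model so the
    sampling and scoring code runs on it unchanged.
    """

    def __init__(
        self,
        tokens: list[str],
        start_probs: dict[str, float],
        transitions: dict[str, dict[str, float]],
    ):
        self.vocabulary = Vocabulary(tokens=(PAD, START, END) + tuple(tokens))
        V = self.vocabulary.size
        self._table = np.zeros((V, V), dtype=np.float64)

        def fill(row_idx: int, probs: dict[str, float]):
            for tok, p in probs.items():
                col = (
                    self.vocabulary.end_index
                    if tok == END
                    else self.vocabulary.index(tok)
                )
                self._table[row_idx, col] = p
            s = self._table[row_idx].sum()
            if not np.isclose(s, 1.0, atol=1e-9):
                raise ValueError(f"probability row sums to {s}, not 1")

        fill(self.vocabulary.start_index, start_probs)
        for tok, row in transitions.items():
            fill(self.vocabulary.index(tok), row)
        # every non-special token needs an outgoing row (end reachable)
        for tok in tokens:
            i = self.vocabulary.index(tok)
            if self._table[i].sum() == 0:
                raise ValueError(f"no transition row for token {tok!r}")

    # --- stepwise model interface ----------------------------------------
    def init_state(self, batch: int):
        return None

    def step(self, tokens: np.ndarray, state):
        probs = self._table[np.asarray(tokens, dtype=np.int64)]
        return np.log(np.maximum(probs, 1e-300)), None

    def next_token_probabilities(self, prefix) -> np.ndarray:
        last = self.vocabulary.start_index if len(prefix) == 0 else int(prefix[-1])
        return self._table[last].copy()

    # --- exact enumeration -------------------------------------------------
    def string_probability(self, smiles: str) -> float:
        """Exact probability of generating ``smiles`` then terminating."""
        idx = [self.vocabulary.index(t) for t in tokenize(smiles)]
        p = 1.0
        prev = self.vocabulary.start_index
        for i in idx:
            p *= self._table[prev, i]
            prev = i
        return p * self._table[prev, self.vocabulary.end_index]


def enumerate_string_distribution(
    model: MarkovCharModel, max_len: int
) -> dict[str, float]:
    """Exact probability of every terminated string of at most ``max_len`` tokens.

    Only tractable for tiny models (<= 4 non-special tokens, max_len <= 6);
    the probabilities sum to the total termination mass (<= 1). Serves as
    the brute-force oracle for beam search and perplexity.
    """
    vocab = model.vocabulary
    n_tokens = vocab.size - 3
    if n_tokens > 4 or max_len > 6:
        raise ValueError("enumeration is restricted to <=4 tokens and max_len <= 6")
    specials = {vocab.pad_index, vocab.start_index, vocab.end_index}
    token_idx = [i for i in range(vocab.size) if i not in specials]
    out: dict[str, float] = {}

    def walk(prefix: tuple[int, ...], prev: int, p: float):
        p_end = p * model._table[prev, vocab.end_index]
        if p_end > 0:
            out["".join(vocab.tokens[i] for i in prefix)] = p_end
        if len(prefix) == max_len:
            return
        for i in token_idx:
            q = p * model._table[prev, i]
            if q > 0:
                walk(prefix + (i,), i, q)

    walk((), vocab.start_index, 1.0)
    return out
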