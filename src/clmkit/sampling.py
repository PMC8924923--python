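"""Generation of SMILES strings from a fitted model.

Two strategies, matching how chemical language models are deployed:

* multinomial (temperature) sampling — each next token is drawn from the
  temperature-scaled softmax of the model's logits (T = 1 leaves the
  learned distribution untouched);
* beam search — deterministic breadth-limited search keeping the ``k``
  most probable partial strings, scored by raw cumulative log-probability
  (no internal length normalization; perplexity normalizes later).

Both operate on any model exposing ``init_state(batch)`` /
``step(tokens, state)`` and a vocabulary — the LSTM model or the
enumerable Markov models used as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import log_softmax
from .smiles_data import Vocabulary


def get_vocabulary(model) -> Vocabulary:
    vocab = getattr(model, "vocabulary_", None) or getattr(model, "vocabulary", None)
    if vocab is None:
        raise ValueError("model has no vocabulary")
    return vocab


def temperature_softmax(logits: np.ndarray, T: float = 1.0) -> np.ndarray:
    """``p_i = exp(z_i / T) / sum_j exp(z_j / T)``, computed stably.

    T = 1 recovers the plain softmax; T -> 0 sharpens towards the argmax
    (that limit is served by greedy/beam decoding, so T must be positive).
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    z = np.asarray(logits, dtype=np.float64) / T
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


@dataclass(frozen=True)
class SampledString:
    smiles: str
    log_prob: float
    terminated: bool


@dataclass
class SamplingRun:
    """A batch of generated strings plus the generation metadata."""

    method: str  # "multinomial" | "beam"
    strings: list[SampledString]
    max_length: int
    temperature: float | None = None
    beam_width: int | None = None
    seed: int | None = None
    epoch: int | None = None
    warning: str | None = None

    @property
    def smiles(self) -> list[str]:
        return [s.smiles for s in self.strings]

    def terminated_smiles(self) -> list[str]:
        return [s.smiles for s in self.strings if s.terminated]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": [s.smiles for s in self.strings],
                "log_prob": [s.log_prob for s in self.strings],
                "terminated": [s.terminated for s in self.strings],
                "method": self.method,
                "epoch": self.epoch,
                "seed": self.seed,
            }
        )


def _select_state(state, idx):
    if state is None:
        return None
    if isinstance(state, tuple):
        return tuple(_select_state(s, idx) for s in state)
    return state[idx]


def _mask_specials(logits: np.ndarray, vocab: Vocabulary) -> np.ndarray:
    """Forbid pad and start tokens during generation (never legal outputs)."""
    out = np.array(logits, dtype=np.float64, copy=True)
    out[..., vocab.pad_index] = -np.inf
    out[..., vocab.start_index] = -np.inf
    return out


def sample_multinomial(
    model,
    n: int,
    T: float = 1.0,
    max_length: int = 90,
    seed: int = 0,
    epoch: int | None = None,
) -> SamplingRun:
    """Draw ``n`` strings token-by-token from the temperature softmax.

    Generation stops at the end token or after ``max_length`` tokens;
    strings hitting the cap are flagged unterminated. The recorded
    log-probability is the sum of log p over drawn tokens (end included).
    Reproducible for a given ``seed``; duplicates are retained.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vocab = get_vocabulary(model)
    rng = np.random.default_rng(seed)
    state = model.init_state(n)
    current = np.full(n, vocab.start_index, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    logp_total = np.zeros(n, dtype=np.float64)
    token_lists: list[list[int]] = [[] for _ in range(n)]
    for _ in range(max_length):
        logits, state = model.step(current, state)
        p = temperature_softmax(_mask_specials(logits, vocab), T)
        u = rng.random((n, 1))
        drawn = (np.cumsum(p, axis=1) < u).sum(axis=1)
        drawn = np.minimum(drawn, p.shape[1] - 1)
        step_logp = np.log(np.maximum(p[np.arange(n), drawn], 1e-300))
        for b in np.nonzero(alive)[0]:
            logp_total[b] += step_logp[b]
            if drawn[b] == vocab.end_index:
                alive[b] = False
            else:
                token_lists[b].append(int(drawn[b]))
        current = np.where(alive, drawn, vocab.end_index)
        if not alive.any():
            break
    strings = [
        SampledString(
            smiles="".join(vocab.tokens[i] for i in toks),
            log_prob=float(logp_total[b]),
            terminated=not alive[b],
        )
        for b, toks in enumerate(token_lists)
    ]
    return SamplingRun(
        method="multinomial",
        strings=strings,
        max_length=max_length,
        temperature=T,
        seed=seed,
        epoch=epoch,
    )


def sample_beam(
    model,
    k: int,
    max_length: int = 90,
    epoch: int | None = None,
) -> SamplingRun:
    """Length-synchronous beam search over cumulative log-probability.

    At each length step the ``k`` best live prefixes are each extended by
    every vocabulary token; hypotheses emitting the end token are set
    aside and no longer extended. Up to ``k`` terminated strings are
    returned sorted by descending total log-probability. Ties are broken
    by lexicographic order of the token-index sequence, so the search is
    fully deterministic; ``k = 1`` is greedy argmax decoding.
    """
    if k < 1:
        raise ValueError("beam width k must be >= 1")
    vocab = get_vocabulary(model)
    V = vocab.size
    # live beams: token tuples + cumulative log-probability + stacked states
    beams: list[tuple[int, ...]] = [()]
    beam_logp = np.zeros(1, dtype=np.float64)
    state = model.init_state(1)
    current = np.full(1, vocab.start_index, dtype=np.int64)
    finished: list[tuple[float, tuple[int, ...]]] = []
    for _ in range(max_length):
        logits, state = model.step(current, state)
        logp = log_softmax(_mask_specials(logits, vocab))
        cand = beam_logp[:, None] + logp  # (n_beams, V)
        entries = []  # (-logp, tokens, parent, token)
        for b, toks in enumerate(beams):
            for v in range(V):
                lp = cand[b, v]
                if not np.isfinite(lp):
                    continue
                if v == vocab.end_index:
                    finished.append((lp, toks))
                else:
                    entries.append((-lp, toks + (v,), b, v))
        if not entries:
            break
        entries.sort(key=lambda e: (e[0], e[1]))
        entries = entries[:k]
        parents = np.array([e[2] for e in entries], dtype=np.int64)
        beams = [e[1] for e in entries]
        beam_logp = np.array([-e[0] for e in entries], dtype=np.float64)
        state = _select_state(state, parents)
        current = np.array([e[3] for e in entries], dtype=np.int64)
    finished.sort(key=lambda f: (-f[0], f[1]))
    finished = finished[:k]
    strings = [
        SampledString(
            smiles="".join(vocab.tokens[i] for i in toks),
            log_prob=float(lp),
            terminated=True,
        )
        for lp, toks in finished
    ]
    return SamplingRun(
        method="beam",
        strings=strings,
        max_length=max_length,
        beam_width=k,
        epoch=epoch,
        warning=None if strings else "no hypothesis terminated within max_length",
    )
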