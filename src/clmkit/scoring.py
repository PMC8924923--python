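"""Perplexity scoring, ranking, and the delta (pretraining-bias) score.

For a tokenized SMILES string with N prediction steps (its tokens plus the
terminating end token) and model probabilities p_i of the true i-th token,

    PP = exp( -(1/N) * sum_i ln p_i )

so PP = 1 for a perfectly confident correct model and PP = V under a
uniform model over V tokens; low perplexity is desirable. Ranking a
molecule set under the fine-tuned and the pretrained model gives per-
molecule ranks rank_ft and rank_pt (rank 1 = lowest perplexity), and

    delta = rank_pt - rank_ft

so a positive delta marks a molecule the fine-tuned model favours and a
negative delta flags pretraining bias: the molecule is more plausible
under the generic pretrained model than under the task-tuned one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampling import get_vocabulary
from .smiles_data import canonicalize, encode

logger = logging.getLogger(__name__)

LOGP_FLOOR = math.log(1e-30)


def _sequence_log_probs(model, sequences):
    """Per-step log-probabilities of the true tokens, via the model's batched
    path when it has one, otherwise through the stepwise interface."""
    if hasattr(model, "sequence_log_probs"):
        return model.sequence_log_probs(sequences)
    vocab = get_vocabulary(model)
    out = []
    for seq in sequences:
        state = model.init_state(1)
        current = np.array([vocab.start_index], dtype=np.int64)
        logps = np.empty(len(seq))
        for i, tok in enumerate(seq):
            logits, state = model.step(current, state)
            z = np.asarray(logits[0], dtype=np.float64)
            z = z - z.max()
            logps[i] = z[tok] - np.log(np.exp(z).sum())
            current = np.array([tok], dtype=np.int64)
        out.append(logps)
    return out


def perplexity(model, smiles: str) -> float:
    """Perplexity of one SMILES string under a fitted model."""
    return perplexities(model, [smiles])[0]


def perplexities(model, molecules: list[str]) -> np.ndarray:
    """Vectorized perplexity; per-step log-probabilities floored at ln(1e-30).

    Underflow past the floor is logged rather than raised, so a string the
    model finds impossible scores as a very large finite value instead of
    crashing the analysis.
    """
    vocab = get_vocabulary(model)
    seqs = [encode(s, vocab).token_indices for s in molecules]
    logps = _sequence_log_probs(model, seqs)
    out = np.empty(len(seqs))
    n_floored = 0
    for i, lp in enumerate(logps):
        n_floored += int((lp < LOGP_FLOOR).sum())
        lp = np.maximum(lp, LOGP_FLOOR)
        out[i] = math.exp(-float(lp.mean()))
    if n_floored:
        logger.info("perplexities: floored %d per-step log-probabilities", n_floored)
    return out


@dataclass(frozen=True)
class ScoredMolecule:
    """A molecule scored under a fine-tuned and a pretrained checkpoint."""

    smiles: str
    perplexity_ft: float
    perplexity_pt: float
    rank_ft: int
    rank_pt: int
    valid: bool = True

    @property
    def delta(self) -> int:
        return self.rank_pt - self.rank_ft


def _dedupe(molecules: list[str], include_invalid: bool) -> tuple[list[str], list[bool]]:
    """Deduplicate by canonical SMILES (first occurrence wins); invalid
    strings are dropped unless ``include_invalid``, in which case they are
    kept keyed by their raw text."""
    seen: set[str] = set()
    kept: list[str] = []
    valid: list[bool] = []
    for s in molecules:
        canonical = canonicalize(s)
        if canonical is None:
            if not include_invalid:
                continue
            key, out_s, ok = s, s, False
        else:
            key, out_s, ok = canonical, canonical, True
        if key in seen:
            continue
        seen.add(key)
        kept.append(out_s)
        valid.append(ok)
    return kept, valid


def _ranks(ppls: np.ndarray, keys: list[str]) -> np.ndarray:
    """Rank 1 = lowest perplexity; ties broken by lexicographic SMILES."""
    order = sorted(range(len(ppls)), key=lambda i: (ppls[i], keys[i]))
    ranks = np.empty(len(ppls), dtype=np.int64)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def rank_by_perplexity(
    model, molecules: list[str], include_invalid: bool = False
) -> list[tuple[str, float, int]]:
    """Score and rank a molecule set; returns (smiles, perplexity, rank) in rank order."""
    kept, _ = _dedupe(molecules, include_invalid)
    if not kept:
        raise ValueError("no scoreable molecules (all invalid or empty input)")
    ppls = perplexities(model, kept)
    ranks = _ranks(ppls, kept)
    rows = [(kept[i], float(ppls[i]), int(ranks[i])) for i in range(len(kept))]
    rows.sort(key=lambda r: r[2])
    return rows


def delta_scores(
    pt_model, ft_model, molecules: list[str], include_invalid: bool = False
) -> list[ScoredMolecule]:
    """Rank the set under both checkpoints independently; delta = rank_pt - rank_ft.

    Both models must share a vocabulary. Ranks are each a permutation of
    1..n, so deltas always sum to zero over the set.
    """
    if get_vocabulary(pt_model).tokens != get_vocabulary(ft_model).tokens:
        raise ValueError("pretrained and fine-tuned models must share a vocabulary")
    kept, valid = _dedupe(molecules, include_invalid)
    if not kept:
        raise ValueError("no scoreable molecules (all invalid or empty input)")
    ppl_pt = perplexities(pt_model, kept)
    ppl_ft = perplexities(ft_model, kept)
    rank_pt = _ranks(ppl_pt, kept)
    rank_ft = _ranks(ppl_ft, kept)
    return [
        ScoredMolecule(
            smiles=kept[i],
            perplexity_ft=float(ppl_ft[i]),
            perplexity_pt=float(ppl_pt[i]),
            rank_ft=int(rank_ft[i]),
            rank_pt=int(rank_pt[i]),
            valid=valid[i],
        )
        for i in range(len(kept))
    ]


def negative_delta_fraction(scored: list[ScoredMolecule]) -> float:
    """Fraction of molecules with strictly negative delta (pretraining bias)."""
    if not scored:
        raise ValueError("empty scored set")
    return sum(1 for s in scored if s.delta < 0) / len(scored)


def scored_to_dataframe(scored: list[ScoredMolecule]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smiles": [s.smiles for s in scored],
            "perplexity_ft": [s.perplexity_ft for s in scored],
            "perplexity_pt": [s.perplexity_pt for s in scored],
            "rank_ft": [s.rank_ft for s in scored],
            "rank_pt": [s.rank_pt for s in scored],
            "delta": [s.delta for s in scored],
            "valid": [s.valid for s in scored],
        }
    )


def bias_curve(pt_model, ft_models, samples_per_epoch) -> pd.DataFrame:
    """Per-epoch negative-delta fractions for fine-tuning snapshots.

    ``samples_per_epoch`` maps each fine-tuned snapshot (by position) to
    the strings sampled from it; rows are (epoch, n_scored,
    neg_delta_fraction).
    """
    rows = []
    for ft, strings in zip(ft_models, samples_per_epoch):
        scored = delta_scores(pt_model, ft, strings)
        rows.append(
            {
                "epoch": getattr(ft, "epoch_", None),
                "n_scored": len(scored),
                "neg_delta_fraction": negative_delta_fraction(scored),
            }
        )
    return pd.DataFrame(rows)
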