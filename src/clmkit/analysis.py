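"""Validity, fingerprint-distance and correlation analyses of generated sets.

Chemical relevance of the perplexity score is assessed by correlating it
with structural distance to the fine-tuning set: Tanimoto distance
(1 - similarity) on Morgan fingerprints (radius 2, 1024 bits; common
substructures) and on Gobbi-Poppinger 2D pharmacophore fingerprints
(shared pharmacophoric motifs). Sampling strategies are compared by the
perplexity of their top-scoring molecules, optionally after filtering out
designs within 50% Morgan similarity of the fine-tuning set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate as Pharm2DGenerate
from rdkit.Chem.Pharm2D import Gobbi_Pharm2D
from scipy import stats

from .scoring import delta_scores, negative_delta_fraction, perplexities
from .smiles_data import canonicalize

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def validity(strings: list[str]) -> float:
    """Fraction of strings RDKit parses into molecules."""
    if not strings:
        raise ValueError("empty string list")
    ok = sum(1 for s in strings if Chem.MolFromSmiles(s) is not None)
    return ok / len(strings)


def fingerprint(smiles: str, kind: str = "morgan"):
    """Fingerprint of one molecule: 'morgan' (1024-bit, radius 2) or 'ph4'
    (Gobbi-Poppinger 2D pharmacophore, sparse)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot fingerprint invalid SMILES {smiles!r}")
    if kind == "morgan":
        return _MORGAN.GetFingerprint(mol)
    if kind == "ph4":
        return Pharm2DGenerate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory)
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def tanimoto_distance(fp_a, fp_b) -> float:
    """1 - Tanimoto similarity; identical fingerprints give 0, disjoint 1.

    Two all-zero fingerprints are treated as identical (distance 0, with a
    warning) rather than undefined.
    """
    if fp_a.GetNumOnBits() == 0 and fp_b.GetNumOnBits() == 0:
        warnings.warn("both fingerprints empty; defining distance as 0")
        return 0.0
    return 1.0 - DataStructs.TanimotoSimilarity(fp_a, fp_b)


def _set_fingerprints(smiles_set: list[str], kind: str):
    return [fingerprint(s, kind) for s in smiles_set]


def distances_to_set(mol: str, reference_set: list[str], kind: str = "morgan") -> np.ndarray:
    if not reference_set:
        raise ValueError("reference set is empty")
    fp = fingerprint(mol, kind)
    refs = _set_fingerprints(reference_set, kind)
    return np.array([tanimoto_distance(fp, r) for r in refs])


def min_distance_to_set(mol: str, reference_set: list[str], kind: str = "morgan") -> float:
    """Distance to the closest molecule of the set (0 if the molecule is in it)."""
    return float(distances_to_set(mol, reference_set, kind).min())


def mean_distance_to_set(mol: str, reference_set: list[str], kind: str = "morgan") -> float:
    """Mean distance to all set members — the 'average distance' correlated
    with perplexity."""
    return float(distances_to_set(mol, reference_set, kind).mean())


def perplexity_distance_correlation(pairs) -> float:
    """Pearson correlation between perplexity and mean fingerprint distance.

    ``pairs`` is a sequence of (perplexity, mean_distance). Returns NaN
    (with a warning) when either variable is constant.
    """
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (perplexity, distance) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class SamplerComparison:
    """Top-k perplexity summary of a multinomial run vs a beam run."""

    top_multinomial: list[tuple[str, float]]
    top_beam: list[tuple[str, float]]
    multinomial_wins: bool | None  # None = tie or a side has no candidates
    truncated: bool


def _unique_valid(strings: list[str]) -> list[str]:
    seen, out = set(), []
    for s in strings:
        c = canonicalize(s)
        if c is None or c in seen:
            continue
        seen.add(c)
        out.append(c)
    return out


def compare_samplers(
    model,
    multinomial_run,
    beam_run,
    top_k: int = 50,
    fine_tuning_set: list[str] | None = None,
    min_distance: float = 0.5,
) -> SamplerComparison:
    """Perplexity of the top-k unique valid molecules from each strategy.

    With ``fine_tuning_set`` given, molecules within ``1 - min_distance``
    Morgan similarity of the closest set member are filtered out first
    (the diversity-constrained variant). The win indicator is True when
    the multinomial best perplexity is strictly lower than the beam best,
    False when strictly higher, None on ties or when either side is empty.
    """

    def top(run):
        mols = _unique_valid(run.terminated_smiles())
        if fine_tuning_set is not None:
            mols = [
                m for m in mols if min_distance_to_set(m, fine_tuning_set) > min_distance
            ]
        if not mols:
            return [], False
        ppl = perplexities(model, mols)
        order = np.argsort(ppl, kind="stable")[:top_k]
        return [(mols[i], float(ppl[i])) for i in order], len(mols) < top_k

    top_m, trunc_m = top(multinomial_run)
    top_b, trunc_b = top(beam_run)
    if not top_m or not top_b:
        wins = None
    elif top_m[0][1] < top_b[0][1]:
        wins = True
    elif top_m[0][1] > top_b[0][1]:
        wins = False
    else:
        wins = None
    return SamplerComparison(
        top_multinomial=top_m,
        top_beam=top_b,
        multinomial_wins=wins,
        truncated=trunc_m or trunc_b,
    )


def epoch_summary(
    epoch: int,
    sampled_strings: list[str],
    fine_tuning_set: list[str],
    ft_model,
    pt_model,
    top_k: int = 50,
) -> dict:
    """One row of the per-epoch analysis table.

    Validity of the raw sample, mean Morgan/pharmacophore distance of the
    unique valid molecules to the fine-tuning set, Pearson correlation of
    perplexity with each distance, the negative-delta fraction against the
    pretrained model, and the top-k perplexities.
    """
    out = {"epoch": epoch, "validity": validity(sampled_strings)}
    mols = _unique_valid(sampled_strings)
    ppl = perplexities(ft_model, mols)
    for kind, label in (("morgan", "morgan"), ("ph4", "ph4")):
        dists = np.array([mean_distance_to_set(m, fine_tuning_set, kind) for m in mols])
        out[f"mean_distance_{label}"] = float(dists.mean())
        out[f"pearson_{label}"] = perplexity_distance_correlation(zip(ppl, dists))
    scored = delta_scores(pt_model, ft_model, mols)
    out["neg_delta_fraction"] = negative_delta_fraction(scored)
    order = np.argsort(ppl, kind="stable")[:top_k]
    out["topk_perplexities"] = [float(ppl[i]) for i in order]
    return out


def summary_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
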