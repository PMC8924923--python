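"""Desk-scale end-to-end experiments on synthetic corpora.

These pipelines reproduce, at laptop scale, the study design the toolkit
supports at full scale: pretrain a reduced CLM on a mixed-family synthetic
corpus, fine-tune it on a handful of molecules from one family, sample
during fine-tuning, and measure validity and delta-score bias signals.
Problem sizes (5,000-string corpus, 64/32-unit model, 10 pretraining and
20 fine-tuning epochs, 1,000 samples every second epoch) are the package's
desk-scale defaults. The optimizer settings are likewise scaled to the
regime: Adam at 2e-3 with batches of 32 for pretraining (the full-scale
1e-4/128 belongs to the million-string regime) and a gentler 5e-4 for
fine-tuning, where each epoch is a single 5-40-string batch.
"""

from __future__ import annotations

import pandas as pd

from .analysis import validity
from .clm_model import SmilesLSTM
from .fixtures import FixtureSpec, generate_corpus
from .sampling import sample_multinomial
from .scoring import delta_scores, scored_to_dataframe


def validity_experiment(
    seed: int = 1,
    corpus_size: int = 5000,
    lstm1_units: int = 64,
    lstm2_units: int = 32,
    pretrain_epochs: int = 10,
    finetune_epochs: int = 20,
    sample_every: int = 2,
    n_samples: int = 1000,
    finetune_size: int = 5,
    learning_rate: float = 2e-3,
    finetune_learning_rate: float = 5e-4,
    batch_size: int = 32,
    temperature: float = 1.0,
) -> pd.DataFrame:
    """Per-fine-tuning-epoch SMILES validity of multinomial samples.

    Pretrains a reduced CLM on a seeded mixed-family corpus, fine-tunes on
    a single-family (ether) set, samples ``n_samples`` strings at T=1 after
    every ``sample_every`` epochs, and parses each sample. Returns a frame
    with columns ``epoch, n_sampled, validity``.
    """
    corpus = generate_corpus(FixtureSpec(family="mix", n=corpus_size, seed=seed))
    model = SmilesLSTM(
        lstm1_units=lstm1_units,
        lstm2_units=lstm2_units,
        learning_rate=learning_rate,
        epochs=pretrain_epochs,
        batch_size=batch_size,
        random_state=seed,
    ).fit([r.canonical for r in corpus])
    ft_records = generate_corpus(
        FixtureSpec(family="ether", n=finetune_size, seed=seed + 1000)
    )
    snapshots = model.finetune(
        [r.canonical for r in ft_records],
        epochs=finetune_epochs,
        sample_every=sample_every,
        learning_rate=finetune_learning_rate,
    )
    rows = []
    for i, snap in enumerate(snapshots):
        run = sample_multinomial(
            snap, n=n_samples, T=temperature, max_length=90, seed=seed + 17 + i
        )
        rows.append(
            {
                "epoch": snap.epoch_,
                "n_sampled": len(run.strings),
                "validity": validity(run.smiles),
            }
        )
    return pd.DataFrame(rows)


def bias_experiment(
    seed: int = 1,
    corpus_size: int = 1500,
    lstm1_units: int = 64,
    lstm2_units: int = 32,
    pretrain_epochs: int = 8,
    finetune_epochs: int = 20,
    finetune_size: int = 8,
    heldout_size: int = 100,
    learning_rate: float = 2e-3,
    finetune_learning_rate: float = 5e-4,
    batch_size: int = 32,
):
    """Delta-score recovery of a planted fine-tuning family.

    Fine-tunes a mixture-pretrained CLM on ether-family molecules, then
    scores held-out ethers (in-family) and alkanes/aromatics (out-of-
    family) under both checkpoints. If the delta score detects pretraining
    bias, in-family molecules should carry positive mean delta and
    out-of-family molecules negative mean delta.

    Returns ``(mean_delta_in_family, mean_delta_out_family, scored_frame)``.
    """
    corpus = generate_corpus(FixtureSpec(family="mix", n=corpus_size, seed=seed))
    pt = SmilesLSTM(
        lstm1_units=lstm1_units,
        lstm2_units=lstm2_units,
        learning_rate=learning_rate,
        epochs=pretrain_epochs,
        batch_size=batch_size,
        random_state=seed,
    ).fit([r.canonical for r in corpus])
    ft_records = generate_corpus(
        FixtureSpec(family="ether", n=finetune_size, seed=seed + 2000)
    )
    ft = pt.finetune(
        [r.canonical for r in ft_records],
        epochs=finetune_epochs,
        sample_every=finetune_epochs,
        learning_rate=finetune_learning_rate,
    )[-1]
    in_family = generate_corpus(
        FixtureSpec(family="ether", n=heldout_size, seed=seed + 3000)
    )
    out_alkane = generate_corpus(
        FixtureSpec(family="alkane", n=heldout_size // 2, seed=seed + 4000)
    )
    out_arom = generate_corpus(
        FixtureSpec(family="aromatic", n=heldout_size // 2, seed=seed + 5000)
    )
    in_set = {r.canonical for r in in_family}
    mols = [r.canonical for r in in_family + out_alkane + out_arom]
    scored = delta_scores(pt, ft, mols)
    df = scored_to_dataframe(scored)
    df["in_family"] = [s.smiles in in_set for s in scored]
    mean_in = float(df.loc[df.in_family, "delta"].mean())
    mean_out = float(df.loc[~df.in_family, "delta"].mean())
    return mean_in, mean_out, df
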