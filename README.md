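# clmkit

Chemical language models (CLMs) generate candidate molecules as SMILES
strings, one character at a time, after pretraining on a large generic
corpus and fine-tuning on a handful of known actives. Two practical
questions follow: *which of the thousands of generated strings should a
chemist look at first*, and *how much of what the model generates is
driven by the generic pretraining corpus rather than the design
objective?* `clmkit` is a toolkit for both, aimed at computational
chemists running low-data de novo design campaigns.

## The scores

For a tokenized SMILES string with `N` prediction steps (its tokens plus
the terminating end symbol) and model probabilities `p_i` of the true
`i`-th token, the **perplexity** under a model is

```
PP = exp( -(1/N) * sum_{i=1..N} ln p_i )
```

`PP = 1` for a perfectly confident correct model, `PP = V` (the
vocabulary size) under a uniform model; low perplexity means the string
matches what the model has learned. Ranking a generated set by
perplexity under the fine-tuned model (`rank_ft`, rank 1 = lowest) and
under the pretrained model (`rank_pt`) gives the **delta score**

```
delta = rank_pt - rank_ft
```

A positive delta marks a molecule the fine-tuned model favours; a
negative delta flags **pretraining bias** — the molecule is more
plausible under the generic pretrained model than under the task-tuned
one, so it likely does not reflect the design objective.

The model itself is an LSTM network (batch normalization → LSTM 1024 →
LSTM 256 → batch normalization → per-step softmax over the vocabulary;
5,820,515 parameters at a 71-symbol vocabulary), trained by
next-character prediction and implemented here in NumPy with full
backpropagation through time. Generation is by multinomial sampling from
the temperature softmax `p_i = exp(z_i/T) / sum_j exp(z_j/T)` (default
`T = 1`) or by deterministic beam search of width `k`.

## Worked example

Everything runs on seeded synthetic corpora — no downloads. The snippet
pretrains a reduced model on a mixed-family corpus, fine-tunes it on
five polyether molecules, then samples and scores:

```python
from clmkit import (FixtureSpec, generate_corpus, SmilesLSTM, sample_multinomial,
                    delta_scores, negative_delta_fraction, validity, rank_by_perplexity)

corpus = generate_corpus(FixtureSpec(family="mix", n=1000, seed=0))
pt = SmilesLSTM(lstm1_units=64, lstm2_units=32, learning_rate=2e-3,
                epochs=8, batch_size=32, random_state=0)
pt.fit([r.canonical for r in corpus])

ft_set = [r.canonical for r in generate_corpus(FixtureSpec(family="ether", n=5, seed=100))]
ft = pt.finetune(ft_set, epochs=20, sample_every=20, learning_rate=5e-4)[-1]

run = sample_multinomial(ft, n=200, T=1.0, seed=7)
print(f"validity: {validity(run.smiles):.3f}")

scored = delta_scores(pt, ft, run.smiles)
print(f"scored molecules: {len(scored)}")
print(f"negative-delta fraction: {negative_delta_fraction(scored):.3f}")
for s, ppl, rank in rank_by_perplexity(ft, run.smiles)[:3]:
    print(f"rank {rank}: {s}  (perplexity {ppl:.3f})")
```

Output:

```
validity: 0.970
scored molecules: 194
negative-delta fraction: 0.418
rank 1: CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCOCC  (perplexity 1.181)
rank 2: CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC  (perplexity 1.184)
rank 3: CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCOCC  (perplexity 1.201)
```

97% of the samples parse as molecules; the 200 samples collapse to 194
unique valid structures; 41.8% of them carry a negative delta — they are
still explained better by the generic pretrained model than by the
five-molecule objective — and the best-ranked strings are ether-like
chains, matching the fine-tuning family.

The same workflow is available from the shell via the `clm` command
(`clm preprocess`, `clm fixtures`, `clm pretrain`, `clm finetune`,
`clm sample`, `clm score`, `clm bias-report`, `clm analyze`).

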