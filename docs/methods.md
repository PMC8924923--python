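# Methods

## Model

The chemical language model is an autoregressive next-token model over
tokenized SMILES strings. Architecture, in order: batch normalization of
the one-hot input, an LSTM with 1024 units, an LSTM with 256 units,
batch normalization, and a per-step dense softmax over the vocabulary.
Counting batch-normalization scale, offset and both moving statistics,
the total parameter count is

```
4V + 4(1024(V+1024) + 1024) + 4(256(1024+256) + 256) + 4*256 + 257V
  = 4357 V + 5,511,168
```

which equals 5,820,515 at a one-hot dimension of V = 71. The network is
implemented in NumPy (`clmkit._nn`) with full backpropagation through
time; no deep-learning framework is used. Arithmetic is float32; gate
order is input/forget/cell/output with forget-gate bias initialized to
1, Glorot-uniform input weights, and per-gate orthogonal recurrent
weights.

Training minimizes per-step categorical cross-entropy of the next token
under teacher forcing, with sequences padded to the batch maximum and
padded steps excluded from the loss, from the batch-normalization
statistics, and from N. The optimizer is Adam (eps 1e-8) with global
gradient-norm clipping at 5. Full-scale defaults target the
million-string regime (learning rate 1e-4, batch 128, 90 pretraining epochs, 100
fine-tuning epochs with snapshots every second epoch); see "Desk-scale
configuration" for the reduced defaults actually exercised here.

Batch normalization uses eps 1e-3 and momentum 0.9 for the moving
statistics; momentum 0.9 (rather than a slower 0.99) lets the moving
statistics converge within the few hundred gradient steps of a reduced
run, keeping train-mode and inference-mode behaviour consistent. During
fine-tuning the statistics are frozen by default (`freeze_batchnorm`):
a fine-tuning batch of 5-40 sequences yields degenerate batch
statistics, and letting them overwrite the pretrained moving averages
destabilizes subsequent sampling; the scale/offset parameters keep
training. This is the one deliberate departure from plain continued
training, and it is switchable.

## Tokenization and data handling

SMILES are tokenized character-by-character with the two-letter
organic-subset halogens `Cl` and `Br` merged into single tokens;
bracket-atom characters are individual tokens. The split is lossless,
so tokenize/detokenize round-trips exactly. The vocabulary orders
specials first (pad, start, end) and corpus tokens sorted, fixing the
one-hot dimension deterministically. A sequence's prediction-step count
N includes the end token and excludes the start token: including the
end step makes perplexity sensitive to premature-termination
probability, which a generation task must penalize.

Corpus standardization parses with RDKit, keeps the largest fragment of
multi-fragment (salt) entries (ties by lexicographically smallest
canonical SMILES), canonicalizes, deduplicates by canonical string
keeping first occurrence, and retains canonical strings of 20-90
characters. The length filter applies to the canonical string's
character count. Standardization is idempotent. Fine-tuning sets are
drawn uniformly without replacement from rows with activity strictly
greater than the threshold (default 6, pChEMBL-like), reproducibly per
seed, in sizes 5/10/20/40 by default.

## Sampling

Multinomial sampling draws each next token from the temperature softmax
of the model's logits (computed with max-subtraction; T must be > 0 —
the T→0 limit is greedy decoding, not a temperature). Pad and start
tokens are masked out of the generation distribution (they are never
legal outputs); scoring, by contrast, always uses the full
distribution. Strings that reach `max_length` (default 90, mirroring
the corpus ceiling) without an end token are flagged unterminated and
excluded from ranking analyses by default. Duplicates are retained in a
run and collapsed only where an analysis requires unique molecules.

Beam search is length-synchronous over raw cumulative log-probability —
no internal length normalization, since perplexity applies the length
normalization afterwards. Terminated hypotheses are set aside and no
longer extended; up to k strings are returned sorted by descending
log-probability, with exact ties broken by lexicographic order of the
token-index sequence so results are fully deterministic. Width k=1 is
greedy argmax decoding.

## Scoring

Perplexity is computed in the log domain; per-step log-probabilities
are floored at ln(1e-30), with flooring events logged, so "impossible"
strings score as very large finite values rather than crashing.
Ranking: molecules are deduplicated by canonical SMILES (the canonical
form is what gets scored, consistent with canonical training corpora),
rank 1 is the lowest perplexity, ties break lexicographically. Invalid
strings are excluded from ranking and delta analyses by default
(`include_invalid` retains them, keyed and scored by their raw text).
delta = rank_pt − rank_ft, so positive delta = favoured by fine-tuning;
ranks are permutations of 1..n under both models, hence deltas sum to
zero exactly over any scored set.

## Analyses

Structural relevance uses Morgan fingerprints (radius 2, 1024 bits) and
Gobbi-Poppinger 2D pharmacophore fingerprints, converted to Tanimoto
distances (1 − similarity; two empty fingerprints are defined as
distance 0 with a warning). A molecule's "average distance" to the
fine-tuning set is its mean distance over all set members; the
per-epoch correlation of perplexity with that distance is Pearson's r
(flagged NaN for constant inputs). Sampler comparison takes each
method's top-k (default 50) lowest-perplexity unique valid molecules,
optionally after removing designs within 50% Morgan similarity of the
closest fine-tuning molecule; the win indicator compares best
perplexities strictly and is antisymmetric under swapping the runs.

## Synthetic data

The fixture generator builds guaranteed-valid SMILES by grammar-level
construction (never rejection on validity): branched alkanes, linear
polyethers with no O-O adjacency, and para-substituted alkylbenzenes,
each canonicalized and kept only if the canonical length falls in the
requested range (default 20-40 characters), deduplicated, and
seed-reproducible. The "mix" family draws the three families uniformly,
emulating a broad pretraining distribution; single families emulate
narrow fine-tuning objectives. An optional activity model (base +
family offset + Gaussian noise, defaults 5.0 / {ether +2, alkane 0,
aromatic −1} / sd 0.5) makes one family predominantly "active" for
fine-tuning-set construction. These fixtures deliberately do not mimic
real screening-library property distributions, stereochemistry, charged
species or ring-system diversity — passing tests demonstrates the
machinery (training, sampling, scoring, bias detection) on data with
the right statistical shape, not performance on drug-like chemistry.

First-order Markov character models with explicit transition tables
provide exact oracles: their full string distribution is enumerable for
tiny vocabularies, giving brute-force references for beam search and
product-form references for perplexity.

## Desk-scale configuration

The end-to-end experiments (`clmkit.experiments`) run a reduced model:
64/32 LSTM units, 5,000-string mixture corpus, 10 pretraining epochs,
a 5-string ether fine-tuning set, 20 fine-tuning epochs with 1,000
multinomial samples at T=1 every second epoch. Optimizer settings are
scaled to that regime: Adam at 2e-3 with batches of 32 for pretraining,
5e-4 for fine-tuning (each fine-tuning epoch is a single small batch).
The bias-recovery experiment uses a 1,500-string corpus, 8 pretraining
epochs, an 8-string fine-tuning set and 100 held-out molecules per
side, asserting only the direction of the mean delta (in-family
positive, out-of-family negative), not its magnitude.

## Numerical and degenerate-case choices

- Checkpoints are NumPy archives of all parameter arrays (moving
  statistics included) plus vocabulary and provenance JSON; reloading
  reproduces probabilities bit-for-bit on the same platform.
- Determinism: every stochastic component (initialization, batch
  shuffling, sampling, set selection) takes an explicit seed; identical
  seeds give identical results.
- An empty standardized corpus is a legal result (no survivors); an
  empty vocabulary, empty string to encode, or out-of-vocabulary token
  is an error naming the offender.
- Beam search that never terminates within `max_length` returns an
  empty run with a warning flag rather than failing.

## Known limitations

- The NumPy implementation targets CPU desk scale; million-string
  pretraining of the 1024/256 network is out of its intended range.
- Fine-tuning snapshots are deep copies; for very large models a
  disk-backed snapshot scheme would be preferable.
- Scoring operates on canonical SMILES; perplexity of non-canonical
  writings of the same molecule is not aggregated (no augmentation).
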