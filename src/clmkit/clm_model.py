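"""The LSTM chemical language model (CLM).

A CLM is an autoregressive next-token model over tokenized SMILES strings:
batch normalization of the one-hot input, two stacked LSTM layers (1024 and
256 units by default), batch normalization, and a per-step dense softmax
over the vocabulary. With a 71-symbol vocabulary the default architecture
has exactly 5,820,515 parameters (including batch-normalization moving
statistics), i.e. ``4357 * V + 5,511,168``.

:class:`SmilesLSTM` follows scikit-learn estimator conventions: hyper-
parameters in ``__init__``, training via :meth:`fit` (pretraining) and
:meth:`finetune` (transfer learning on a small task-specific set), fitted
state in trailing-underscore attributes, and ``get_params``/``set_params``
from ``BaseEstimator``. Module-level :func:`pretrain` / :func:`finetune`
are thin functional wrappers.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _nn
from .smiles_data import (
    EncodedSequence,
    SmilesRecord,
    Vocabulary,
    build_vocabulary,
    encode,
)


@dataclass(frozen=True)
class ClmArchitecture:
    """Shape of the network; fixes the parameter count via a closed form."""

    vocab_size: int
    lstm1_units: int = 1024
    lstm2_units: int = 256

    def __post_init__(self):
        if min(self.vocab_size, self.lstm1_units, self.lstm2_units) < 1:
            raise ValueError("architecture dimensions must be positive")


def parameter_count(arch: ClmArchitecture) -> int:
    """Closed-form total parameter count, batch-norm moving statistics included.

    Input batch norm contributes 4V (scale, offset, moving mean/variance);
    each LSTM with H units on D inputs contributes 4*(H*(D+H)+H); the output
    batch norm 4*H2; the per-step dense softmax (H2+1)*V.
    """
    v, h1, h2 = arch.vocab_size, arch.lstm1_units, arch.lstm2_units
    return (
        4 * v
        + 4 * (h1 * (v + h1) + h1)
        + 4 * (h2 * (h1 + h2) + h2)
        + 4 * h2
        + (h2 + 1) * v
    )


@dataclass
class TrainingConfig:
    """Training hyperparameters.

    Defaults mirror the full-scale regime: Adam at 1e-4 for 90 pretraining
    epochs, 100 fine-tuning epochs with 1000 strings sampled every second
    epoch. Desk-scale runs override epochs and learning rate explicitly.
    """

    learning_rate: float = 1e-4
    pretrain_epochs: int = 90
    finetune_epochs: int = 100
    sample_every: int = 2
    sample_size: int = 1000
    batch_size: int = 128
    validation_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive")
        if min(self.pretrain_epochs, self.finetune_epochs) < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.sample_every < 1 or self.sample_size < 1:
            raise ValueError("sampling schedule must be positive")


def _to_index_tuples(X, vocab: Vocabulary) -> list[tuple[int, ...]]:
    out = []
    for item in X:
        if isinstance(item, EncodedSequence):
            if max(item.token_indices) >= vocab.size:
                raise ValueError("encoded sequence index outside vocabulary")
            out.append(item.token_indices)
        else:
            out.append(encode(item, vocab).token_indices)
    return out


class SmilesLSTM(BaseEstimator):
    """LSTM chemical language model with perplexity-ready scoring.

    Parameters
    ----------
    lstm1_units, lstm2_units : int
        Sizes of the two stacked LSTM layers. The full-scale model uses
        1024/256; reduced models (e.g. 64/32) train in minutes on a CPU.
    learning_rate : float
        Adam step size.
    epochs : int
        Pretraining epochs for :meth:`fit`.
    batch_size : int
        Sequences per gradient step (padded to the batch maximum length).
    validation_fraction : float
        Held-out fraction for the per-epoch validation cross-entropy.
    random_state : int
        Seed for initialization and batch shuffling.

    Attributes
    ----------
    vocabulary_ : Vocabulary
        Token set the model was fitted with.
    network_ : SequenceNetwork
        The underlying parameter arrays.
    history_ : pandas.DataFrame
        Columns ``epoch, split, cross_entropy``.
    stage_ : str
        ``"pretrained"`` or ``"fine-tuned"``.
    epoch_ : int
        Epochs completed in the current stage.
    """

    def __init__(
        self,
        lstm1_units: int = 1024,
        lstm2_units: int = 256,
        learning_rate: float = 1e-4,
        epochs: int = 90,
        batch_size: int = 128,
        validation_fraction: float = 0.05,
        clip_norm: float = 5.0,
        random_state: int = 0,
    ):
        self.lstm1_units = lstm1_units
        self.lstm2_units = lstm2_units
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.clip_norm = clip_norm
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None, vocabulary: Vocabulary | None = None) -> "SmilesLSTM":
        """Pretrain on a corpus of SMILES strings, records, or encoded sequences.

        ``epochs=0`` yields a randomly initialized but fully scoreable model.
        """
        if len(X) == 0:
            raise ValueError("cannot fit on an empty corpus")
        if vocabulary is None:
            if all(isinstance(x, (str, SmilesRecord)) for x in X):
                records = [
                    x if isinstance(x, SmilesRecord) else SmilesRecord(raw=x, canonical=x)
                    for x in X
                ]
                vocabulary = build_vocabulary(records)
            else:
                raise ValueError("pass vocabulary= when fitting on encoded sequences")
        self.vocabulary_ = vocabulary
        rng = np.random.default_rng([self.random_state, 0])
        self.network_ = _nn.SequenceNetwork(
            vocabulary.size, self.lstm1_units, self.lstm2_units, rng
        )
        self.stage_ = "pretrained"
        self.epoch_ = 0
        self.provenance_ = {"stage": "pretrained", "epoch": 0, "seed": self.random_state}
        seqs = _to_index_tuples(X, vocabulary)
        if self.validation_fraction > 0 and len(seqs) >= 20:
            split_rng = np.random.default_rng([self.random_state, 1])
            order = split_rng.permutation(len(seqs))
            n_val = int(round(self.validation_fraction * len(seqs)))
            val = [seqs[i] for i in order[:n_val]]
            train = [seqs[i] for i in order[n_val:]]
        else:
            train, val = seqs, []
        history = self._train(train, val, self.epochs, start_epoch=0)
        self.history_ = pd.DataFrame(history, columns=["epoch", "split", "cross_entropy"])
        self.epoch_ = self.epochs
        self.provenance_["epoch"] = self.epochs
        return self

    def _batches(self, seqs, rng):
        order = rng.permutation(len(seqs))
        pad = self.vocabulary_.pad_index
        start = self.vocabulary_.start_index
        for lo in range(0, len(seqs), self.batch_size):
            chunk = [seqs[i] for i in order[lo : lo + self.batch_size]]
            T = max(len(s) for s in chunk)
            B = len(chunk)
            tokens_in = np.full((B, T), pad, dtype=np.int64)
            targets = np.full((B, T), pad, dtype=np.int64)
            mask = np.zeros((B, T), dtype=_nn.DTYPE)
            for b, s in enumerate(chunk):
                n = len(s)
                tokens_in[b, 0] = start
                tokens_in[b, 1:n] = s[:-1]
                targets[b, :n] = s
                mask[b, :n] = 1.0
            yield tokens_in, targets, mask

    def _eval_xent(self, seqs) -> float:
        total, n = 0.0, 0.0
        rng = np.random.default_rng(0)
        for tokens_in, targets, mask in self._batches(seqs, rng):
            total += self.network_.sequence_loss(tokens_in, targets, mask) * mask.sum()
            n += mask.sum()
        return total / n

    def _train(self, train, val, epochs, start_epoch, learning_rate=None, seed_salt=2):
        net = self.network_
        trainable = {k: v for k, v in net.parameters().items() if k in net.trainable_names()}
        opt = _nn.Adam(
            trainable,
            lr=learning_rate if learning_rate is not None else self.learning_rate,
            clip_norm=self.clip_norm,
        )
        history = []
        for e in range(epochs):
            epoch = start_epoch + e + 1
            rng = np.random.default_rng([self.random_state, seed_salt, epoch])
            tot, n = 0.0, 0.0
            for tokens_in, targets, mask in self._batches(train, rng):
                loss, grads = net.loss_and_grads(tokens_in, targets, mask)
                opt.step({k: grads[k] for k in trainable})
                tot += loss * mask.sum()
                n += mask.sum()
            history.append((epoch, "train", tot / n))
            if val:
                history.append((epoch, "validation", self._eval_xent(val)))
        return history

    # ------------------------------------------------------------- finetune
    def finetune(
        self,
        X,
        epochs: int = 100,
        sample_every: int = 2,
        learning_rate: float | None = None,
        freeze_batchnorm: bool = True,
    ) -> list["SmilesLSTM"]:
        """Transfer learning: continue training on a small set, snapshotting.

        Returns one model snapshot per ``sample_every`` epochs (epochs
        ``sample_every, 2*sample_every, ...``); with ``epochs=0`` a single
        snapshot identical in scoring behaviour to the base model. The base
        model itself is left untouched.

        Batch-normalization statistics are frozen by default: fine-tuning
        batches of 5-40 sequences give degenerate batch statistics that
        destabilize subsequent sampling, so the layers run on the statistics
        accumulated during pretraining while their scale/offset (and all
        other weights) keep training.
        """
        self._check_fitted()
        seqs = _to_index_tuples(X, self.vocabulary_)
        work = copy.deepcopy(self)
        work.stage_ = "fine-tuned"
        if epochs == 0:
            snap = copy.deepcopy(work)
            snap.epoch_ = 0
            snap.provenance_ = dict(self.provenance_, stage="fine-tuned", epoch=0,
                                    parent=self.provenance_.get("stage"))
            return [snap]
        snapshots = []
        history = list(self.history_.itertuples(index=False, name=None)) if hasattr(self, "history_") else []
        net = work.network_
        net.bn_frozen = freeze_batchnorm
        trainable = {k: v for k, v in net.parameters().items() if k in net.trainable_names()}
        opt = _nn.Adam(
            trainable,
            lr=learning_rate if learning_rate is not None else self.learning_rate,
            clip_norm=self.clip_norm,
        )
        for epoch in range(1, epochs + 1):
            rng = np.random.default_rng([self.random_state, 3, epoch])
            tot, n = 0.0, 0.0
            for tokens_in, targets, mask in work._batches(seqs, rng):
                loss, grads = net.loss_and_grads(tokens_in, targets, mask)
                opt.step({k: grads[k] for k in trainable})
                tot += loss * mask.sum()
                n += mask.sum()
            history.append((epoch, "finetune", tot / n))
            if epoch % sample_every == 0:
                snap = copy.deepcopy(work)
                snap.network_.bn_frozen = False
                snap.epoch_ = epoch
                snap.history_ = pd.DataFrame(
                    history, columns=["epoch", "split", "cross_entropy"]
                )
                snap.provenance_ = dict(
                    stage="fine-tuned", epoch=epoch, seed=self.random_state,
                    parent=self.provenance_.get("stage", "pretrained"),
                )
                snapshots.append(snap)
        return snapshots

    # ------------------------------------------------------------- scoring
    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise ValueError("model is not fitted; call fit() first")

    def next_token_probabilities(self, prefix) -> np.ndarray:
        """P(next token | start, prefix) as a length-V vector summing to 1.

        ``prefix`` is a list of token indices (the start token is implicit).
        """
        self._check_fitted()
        V = self.vocabulary_.size
        idx = list(prefix)
        if any(not (0 <= i < V) for i in idx):
            raise ValueError(f"prefix contains an index outside the {V}-token vocabulary")
        tokens = np.array([[self.vocabulary_.start_index] + idx], dtype=np.int64)
        state = self.network_.init_state(1)
        logits = None
        for t in range(tokens.shape[1]):
            logits, state = self.network_.step(tokens[:, t], state)
        return _nn.softmax(logits[0])

    def init_state(self, batch: int):
        self._check_fitted()
        return self.network_.init_state(batch)

    def step(self, tokens: np.ndarray, state):
        return self.network_.step(tokens, state)

    def sequence_log_probs(self, sequences: list[tuple[int, ...]]) -> list[np.ndarray]:
        """Per-step log P(true next token) for each index sequence (batched).

        Each sequence is the target stream (tokens plus end token); the
        returned array for a sequence of N steps has length N.
        """
        self._check_fitted()
        pad = self.vocabulary_.pad_index
        start = self.vocabulary_.start_index
        out = []
        for lo in range(0, len(sequences), 512):
            chunk = sequences[lo : lo + 512]
            T = max(len(s) for s in chunk)
            B = len(chunk)
            tokens_in = np.full((B, T), pad, dtype=np.int64)
            targets = np.full((B, T), pad, dtype=np.int64)
            for b, s in enumerate(chunk):
                n = len(s)
                tokens_in[b, 0] = start
                tokens_in[b, 1:n] = s[:-1]
                targets[b, :n] = s
            logits = self.network_.forward(tokens_in, None, training=False)
            logp = _nn.log_softmax(logits)
            picked = logp[np.arange(B)[:, None], np.arange(T)[None, :], targets]
            for b, s in enumerate(chunk):
                out.append(picked[b, : len(s)].astype(np.float64))
        return out

    # --------------------------------------------------------- persistence
    def n_parameters(self) -> int:
        """Total parameter count by introspection of the built network."""
        self._check_fitted()
        return self.network_.n_parameters()

    def save(self, path: str) -> None:
        """Write a checkpoint archive (weights + vocabulary + provenance)."""
        self._check_fitted()
        meta = {
            "params": self.get_params(),
            "vocabulary": json.loads(self.vocabulary_.to_json()),
            "provenance": self.provenance_,
            "stage": self.stage_,
            "epoch": self.epoch_,
        }
        arrays = {f"w::{k}": v for k, v in self.network_.parameters().items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str) -> "SmilesLSTM":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            weights = {
                k[len("w::"):]: data[k] for k in data.files if k.startswith("w::")
            }
        model = cls(**meta["params"])
        model.vocabulary_ = Vocabulary(
            tokens=tuple(meta["vocabulary"]["tokens"]),
            pad_token=meta["vocabulary"]["pad_token"],
            start_token=meta["vocabulary"]["start_token"],
            end_token=meta["vocabulary"]["end_token"],
        )
        rng = np.random.default_rng(0)
        model.network_ = _nn.SequenceNetwork(
            model.vocabulary_.size, model.lstm1_units, model.lstm2_units, rng
        )
        model.network_.set_parameters(weights)
        model.provenance_ = meta["provenance"]
        model.stage_ = meta["stage"]
        model.epoch_ = meta["epoch"]
        model.history_ = pd.DataFrame(columns=["epoch", "split", "cross_entropy"])
        return model


def pretrain(records, config: TrainingConfig, vocabulary: Vocabulary | None = None,
             lstm1_units: int = 1024, lstm2_units: int = 256) -> SmilesLSTM:
    """Functional wrapper: pretrain a model per a :class:`TrainingConfig`."""
    model = SmilesLSTM(
        lstm1_units=lstm1_units,
        lstm2_units=lstm2_units,
        learning_rate=config.learning_rate,
        epochs=config.pretrain_epochs,
        batch_size=config.batch_size,
        validation_fraction=config.validation_fraction,
        random_state=config.seed,
    )
    return model.fit(records, vocabulary=vocabulary)


def finetune(base: SmilesLSTM, records, config: TrainingConfig) -> list[SmilesLSTM]:
    """Functional wrapper over :meth:`SmilesLSTM.finetune`."""
    return base.finetune(
        records,
        epochs=config.finetune_epochs,
        sample_every=config.sample_every,
        learning_rate=config.learning_rate,
    )
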