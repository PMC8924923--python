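import numpy as np
import pytest

from clmkit.clm_model import SmilesLSTM
from clmkit.fixtures import FixtureSpec, MarkovCharModel, generate_corpus
from clmkit.smiles_data import END, PAD, START, Vocabulary


@pytest.fixture(scope="session")
def markov_co():
    """Enumerable two-token Markov model over C/O with reachable termination."""
    return MarkovCharModel(
        tokens=["C", "O"],
        start_probs={"C": 0.7, "O": 0.3},
        transitions={
            "C": {"C": 0.5, "O": 0.2, END: 0.3},
            "O": {"C": 0.9, END: 0.1},
        },
    )


@pytest.fixture(scope="session")
def mixture_corpus():
    return generate_corpus(FixtureSpec(family="mix", n=500, seed=11))


@pytest.fixture(scope="session")
def overfit_model():
    """A tiny model trained to convergence on a single 20-carbon alkane."""
    s = "C" * 20
    model = SmilesLSTM(
        lstm1_units=32,
        lstm2_units=16,
        learning_rate=5e-3,
        epochs=300,
        batch_size=8,
        validation_fraction=0.0,
        random_state=0,
    ).fit([s] * 8)
    return model, s


@pytest.fixture(scope="session")
def small_pretrained(mixture_corpus):
    """A small mixture-pretrained model shared across training-dependent tests."""
    return SmilesLSTM(
        lstm1_units=48,
        lstm2_units=24,
        learning_rate=2e-3,
        epochs=6,
        batch_size=32,
        validation_fraction=0.1,
        random_state=3,
    ).fit([r.canonical for r in mixture_corpus])


class UniformModel:
    """Model assigning the uniform distribution over V tokens at every step."""

    def __init__(self, vocab_size: int = 7):
        extra = tuple("CO()1c"[: vocab_size - 3])
        self.vocabulary = Vocabulary(tokens=(PAD, START, END) + extra)

    def init_state(self, batch):
        return None

    def step(self, tokens, state):
        return np.zeros((len(tokens), self.vocabulary.size)), None


class ScriptedModel:
    """Model placing (essentially) all probability on a scripted string.

    Used for the degenerate all-p_i-equal-1 perplexity identity.
    """

    def __init__(self, script_indices, vocab: Vocabulary):
        self.vocabulary = vocab
        self.script = list(script_indices) + [vocab.end_index]

    def init_state(self, batch):
        return np.zeros(batch, dtype=np.int64)  # per-sequence position

    def step(self, tokens, state):
        V = self.vocabulary.size
        logits = np.full((len(tokens), V), -1e4)
        for b, pos in enumerate(state):
            target = self.script[min(pos, len(self.script) - 1)]
            logits[b, target] = 1e4
        return logits, state + 1
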