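import numpy as np
import pytest

from clmkit.clm_model import ClmArchitecture, SmilesLSTM, parameter_count
from clmkit.fixtures import FixtureSpec, generate_corpus
from clmkit.scoring import perplexities
from clmkit.smiles_data import encode


class TestParameterCount:
    def test_published_architecture_has_5820515_parameters(self):
        """batch norm -> LSTM 1024 -> LSTM 256 -> batch norm -> softmax at V=71."""
        assert parameter_count(ClmArchitecture(vocab_size=71)) == 5_820_515

    def test_closed_form_is_affine_in_vocab_size(self):
        assert parameter_count(ClmArchitecture(vocab_size=1)) == 4357 + 5_511_168
        for v in (4, 30, 71):
            assert parameter_count(ClmArchitecture(vocab_size=v)) == 4357 * v + 5_511_168

    @pytest.mark.parametrize("v", [4, 30, 71])
    def test_introspection_matches_closed_form(self, v):
        # build a vocabulary of exactly v symbols via explicit tokens
        from clmkit.smiles_data import PAD, START, END, EncodedSequence, Vocabulary

        extra = tuple(f"t{i}" for i in range(v - 3))
        vocab = Vocabulary(tokens=(PAD, START, END) + extra)
        seq = EncodedSequence(token_indices=(3,) * 10 + (vocab.end_index,))
        model = SmilesLSTM(lstm1_units=1024, lstm2_units=256, epochs=0)
        model.fit([seq], vocabulary=vocab)
        assert model.n_parameters() == parameter_count(ClmArchitecture(vocab_size=v))

    def test_reduced_architecture_counts(self):
        model = SmilesLSTM(lstm1_units=64, lstm2_units=32, epochs=0).fit(["C" * 25])
        v = model.vocabulary_.size
        expected = parameter_count(
            ClmArchitecture(vocab_size=v, lstm1_units=64, lstm2_units=32)
        )
        assert model.n_parameters() == expected


class TestTraining:
    def test_loss_decreases_on_small_corpus(self, mixture_corpus):
        model = SmilesLSTM(
            lstm1_units=32, lstm2_units=16, learning_rate=2e-3,
            epochs=5, batch_size=32, random_state=7,
        ).fit([r.canonical for r in mixture_corpus])
        train = model.history_.query("split == 'train'")
        assert train.cross_entropy.iloc[-1] < train.cross_entropy.iloc[0]

    def test_zero_epochs_still_scoreable(self):
        model = SmilesLSTM(lstm1_units=16, lstm2_units=8, epochs=0).fit(["C" * 25])
        p = model.next_token_probabilities([model.vocabulary_.index("C")])
        assert p.shape == (model.vocabulary_.size,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_gives_identical_loss_trace(self, mixture_corpus):
        strings = [r.canonical for r in mixture_corpus[:120]]
        kwargs = dict(lstm1_units=24, lstm2_units=12, learning_rate=2e-3,
                      epochs=2, batch_size=32, random_state=5)
        a = SmilesLSTM(**kwargs).fit(strings)
        b = SmilesLSTM(**kwargs).fit(strings)
        assert a.history_.cross_entropy.tolist() == b.history_.cross_entropy.tolist()

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            SmilesLSTM(epochs=0).fit([])


class TestFinetune:
    def test_snapshot_schedule(self, small_pretrained):
        strings = ["CC" + "OCC" * 8] * 5
        snaps = small_pretrained.finetune(strings, epochs=10, sample_every=2)
        assert [s.epoch_ for s in snaps] == [2, 4, 6, 8, 10]
        assert all(s.stage_ == "fine-tuned" for s in snaps)

    def test_zero_epochs_identical_to_base(self, small_pretrained):
        (snap,) = small_pretrained.finetune(["CC" + "OCC" * 8], epochs=0)
        probe = "CCOCCOCCCCOCCOCCCCCC"
        np.testing.assert_array_equal(
            perplexities(snap, [probe]), perplexities(small_pretrained, [probe])
        )

    def test_finetuning_reduces_set_perplexity(self, small_pretrained):
        ft_set = [r.canonical for r in generate_corpus(
            FixtureSpec(family="ether", n=5, seed=77))]
        snaps = small_pretrained.finetune(ft_set, epochs=40, sample_every=40,
                                          learning_rate=2e-3)
        before = perplexities(small_pretrained, ft_set).mean()
        after = perplexities(snaps[-1], ft_set).mean()
        assert after < before

    def test_base_model_is_untouched(self, small_pretrained):
        probe = "CCOCCOCCCCOCCOCCCCCC"
        before = perplexities(small_pretrained, [probe])[0]
        small_pretrained.finetune(["CC" + "OCC" * 8] * 3, epochs=4, sample_every=2)
        assert perplexities(small_pretrained, [probe])[0] == before

    def test_vocabulary_mismatch_raises(self, small_pretrained):
        with pytest.raises(KeyError):
            small_pretrained.finetune(["CN" * 12], epochs=2)


class TestDistributionRecovery:
    def test_markov_source_preferred_over_shuffled_strings(self, markov_co):
        """A CLM trained on draws from a first-order Markov character source
        scores fresh source strings below character-shuffled versions."""
        from clmkit.sampling import sample_multinomial

        run = sample_multinomial(markov_co, n=3000, T=1.0, max_length=30, seed=21)
        strings = [s.smiles for s in run.strings if s.terminated and len(s.smiles) >= 5]
        assert len(strings) >= 290
        train, fresh = strings[:250], strings[250:290]
        model = SmilesLSTM(
            lstm1_units=24, lstm2_units=12, learning_rate=2e-3,
            epochs=15, batch_size=32, validation_fraction=0.0, random_state=9,
        ).fit(train)
        rng = np.random.default_rng(2)
        shuffled = ["".join(rng.permutation(list(s))) for s in fresh]
        assert perplexities(model, fresh).mean() < perplexities(model, shuffled).mean()


class TestScoringInterface:
    def test_probabilities_sum_to_one(self, small_pretrained):
        vocab = small_pretrained.vocabulary_
        prefix = encode("CCOCC", vocab).token_indices[:-1]
        p = small_pretrained.next_token_probabilities(list(prefix))
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_index_raises(self, small_pretrained):
        with pytest.raises(ValueError):
            small_pretrained.next_token_probabilities([small_pretrained.vocabulary_.size])

    def test_overfit_model_predicts_termination(self, overfit_model):
        model, s = overfit_model
        prefix = encode(s, model.vocabulary_).token_indices[:-1]
        p = model.next_token_probabilities(list(prefix))
        assert p[model.vocabulary_.end_index] > 0.9


class TestCheckpointIO:
    def test_save_load_probabilities_bit_identical(self, small_pretrained, tmp_path):
        path = str(tmp_path / "model.npz")
        small_pretrained.save(path)
        loaded = SmilesLSTM.load(path)
        probe = ["CCOCCOCCCCOCCOCCCCCC", "C" * 30]
        np.testing.assert_array_equal(
            perplexities(loaded, probe), perplexities(small_pretrained, probe)
        )
        assert loaded.vocabulary_.tokens == small_pretrained.vocabulary_.tokens
        assert loaded.stage_ == small_pretrained.stage_
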