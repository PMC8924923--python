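import numpy as np
import pytest
from rdkit import DataStructs

from clmkit.analysis import (
    compare_samplers,
    fingerprint,
    mean_distance_to_set,
    min_distance_to_set,
    perplexity_distance_correlation,
    tanimoto_distance,
    validity,
)
from clmkit.fixtures import FixtureSpec, generate_corpus
from clmkit.sampling import SampledString, SamplingRun, sample_beam


def _bitvec(on_bits, size=16):
    bv = DataStructs.ExplicitBitVect(size)
    for b in on_bits:
        bv.SetBit(b)
    return bv


class TestValidity:
    def test_unclosed_ring_is_invalid(self):
        assert validity(["CCO", "C1CC"]) == 0.5

    def test_generated_fixtures_all_valid(self):
        corpus = generate_corpus(FixtureSpec(family="mix", n=50, seed=1))
        assert validity([r.canonical for r in corpus]) == 1.0

    def test_order_and_duplication_invariance(self):
        strings = ["CCO", "C1CC", "CCC", "xx"]
        assert validity(strings) == validity(strings[::-1])
        assert validity(strings * 3) == validity(strings)


class TestTanimoto:
    def test_identity_gives_zero(self):
        fp = fingerprint("CCOCCOCC")
        assert tanimoto_distance(fp, fp) == 0.0

    def test_disjoint_bits_give_one(self):
        assert tanimoto_distance(_bitvec({0, 1}), _bitvec({5, 6})) == 1.0

    def test_hand_computed_overlap(self):
        # |a & b| = 2, |a | b| = 8 -> distance 0.75
        a = _bitvec({0, 1, 2, 3, 4})
        b = _bitvec({3, 4, 5, 6, 7})
        assert tanimoto_distance(a, b) == pytest.approx(0.75)

    def test_both_empty_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tanimoto_distance(_bitvec(set()), _bitvec(set())) == 0.0

    def test_symmetric_and_bounded_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = _bitvec(set(rng.integers(0, 16, 5).tolist()))
            b = _bitvec(set(rng.integers(0, 16, 5).tolist()))
            d = tanimoto_distance(a, b)
            assert 0.0 <= d <= 1.0
            assert d == tanimoto_distance(b, a)

    def test_morgan_fingerprint_length(self):
        assert fingerprint("CCOCCOCC").GetNumBits() == 1024

    def test_pharmacophore_kind_available(self):
        fp = fingerprint("CCOCCOCCO", kind="ph4")
        assert fp.GetNumOnBits() >= 0

    def test_invalid_molecule_rejected(self):
        with pytest.raises(ValueError):
            fingerprint("C1CC")


class TestSetDistances:
    def test_member_has_zero_min_distance(self):
        ref = ["CCOCCOCC", "CCCCCCCC"]
        assert min_distance_to_set("CCOCCOCC", ref) == 0.0

    def test_singleton_set_equals_pairwise(self):
        d = min_distance_to_set("CCOCCOCC", ["CCCCCCCC"])
        pair = tanimoto_distance(fingerprint("CCOCCOCC"), fingerprint("CCCCCCCC"))
        assert d == pytest.approx(pair)

    def test_matches_brute_force_on_fixture(self):
        ref = [r.canonical for r in generate_corpus(FixtureSpec(family="mix", n=20, seed=13))]
        mol = "CCCCCCCCCCCCCOCCCCCCCC"
        fps = [fingerprint(s) for s in ref]
        fp = fingerprint(mol)
        brute = min(tanimoto_distance(fp, f) for f in fps)
        assert min_distance_to_set(mol, ref) == pytest.approx(brute)
        brute_mean = np.mean([tanimoto_distance(fp, f) for f in fps])
        assert mean_distance_to_set(mol, ref) == pytest.approx(brute_mean)


class TestPearson:
    def test_exact_line_gives_unity(self):
        x = np.arange(10.0)
        assert perplexity_distance_correlation(zip(x, 2 * x + 1)) == pytest.approx(1.0)
        assert perplexity_distance_correlation(zip(x, -x)) == pytest.approx(-1.0)

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=100)
        y = 0.5 * x + rng.normal(size=100)
        got = perplexity_distance_correlation(zip(x, y))
        xc, yc = x - x.mean(), y - y.mean()
        ref = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert got == pytest.approx(ref, abs=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        base = perplexity_distance_correlation(zip(x, y))
        scaled = perplexity_distance_correlation(zip(3 * x + 5, y))
        flipped = perplexity_distance_correlation(zip(-2 * x, y))
        assert scaled == pytest.approx(base, abs=1e-12)
        assert flipped == pytest.approx(-base, abs=1e-12)

    def test_constant_input_flagged_nan(self):
        with pytest.warns(UserWarning):
            out = perplexity_distance_correlation([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
        assert np.isnan(out)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            perplexity_distance_correlation([(1.0, 2.0)])


def _run(strings, method="multinomial"):
    return SamplingRun(
        method=method,
        strings=[SampledString(s, -1.0, True) for s in strings],
        max_length=90,
    )


class TestCompareSamplers:
    def test_identical_runs_tie(self, small_pretrained):
        strings = ["C" * 25, "CCOCCOCCCCOCCOCCCCCC"]
        cmp = compare_samplers(small_pretrained, _run(strings), _run(strings, "beam"))
        assert cmp.multinomial_wins is None

    def test_beam_holding_best_strings_wins(self, markov_co):
        beam = sample_beam(markov_co, k=50, max_length=6)
        # the multinomial side only has a low-probability string ("CO" has
        # perplexity ~4.15, far above the beam's best candidates)
        cmp = compare_samplers(markov_co, _run(["CO"]), beam, top_k=5)
        assert cmp.multinomial_wins is False

    def test_top_k_truncation_flagged(self, small_pretrained):
        cmp = compare_samplers(
            small_pretrained, _run(["C" * 25]), _run(["CCOCCOCCCCOCCOCCCCCC"], "beam"),
            top_k=50,
        )
        assert cmp.truncated

    def test_empty_side_gives_no_winner(self, small_pretrained):
        cmp = compare_samplers(small_pretrained, _run(["C1CC"]), _run(["C" * 25], "beam"))
        assert cmp.multinomial_wins is None and cmp.top_multinomial == []

    def test_win_indicator_antisymmetric(self, small_pretrained):
        a = _run(["C" * 25, "CCCCCC(C)CCCCCCCCCCCC"])
        b = _run(["CCOCCOCCCCOCCOCCCCCC"], "beam")
        fwd = compare_samplers(small_pretrained, a, b)
        rev = compare_samplers(small_pretrained, b, a)
        if fwd.multinomial_wins is None:
            assert rev.multinomial_wins is None
        else:
            assert rev.multinomial_wins is (not fwd.multinomial_wins)

    def test_similarity_filter_removes_near_duplicates(self, small_pretrained):
        ft_set = ["CCOCCOCCCCOCCOCCCCCC"]
        run = _run(["CCOCCOCCCCOCCOCCCCCC", "C" * 25])
        cmp = compare_samplers(
            small_pretrained, run, _run(["C" * 24], "beam"),
            fine_tuning_set=ft_set, min_distance=0.5,
        )
        kept = [m for m, _ in cmp.top_multinomial]
        assert "CCOCCOCCCCOCCOCCCCCC" not in kept
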