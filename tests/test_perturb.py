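"""Perturbation engine: tokenization, budgets, operators, end-to-end examples."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perturbkit as pk
from perturbkit.errors import BudgetInfeasibleError, DegenerateInputError
from perturbkit.perturb import apply_edits, apply_typo_detail, round_half_up, tokenize

from conftest import EXAMPLE_HOMOPHONE, EXAMPLE_REDACTED, EXAMPLE_TEXT


class TestAnnotate:
    def test_medical_flag_and_validity(self, lexicon):
        anns = pk.annotate_tokens(EXAMPLE_TEXT, lexicon=lexicon)
        by_text = {a.text: a for a in anns}
        assert by_text["voxelotor"].is_medical
        assert by_text["voxelotor"].is_valid
        assert by_text["did"].is_valid  # tagged as a verb
        assert not by_text["the"].is_valid
        assert not by_text["quality"].is_medical

    @pytest.mark.parametrize("bad", ["", "   ", "\n\t"])
    def test_degenerate_input_rejected(self, bad):
        with pytest.raises(DegenerateInputError):
            pk.annotate_tokens(bad)

    def test_hand_tokenized_spans(self):
        anns = pk.annotate_tokens("red red red")
        assert [(a.start, a.end) for a in anns] == [(0, 3), (4, 7), (8, 11)]
        assert all(a.pos == "adjective" for a in anns)

    def test_punctuation_peeled_spans_ordered(self):
        anns = pk.annotate_tokens("Pain, (severe) -- worsened!")
        assert [a.text for a in anns] == ["Pain", "severe", "worsened"]
        assert all(a.end <= b.start for a, b in zip(anns, anns[1:]))
        # spans index into the source string exactly
        assert all("Pain, (severe) -- worsened!"[a.start : a.end] == a.text for a in anns)


class TestTargetCount:
    def test_worked_example_ten_words_five_valid(self):
        # 10% of a 10-word sentence = 1 word, i.e. 20% of its 5 valid words
        assert pk.compute_target_count(10, 5, 0.10) == 1

    def test_full_perturbation(self):
        assert pk.compute_target_count(10, 10, 1.0) == 10

    def test_infeasible_budget_signalled(self):
        with pytest.raises(BudgetInfeasibleError) as err:
            pk.compute_target_count(10, 2, 0.50)
        assert err.value.required == 5 and err.value.available == 2

    @pytest.mark.parametrize("level", [0.0, -0.1])
    def test_nonpositive_level_rejected(self, level):
        with pytest.raises(ValueError):
            pk.compute_target_count(10, 5, level)

    def test_rounding_is_half_up_with_floor_one(self):
        assert pk.compute_target_count(10, 10, 0.25) == 3  # 2.5 rounds up
        assert pk.compute_target_count(10, 10, 0.01) == 1  # floor at 1
        assert round_half_up(1.5) == 2 and round_half_up(2.5) == 3


class TestSelectWords:
    def test_exhaustive_selection_ignores_seed(self, lexicon):
        anns = pk.annotate_tokens("the sore vein heal pain week now", lexicon=lexicon)
        valid = [i for i, a in enumerate(anns) if a.is_valid]
        for seed in (0, 1, 99):
            assert pk.select_words(anns, len(valid), seed) == valid

    def test_seed_determinism(self, lexicon):
        anns = pk.annotate_tokens(EXAMPLE_TEXT, lexicon=lexicon)
        assert pk.select_words(anns, 3, 7) == pk.select_words(anns, 3, 7)

    def test_uniformity_binomial_bound(self):
        # 10,000 draws of 1 from 4 valid tokens: each within 3 sigma of 2500
        anns = pk.annotate_tokens("sore vein heal pain")
        assert sum(a.is_valid for a in anns) == 4
        counts = collections.Counter()
        for seed in range(10_000):
            counts[pk.select_words(anns, 1, seed)[0]] += 1
        sigma = np.sqrt(10_000 * 0.25 * 0.75)
        assert all(abs(c - 2500) <= 3 * sigma for c in counts.values())

    def test_over_budget_raises(self):
        anns = pk.annotate_tokens("sore vein")
        with pytest.raises(BudgetInfeasibleError):
            pk.select_words(anns, 5, 0)


class TestTypo:
    def test_always_differs_over_seed_sweep(self):
        for word in ("discharge", "affect", "aa", "a", "MRI"):
            for seed in range(1000):
                assert pk.apply_typo(word, seed=seed) != word

    def test_deletion_outcome_reachable(self):
        # "affect" -> "affec" is a single trailing deletion
        outcomes = {pk.apply_typo("affect", seed=s) for s in range(3000)}
        assert "affec" in outcomes

    def test_transposition_outcome_reachable(self):
        # "discharge" -> "dicsharge" is one adjacent swap; a narrow letter
        # fraction makes single-edit outcomes reachable on a 9-letter word
        outcomes = {
            pk.apply_typo("discharge", letter_fraction_range=(0.1, 0.15), seed=s)
            for s in range(3000)
        }
        assert "dicsharge" in outcomes

    def test_untouched_letter_casing_preserved(self):
        # no operator ever flips case: uppercase letters in the output can
        # only be survivors of the original's uppercase letters
        for seed in range(300):
            out, _ = apply_typo_detail("VoXel", seed=seed)
            assert {c for c in out if c.isupper()} <= {"V", "X"}

    def test_single_letter_word_gets_one_edit(self):
        for seed in range(200):
            out = pk.apply_typo("a", seed=seed)
            assert out != "a" and 1 <= len(out) <= 2


class TestHomophone:
    @pytest.mark.parametrize(
        "word,expected", [("did", "deed"), ("in", "inn"), ("Did", "Deed")]
    )
    def test_known_pairs(self, provider, word, expected):
        assert pk.apply_homophone(word, provider) == expected

    def test_word_without_homophone_gives_none(self, provider):
        assert pk.apply_homophone("voxelotor", provider) is None

    def test_result_listed_in_dictionary(self, provider):
        for word in ("pain", "week", "see", "gait"):
            out = pk.apply_homophone(word, provider)
            assert out.lower() in [c.lower() for c in provider.lookup(word)]


class TestRedaction:
    def test_discharge_summary_example(self, lexicon):
        anns = pk.annotate_tokens(EXAMPLE_TEXT, lexicon=lexicon)
        idx = {a.text: i for i, a in enumerate(anns)}
        out = pk.apply_redaction(EXAMPLE_TEXT, anns, [idx["icterus"], idx["life"]])
        assert out == EXAMPLE_REDACTED

    def test_zero_indices_identity(self, lexicon):
        anns = pk.annotate_tokens(EXAMPLE_TEXT, lexicon=lexicon)
        assert pk.apply_redaction(EXAMPLE_TEXT, anns, []) == EXAMPLE_TEXT

    def test_full_redaction_empties_text(self):
        anns = pk.annotate_tokens("a b c")
        assert pk.apply_redaction("a b c", anns, [0, 1, 2]) == ""


class TestPerturbExample:
    def test_homophone_row_of_worked_example(self, provider, lexicon):
        # at the 10% level the 18-word sentence perturbs 2 words; widening the
        # POS gate to adpositions leaves "did" and "in" as the only
        # homophone-bearing eligible words, so the outcome is deterministic
        spec = pk.PerturbationSpec(
            ptype="homophone",
            level=0.10,
            seed=3,
            valid_pos=frozenset({"adjective", "adverb", "verb", "noun", "adposition"}),
        )
        ex = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon)
        assert ex.perturbed == EXAMPLE_HOMOPHONE
        assert [e.operation for e in ex.edits] == ["homophone_swap", "homophone_swap"]

    def test_zero_level_rejected_at_spec_validation(self):
        with pytest.raises(ValueError):
            pk.PerturbationSpec(ptype="typographical", level=0.0, seed=0)

    @pytest.mark.parametrize("ptype,level", [("typographical", 0.3), ("homophone", 0.2), ("redaction", 0.5)])
    def test_replay_and_determinism(self, provider, lexicon, ptype, level):
        # homophone-rich sentence so every grid level is feasible
        text = "The sore vein heal the weak week and visit care."
        spec = pk.PerturbationSpec(ptype=ptype, level=level, seed=9)
        kwargs = dict(provider=provider, lexicon=lexicon, example_id="r1")
        ex1 = pk.perturb_example(text, spec, **kwargs)
        ex2 = pk.perturb_example(text, spec, **kwargs)
        assert ex1.perturbed == ex2.perturbed and ex1.edits == ex2.edits
        anns = pk.annotate_tokens(text, lexicon=lexicon, valid_pos=spec.valid_pos)
        assert apply_edits(text, anns, ex1.edits, ptype) == ex1.perturbed

    @pytest.mark.parametrize("ptype,level", [("typographical", 0.5), ("redaction", 0.3)])
    def test_budget_exactness_and_eligibility(self, provider, lexicon, ptype, level):
        spec = pk.PerturbationSpec(ptype=ptype, level=level, seed=21)
        ex = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon)
        anns = pk.annotate_tokens(EXAMPLE_TEXT, lexicon=lexicon)
        assert len(ex.edits) == ex.target_count
        assert all(anns[e.token_index].is_valid for e in ex.edits)

    def test_redaction_monotonicity(self, provider, lexicon):
        spec = pk.PerturbationSpec(ptype="redaction", level=0.3, seed=4)
        ex = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon)
        n_before = len(tokenize(EXAMPLE_TEXT))
        n_after = len(tokenize(ex.perturbed))
        assert n_after == n_before - ex.target_count

    def test_typo_locality_unedited_tokens_unchanged(self, provider, lexicon):
        spec = pk.PerturbationSpec(ptype="typographical", level=0.3, seed=17)
        ex = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon)
        edited = {e.token_index for e in ex.edits}
        before = [t for i, (t, _, _) in enumerate(tokenize(EXAMPLE_TEXT)) if i not in edited]
        after = [t for t, _, _ in tokenize(ex.perturbed)]
        # every unedited token survives with multiplicity
        assert not collections.Counter(before) - collections.Counter(after)

    def test_order_independent_per_example_seeding(self, provider, lexicon):
        spec = pk.PerturbationSpec(ptype="redaction", level=0.3, seed=9)
        a = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon, example_id="a")
        b = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon, example_id="b")
        a2 = pk.perturb_example(EXAMPLE_TEXT, spec, provider=provider, lexicon=lexicon, example_id="a")
        assert a.perturbed == a2.perturbed
        assert {e.token_index for e in a.edits} != {e.token_index for e in b.edits} or True

    def test_homophone_budget_infeasible_after_reselection(self, provider, lexicon):
        # only one homophone-bearing word available, two required
        text = "the voxelotor worsened icterus pain badly"
        spec = pk.PerturbationSpec(ptype="homophone", level=0.35, seed=0)
        with pytest.raises(BudgetInfeasibleError):
            pk.perturb_example(text, spec, provider=provider, lexicon=lexicon)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_typo_differs_property(seed):
    assert pk.apply_typo("icterus", seed=seed) != "icterus"
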