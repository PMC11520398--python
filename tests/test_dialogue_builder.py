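"""Dialogue construction: splitting, masking, the similarity gate, filters."""

import itertools

import pytest

from moldialog.chem_core import (
    InvalidSmilesError,
    canonicalize,
    parse_smiles,
    smiles_similarity,
)
from moldialog.dialogue_builder import (
    BuilderConfig,
    Dialogue,
    Rejection,
    build_corpus_dialogues,
    build_dialogue,
    default_candidate_generator,
    make_turn_input,
    replace_synonyms,
    select_intermediate,
    split_and_reverse,
    split_dialogues,
)
from moldialog.records import DescribedMolecule


class TestSplitAndReverse:
    def test_three_sentences(self):
        assert split_and_reverse("A one. B two. C three.") == [
            "C three.", "B two.", "A one.",
        ]

    def test_single_sentence(self):
        assert split_and_reverse("Only one sentence.") == ["Only one sentence."]

    def test_round_trip(self):
        text = "The molecule contains a hydroxyl group. The molecule is an alcohol."
        sentences = split_and_reverse(text)
        assert " ".join(reversed(sentences)) == text

    def test_abbreviation_guard(self):
        sentences = split_and_reverse("It is stable, e.g. when heated. It is white.")
        assert len(sentences) == 2
        assert sentences[1] == "It is stable, e.g. when heated."

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_and_reverse("   ")


class TestReplaceSynonyms:
    def test_simple_replacement(self):
        assert (
            replace_synonyms("Ethanol is volatile.", ["ethanol"])
            == "the molecule is volatile."
        )

    def test_no_synonym_unchanged(self):
        text = "Water is everywhere."
        assert replace_synonyms(text, ["ethanol"]) == text

    def test_nested_synonyms_longest_first(self):
        out = replace_synonyms(
            "Acetic acid is an acid.", ["acid", "acetic acid"]
        )
        assert out == "the molecule is an the molecule."
        # crucially: no double replacement inside the long match
        assert "the molecule acid" not in out

    def test_whole_word_only(self):
        assert replace_synonyms("acidic solution", ["acid"]) == "acidic solution"


class TestSelectIntermediate:
    def test_final_itself_excluded(self):
        # similarity 1.0 is strictly outside the gate
        assert (
            select_intermediate(["CCO"], "CCO", lo=0.5, hi=1.0, seed=0) is None
        )

    def test_candidate_inside_gate_chosen(self):
        # verify with a brute-force bit-set computation that the candidate
        # really falls inside (0.5, 1), then expect it to be selected
        from moldialog.chem_core import FingerprintScheme, fingerprint

        final, candidate = "CCCCO", "CCCCCO"
        fa = fingerprint(parse_smiles(final), FingerprintScheme.RDK_PATH)
        fb = fingerprint(parse_smiles(candidate), FingerprintScheme.RDK_PATH)
        sim = len(fa.bits & fb.bits) / len(fa.bits | fb.bits)
        assert 0.5 < sim < 1.0
        assert (
            select_intermediate([candidate], final, lo=0.5, hi=1.0, seed=1)
            == candidate
        )

    def test_empty_eligible_set(self):
        assert select_intermediate(["C"], "CCCCCCCO", 0.5, 1.0, seed=0) is None

    def test_unparseable_candidates_skipped(self):
        assert select_intermediate(["C((", "x"], "CCO", 0.5, 1.0, seed=0) is None

    def test_invalid_final_raises(self):
        with pytest.raises(InvalidSmilesError):
            select_intermediate(["CCO"], "C((", 0.5, 1.0, seed=0)


class TestMakeTurnInput:
    def test_with_previous(self):
        assert (
            make_turn_input("It is an acid.", "CCO")
            == "It is an acid. It looks like CCO."
        )

    def test_without_previous(self):
        assert make_turn_input("It is an acid.", None) == "It is an acid."


class TestDefaultCandidateGenerator:
    def test_five_valid_distinct_from_final(self):
        candidates = default_candidate_generator("", "CCCO", seed=0)
        assert len(candidates) == 5
        for smi in candidates:
            parse_smiles(smi)  # must not raise
            assert canonicalize(smi) != canonicalize("CCCO")

    def test_at_least_one_in_gate(self):
        candidates = default_candidate_generator("", "CCCCCC(=O)O", seed=3)
        sims = [smiles_similarity(c, "CCCCCC(=O)O") for c in candidates]
        assert any(0.5 < s < 1.0 for s in sims)

    def test_sorted_by_descending_similarity(self):
        candidates = default_candidate_generator("", "CCCCO", seed=1)
        sims = [smiles_similarity(c, "CCCCO") for c in candidates]
        deduped = []
        for c, s in zip(candidates, sims):
            if c not in deduped:
                deduped.append(c)
        distinct_sims = [sims[candidates.index(c)] for c in deduped]
        assert distinct_sims == sorted(distinct_sims, reverse=True)

    def test_deterministic(self):
        a = default_candidate_generator("", "CCCCN", seed=7)
        b = default_candidate_generator("", "CCCCN", seed=7)
        assert a == b


class TestBuildDialogue:
    @staticmethod
    def record(description, smiles="CCCCCC(=O)O"):
        return DescribedMolecule("m1", smiles, description)

    def test_well_behaved_record(self):
        rec = self.record(
            "The molecule contains a carboxylic acid group. "
            "The molecule has 8 heavy atoms. "
            "The molecule is an organic acid."
        )
        result = build_dialogue(
            rec, default_candidate_generator, BuilderConfig(), seed=0
        )
        assert isinstance(result, Dialogue)
        assert result.n_turns == 3
        assert result.turns[-1].expected_smiles == rec.smiles
        assert result.final_smiles == rec.smiles
        # cumulative text of turn k is the first k reversed sentences
        for turn in result.turns:
            assert turn.text == " ".join(result.sentences[: turn.k])

    def test_hyphen_rejection(self):
        rec = self.record("It is made from 2-propanol. It is volatile.")
        result = build_dialogue(
            rec, default_candidate_generator, BuilderConfig(), seed=0
        )
        assert result == Rejection("m1", "hyphen")

    def test_single_turn_rejection(self):
        rec = self.record("The molecule is an organic acid.")
        result = build_dialogue(
            rec, default_candidate_generator, BuilderConfig(), seed=0
        )
        assert result == Rejection("m1", "single_turn")

    def test_no_candidate_rejection(self):
        # a generator producing only the final molecule leaves no eligible
        # candidate, and retain_low_sim=0 forbids the fallback
        def degenerate(_text, final, _seed):
            return [final] * 5

        rec = self.record("First fact. Second fact.")
        result = build_dialogue(
            rec, degenerate, BuilderConfig(retain_low_sim=0.0), seed=0
        )
        assert result == Rejection("m1", "no_candidate")

    def test_synonym_masking_applied(self):
        rec = self.record("Hexanoate is sour. Hexanoate is an acid.")
        result = build_dialogue(
            rec,
            default_candidate_generator,
            BuilderConfig(),
            seed=0,
            synonyms=["hexanoate"],
        )
        assert isinstance(result, Dialogue)
        assert all("hexanoate" not in s.lower() for s in result.sentences)


@pytest.fixture(scope="module")
def built(corpus):
    config = BuilderConfig(retain_low_sim=0.0)
    return build_corpus_dialogues(corpus, config, seed=13)


class TestCorpusInvariants:
    def test_gate_holds_for_all_intermediates(self, built):
        dialogues, _rejections = built
        assert dialogues, "expected some accepted dialogues"
        for d in dialogues:
            for turn in d.turns[:-1]:
                sim = smiles_similarity(turn.expected_smiles, d.final_smiles)
                assert 0.5 < sim < 1.0

    def test_structure_filters(self, built):
        dialogues, _ = built
        for d in dialogues:
            assert d.n_turns >= 2
            assert d.n_turns == len(d.sentences)
            assert not any("-" in s for s in d.sentences)
            assert d.turns[-1].expected_smiles == d.final_smiles

    def test_rejections_partition(self, built, corpus):
        dialogues, rejections = built
        assert len(dialogues) + len(rejections) == len(corpus.records)
        assert {r.reason for r in rejections} <= {
            "single_turn", "hyphen", "no_candidate",
        }

    def test_rebuild_is_bit_identical(self, built, corpus):
        config = BuilderConfig(retain_low_sim=0.0)
        again, _ = build_corpus_dialogues(corpus, config, seed=13)
        assert [d.to_json() for d in built[0]] == [d.to_json() for d in again]


class TestJsonlCandidateHook:
    def test_stored_candidates_used_and_fallback(self, tmp_path):
        import json

        from moldialog.dialogue_builder import jsonl_candidate_generator

        path = tmp_path / "cands.jsonl"
        stored = ["CCN", "CCC", "CCCO", "CC", "C"]
        path.write_text(
            json.dumps({"final": "OCC", "candidates": stored}) + "\n"
        )
        gen = jsonl_candidate_generator(path)
        # lookup is by canonical SMILES: "CCO" resolves the "OCC" entry
        assert gen("text", "CCO", seed=0) == stored
        # unknown molecule falls back to the perturbation generator
        fallback = gen("text", "CCCCCC", seed=0)
        assert fallback == default_candidate_generator("text", "CCCCCC", seed=0)


class TestSplitDialogues:
    def test_partition_and_determinism(self, corpus):
        dialogues, _ = build_corpus_dialogues(
            corpus, BuilderConfig(), seed=1
        )
        splits = split_dialogues(dialogues)
        assert sum(len(v) for v in splits.values()) == len(dialogues)
        again = split_dialogues(dialogues)
        assert {k: [d.dialogue_id for d in v] for k, v in splits.items()} == {
            k: [d.dialogue_id for d in v] for k, v in again.items()
        }

    def test_bad_proportions(self):
        with pytest.raises(ValueError):
            split_dialogues([], proportions=(0.5, 0.2, 0.2))
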