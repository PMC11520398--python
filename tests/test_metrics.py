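"""Metric correctness against independent oracles and hand computations."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from moldialog.metrics import (
    GenerationPrediction,
    TextPrediction,
    bleu,
    evaluate,
    exact_match,
    fts,
    levenshtein,
    meteor,
    rouge_l,
    rouge_n,
    smiles_bleu,
    text_metrics,
)
from moldialog.synthetic_data import gen_molecules


def dp_levenshtein(a: str, b: str) -> int:
    """Independent quadratic dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


class TestExactMatch:
    def test_canonical_rewriting_matches(self):
        em, hit3 = exact_match(
            GenerationPrediction("x", ("OCC", "C", "CC"), "CCO")
        )
        assert (em, hit3) == (1, 1)

    def test_total_miss(self):
        em, hit3 = exact_match(
            GenerationPrediction("x", ("C", "CC", "CCC"), "CCO")
        )
        assert (em, hit3) == (0, 0)

    def test_hit_at_rank_two(self):
        em, hit3 = exact_match(
            GenerationPrediction("x", ("C", "CCO", "CC"), "CCO")
        )
        assert (em, hit3) == (0, 1)

    def test_invalid_prediction_is_nonmatch(self):
        em, hit3 = exact_match(GenerationPrediction("x", ("C((", "CCO"), "CCO"))
        assert (em, hit3) == (0, 1)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected", [("CCO", "CCO", 0), ("CCO", "CC=O", 1), ("", "CCO", 3)]
    )
    def test_known_pairs(self, a, b, expected):
        assert levenshtein(a, b) == expected

    def test_against_dp_oracle_random_pairs(self):
        rng = random.Random(0)
        alphabet = "CNOc1()=#[]Br"
        for _ in range(300):
            a = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 15)))
            b = "".join(rng.choice(alphabet) for _ in range(rng.randint(0, 15)))
            assert levenshtein(a, b) == dp_levenshtein(a, b)

    @given(st.text(alphabet="CNO()=1", max_size=12),
           st.text(alphabet="CNO()=1", max_size=12),
           st.text(alphabet="CNO()=1", max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestBleu:
    def test_identical_is_one(self):
        assert smiles_bleu("CCOCC", "CCOCC") == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        assert smiles_bleu("CCC", "NNN") == 0.0

    def test_hand_computed_pair(self):
        # pred "CCON" vs gold "CCO": 1-grams 3/4, 2-grams 2/3, 3-grams 1/2
        # (effective order 3 = len(gold)); BP = 1 since pred longer
        expected = (3 / 4 * 2 / 3 * 1 / 2) ** (1 / 3)
        assert smiles_bleu("CCON", "CCO") == pytest.approx(expected)

    def test_brevity_penalty(self):
        # pred "CC" vs gold "CCCC": 1-grams 2/2, 2-grams 1/1, BP = exp(1-2)
        expected = math.exp(1 - 4 / 2) * 1.0
        assert smiles_bleu("CC", "CCCC") == pytest.approx(expected)


class TestRouge:
    def test_hand_computed_unigram_f1(self):
        # pred 4 words, gold 5 words, 3 shared → P=3/4, R=3/5, F1=2PR/(P+R)
        pred = ["the", "molecule", "is", "red"]
        gold = ["the", "molecule", "is", "a", "liquid"]
        p, r = 3 / 4, 3 / 5
        assert rouge_n(pred, gold, 1) == pytest.approx(2 * p * r / (p + r))

    def test_rouge2_no_overlap(self):
        assert rouge_n(["a", "b"], ["b", "a"], 2) == 0.0

    def test_rouge_l_subsequence(self):
        # LCS("abcd","acbd") = "abd" (len 3): P=R=3/4
        assert rouge_l(list("abcd"), list("acbd")) == pytest.approx(3 / 4)


class TestMeteor:
    def test_identical_is_exactly_one(self):
        tokens = "the molecule is an organic acid".split()
        assert meteor(tokens, tokens) == pytest.approx(1.0, abs=1e-12)

    def test_reordering_penalized_but_matched(self):
        a = ["b", "a"]
        b = ["a", "b"]
        score = meteor(a, b)
        assert 0 < score < 1

    def test_no_match_is_zero(self):
        assert meteor(["x"], ["y"]) == 0.0


class TestFts:
    def test_identical(self):
        for scheme in ("rdk_path", "maccs", "morgan"):
            assert fts("CCO", "OCC", scheme) == pytest.approx(1.0)

    def test_invalid_pred_scores_zero(self):
        assert fts("C((", "CCO", "morgan") == 0.0

    def test_against_brute_force_bitsets(self):
        """Tanimoto equals |A∩B|/|A∪B| computed from scratch on the raw
        on-bit sets for a fixed small pair."""
        from moldialog.chem_core import fingerprint, parse_smiles

        a = fingerprint(parse_smiles("CCO"), "maccs")
        b = fingerprint(parse_smiles("CCN"), "maccs")
        expected = len(set(a.bits) & set(b.bits)) / len(set(a.bits) | set(b.bits))
        assert fts("CCO", "CCN", "maccs") == pytest.approx(expected)

    def test_symmetric(self):
        mols = [m.canonical_smiles for m in gen_molecules(10, seed=3)]
        for a in mols[:5]:
            for b in mols[5:]:
                assert fts(a, b, "rdk_path") == pytest.approx(fts(b, a, "rdk_path"))


class TestTextMetrics:
    def test_perfect_prediction(self):
        gold = "The molecule is an organic acid. It is corrosive."
        scores = text_metrics(gold, gold)
        for name, value in scores.items():
            assert value == pytest.approx(1.0, abs=1e-6), name

    def test_empty_prediction(self):
        scores = text_metrics("", "The molecule is white.")
        assert all(v == 0.0 for v in scores.values())

    def test_ranges(self):
        scores = text_metrics(
            "the molecule is a white solid", "the molecule is a colorless liquid"
        )
        assert all(0.0 <= v <= 1.0 for v in scores.values())


class TestEvaluate:
    def test_gold_as_prediction_is_perfect(self):
        preds = [
            GenerationPrediction(f"i{k}", (smi,), smi)
            for k, smi in enumerate(["CCO", "c1ccccc1", "CC(=O)O"])
        ]
        report = evaluate(preds, "generation")
        assert report.aggregate["EM"] == 1.0
        assert report.aggregate["hit@3"] == 1.0
        assert report.aggregate["Leven"] == 0.0
        for col in ("BL", "RDK", "MAC", "Morgan"):
            assert report.aggregate[col] == pytest.approx(1.0)

    def test_em_bounded_by_hit3_on_random_predictions(self):
        rng = random.Random(1)
        pool = [m.canonical_smiles for m in gen_molecules(20, seed=5)]
        preds = []
        for k in range(30):
            top3 = tuple(rng.choice(pool) for _ in range(3))
            preds.append(GenerationPrediction(f"r{k}", top3, rng.choice(pool)))
        report = evaluate(preds, "generation")
        assert report.aggregate["EM"] <= report.aggregate["hit@3"]
        per = report.per_item
        assert (per["EM"] <= per["hit@3"]).all()

    def test_single_item_aggregate_equals_item(self):
        preds = [GenerationPrediction("only", ("CCN",), "CCO")]
        report = evaluate(preds, "generation")
        row = report.per_item.iloc[0]
        for col in ("EM", "hit@3", "BL", "Leven", "RDK", "MAC", "Morgan"):
            assert report.aggregate[col] == pytest.approx(row[col])

    def test_understanding_report(self):
        preds = [TextPrediction("a", "the molecule is white", "the molecule is white")]
        report = evaluate(preds, "understanding")
        assert report.n_items == 1
        assert report.aggregate["MET"] == pytest.approx(1.0, abs=1e-6)

    def test_report_io(self, tmp_path):
        preds = [GenerationPrediction("a", ("CCO",), "CCO")]
        report = evaluate(preds, "generation")
        report.write(tmp_path / "rep")
        assert (tmp_path / "rep.tsv").exists()
        assert (tmp_path / "rep.json").exists()
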