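"""Evaluation metrics for molecule understanding and generation.

Understanding (molecule → description) is scored with text metrics:
BLEU-2/4, ROUGE-1/2/L F-scores, and METEOR. Generation (description →
molecule) is scored with exact match and hit@3 on canonical SMILES,
character-level SMILES BLEU, Levenshtein distance on the raw strings, and
fingerprint Tanimoto similarity under the RDK-path, MACCS, and Morgan
schemes. Generation-side similarity metrics score the rank-1 prediction.

Invalid predicted SMILES never crash the evaluation: they count as
non-matches, score 0 on fingerprint similarity, and still get a
Levenshtein distance on the raw string.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import edlib
import pandas as pd

from .chem_core import (
    FingerprintScheme,
    InvalidSmilesError,
    canonicalize,
    fingerprint,
    parse_smiles,
    tanimoto,
)
from .tokenization import tokenize_words

__all__ = [
    "GenerationPrediction",
    "TextPrediction",
    "EvalReport",
    "exact_match",
    "levenshtein",
    "smiles_bleu",
    "fts",
    "text_metrics",
    "bleu",
    "rouge_n",
    "rouge_l",
    "meteor",
    "evaluate",
    "evaluate_file",
]

UNDERSTANDING_COLUMNS = ["BL-2", "BL-4", "RG-1", "RG-2", "RG-L", "MET"]
GENERATION_COLUMNS = ["EM", "hit@3", "BL", "Leven", "RDK", "MAC", "Morgan"]

_FTS_COLUMN = {
    "RDK": FingerprintScheme.RDK_PATH,
    "MAC": FingerprintScheme.MACCS,
    "Morgan": FingerprintScheme.MORGAN,
}


@dataclass(frozen=True)
class GenerationPrediction:
    """Ranked molecule predictions for one item (at most three)."""

    item_id: str
    top3: Sequence[str]
    gold: str

    def __post_init__(self):
        if not self.top3:
            raise ValueError("top3 must be non-empty")


@dataclass(frozen=True)
class TextPrediction:
    """A predicted description for one item."""

    item_id: str
    text: str
    gold: str


def exact_match(pred: GenerationPrediction):
    """(em, hit3): canonical-SMILES match of rank 1 / any of the top 3.

    Unparseable predictions count as non-matches.
    """
    gold = canonicalize(pred.gold)
    matches = []
    for smi in list(pred.top3)[:3]:
        try:
            matches.append(canonicalize(smi) == gold)
        except InvalidSmilesError:
            matches.append(False)
    em = int(matches[0])
    hit3 = int(any(matches))
    return em, hit3


def levenshtein(pred: str, gold: str) -> int:
    """Unit-cost edit distance between two raw strings."""
    if not pred or not gold:
        return max(len(pred), len(gold))
    return edlib.align(pred, gold, mode="NW", task="distance")["editDistance"]


def _ngrams(tokens: Sequence, n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(pred_tokens: Sequence, gold_tokens: Sequence, max_n: int = 4) -> float:
    """Sentence BLEU with brevity penalty.

    The effective order is capped at the shorter sequence length so that a
    perfect one-token prediction still scores 1. Zero higher-order
    precisions are floor-smoothed (1/(2·count)); a zero unigram precision
    yields 0 outright.
    """
    if not pred_tokens or not gold_tokens:
        return 0.0
    n_max = min(max_n, len(pred_tokens), len(gold_tokens))
    log_p = 0.0
    for n in range(1, n_max + 1):
        pred_counts = _ngrams(pred_tokens, n)
        gold_counts = _ngrams(gold_tokens, n)
        total = sum(pred_counts.values())
        matched = sum(min(c, gold_counts[g]) for g, c in pred_counts.items())
        if n == 1 and matched == 0:
            return 0.0
        p = matched / total if matched else 1.0 / (2.0 * total)
        log_p += math.log(p) / n_max
    bp = 1.0 if len(pred_tokens) >= len(gold_tokens) else math.exp(
        1.0 - len(gold_tokens) / len(pred_tokens)
    )
    return bp * math.exp(log_p)


def smiles_bleu(pred: str, gold: str) -> float:
    """BLEU on character tokens (up to 4-grams) of two SMILES strings."""
    return bleu(list(pred), list(gold), max_n=4)


def fts(pred: str, gold: str, scheme: FingerprintScheme | str) -> float:
    """Fingerprint Tanimoto similarity; an unparseable prediction scores 0."""
    gold_fp = fingerprint(parse_smiles(gold), scheme)
    try:
        pred_fp = fingerprint(parse_smiles(pred), scheme)
    except InvalidSmilesError:
        return 0.0
    return tanimoto(pred_fp, gold_fp)


def rouge_n(pred_tokens: Sequence, gold_tokens: Sequence, n: int) -> float:
    """ROUGE-N F1: clipped n-gram overlap."""
    pred_counts = _ngrams(pred_tokens, n)
    gold_counts = _ngrams(gold_tokens, n)
    overlap = sum(min(c, pred_counts[g]) for g, c in gold_counts.items())
    total_pred = sum(pred_counts.values())
    total_gold = sum(gold_counts.values())
    if overlap == 0 or not total_pred or not total_gold:
        return 0.0
    precision = overlap / total_pred
    recall = overlap / total_gold
    return 2 * precision * recall / (precision + recall)


def _lcs_length(a: Sequence, b: Sequence) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_l(pred_tokens: Sequence, gold_tokens: Sequence) -> float:
    """ROUGE-L F1 from the longest common subsequence."""
    if not pred_tokens or not gold_tokens:
        return 0.0
    lcs = _lcs_length(pred_tokens, gold_tokens)
    if lcs == 0:
        return 0.0
    precision = lcs / len(pred_tokens)
    recall = lcs / len(gold_tokens)
    return 2 * precision * recall / (precision + recall)


# METEOR parameters (exact-match configuration, no external synonym source)
_METEOR_ALPHA = 0.9
_METEOR_BETA = 3.0
_METEOR_GAMMA = 0.5


def meteor(pred_tokens: Sequence, gold_tokens: Sequence) -> float:
    """Exact-match METEOR with a fragmentation penalty.

    Unigrams are aligned greedily in order; the harmonic mean weights
    recall 9:1 over precision. Fragmentation is measured as
    (chunks−1)/(matches−1), so a perfectly ordered full match is not
    penalized and identical sequences score exactly 1.
    """
    if not pred_tokens or not gold_tokens:
        return 0.0
    used = [False] * len(gold_tokens)
    positions = []  # gold position of each matched pred token, in pred order
    for tok in pred_tokens:
        for j, g in enumerate(gold_tokens):
            if not used[j] and g == tok:
                used[j] = True
                positions.append(j)
                break
    m = len(positions)
    if m == 0:
        return 0.0
    precision = m / len(pred_tokens)
    recall = m / len(gold_tokens)
    f_mean = precision * recall / (
        _METEOR_ALPHA * precision + (1 - _METEOR_ALPHA) * recall
    )
    chunks = 1 + sum(
        1 for a, b in zip(positions, positions[1:]) if b != a + 1
    )
    frag = (chunks - 1) / max(m - 1, 1)
    penalty = _METEOR_GAMMA * frag ** _METEOR_BETA
    return f_mean * (1 - penalty)


def text_metrics(pred: str, gold: str) -> Dict[str, float]:
    """All understanding metrics for one (prediction, reference) pair.

    Tokens are lowercased words; all scores lie in [0, 1].
    """
    p = [t.lower() for t in tokenize_words(pred)]
    g = [t.lower() for t in tokenize_words(gold)]
    return {
        "bleu2": bleu(p, g, max_n=2),
        "bleu4": bleu(p, g, max_n=4),
        "rouge1": rouge_n(p, g, 1),
        "rouge2": rouge_n(p, g, 2),
        "rougeL": rouge_l(p, g),
        "meteor": meteor(p, g),
    }


@dataclass
class EvalReport:
    """Aggregate metric table mirroring the standard result columns."""

    task: str  # "understanding" | "generation"
    per_item: pd.DataFrame
    aggregate: Dict[str, float]
    n_items: int

    def write(self, out_prefix: str | Path) -> None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        self.per_item.to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
        with open(f"{out_prefix}.json", "w") as fh:
            json.dump(
                {"task": self.task, "n_items": self.n_items, "aggregate": self.aggregate},
                fh,
                indent=2,
                sort_keys=True,
            )


_TEXT_TO_COLUMN = {
    "bleu2": "BL-2", "bleu4": "BL-4", "rouge1": "RG-1",
    "rouge2": "RG-2", "rougeL": "RG-L", "meteor": "MET",
}


def evaluate(predictions: Iterable, task: str) -> EvalReport:
    """Score a batch of predictions.

    ``task`` is "understanding" (TextPrediction items) or "generation"
    (GenerationPrediction items). Aggregates are the per-item means;
    generation similarity columns are computed on the rank-1 prediction.
    """
    rows = []
    if task == "understanding":
        for p in predictions:
            scores = text_metrics(p.text, p.gold)
            rows.append(
                {"item_id": p.item_id}
                | {_TEXT_TO_COLUMN[k]: v for k, v in scores.items()}
            )
        columns = UNDERSTANDING_COLUMNS
    elif task == "generation":
        for p in predictions:
            em, hit3 = exact_match(p)
            top1 = p.top3[0]
            row = {
                "item_id": p.item_id,
                "EM": em,
                "hit@3": hit3,
                "BL": smiles_bleu(top1, p.gold),
                "Leven": levenshtein(top1, p.gold),
            }
            for col, scheme in _FTS_COLUMN.items():
                row[col] = fts(top1, p.gold, scheme)
            rows.append(row)
        columns = GENERATION_COLUMNS
    else:
        raise ValueError(f"unknown task {task!r}")
    if not rows:
        raise ValueError("no predictions to evaluate")
    per_item = pd.DataFrame(rows, columns=["item_id"] + columns)
    aggregate = {c: float(per_item[c].mean()) for c in columns}
    return EvalReport(
        task=task, per_item=per_item, aggregate=aggregate, n_items=len(rows)
    )


def evaluate_file(path: str | Path, task: str) -> EvalReport:
    """Evaluate a predictions JSONL file.

    Generation lines: {"item_id", "top3": [...], "gold"};
    understanding lines: {"item_id", "text", "gold"}.
    """
    preds: List = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            if task == "generation":
                preds.append(
                    GenerationPrediction(d["item_id"], tuple(d["top3"]), d["gold"])
                )
            else:
                preds.append(TextPrediction(d["item_id"], d["text"], d["gold"]))
    return evaluate(preds, task)
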