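"""Entity annotation and SMILES prompting with answer-leakage removal.

Chemical names found in the input text (via a local name→SMILES lexicon,
standing in for a live NER + compound database) are attached to the model
input as retrieval hints. Any hint whose molecule is canonical-equal to an
answer molecule is removed first, so the prompt can never reveal the
expected output. Canonical (structural) equality is used rather than
string equality: a rewriting of the same molecule is still a leak.
"""

from __future__ import annotations

import re
from typing import Iterable, List, Tuple

from .chem_core import InvalidSmilesError, canonicalize
from .records import Dialogue, PromptedInput

__all__ = ["annotate", "build_prompt", "prompt_dialogue_turns"]

HINT_HEADER = "Known molecules:"


def annotate(text: str, lexicon: dict) -> List[Tuple[str, str, Tuple[int, int]]]:
    """Find lexicon names in ``text``.

    Case-insensitive whole-word matching; overlaps resolve to the longest
    match; results are non-overlapping spans in textual order, each as
    (name, smiles, (start, end)).
    """
    if not lexicon:
        raise ValueError("empty lexicon")
    # longest names first so alternation prefers the maximal match
    names = sorted(lexicon, key=len, reverse=True)
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(n) for n in names) + r")\b", re.IGNORECASE
    )
    out = []
    for m in pattern.finditer(text):
        matched = m.group(1)
        # recover the lexicon's casing of the name
        name = next(n for n in names if n.lower() == matched.lower())
        out.append((name, lexicon[name], (m.start(), m.end())))
    return out


def build_prompt(
    text: str,
    annotations: Iterable[Tuple[str, str, Tuple[int, int]]],
    answers: Iterable[str],
    item_id: str = "",
) -> PromptedInput:
    """Attach surviving annotation hints to ``text``.

    Annotations whose SMILES is canonical-equal to any answer are dropped.
    The prompt is the text followed by a trailing
    ``Known molecules: name1: SMILES1; ...`` block (empty block omitted).
    """
    answer_canon = set()
    for a in answers:
        try:
            answer_canon.add(canonicalize(a))
        except InvalidSmilesError:
            continue
    kept = []
    for name, smiles, span in annotations:
        try:
            if canonicalize(smiles) in answer_canon:
                continue
        except InvalidSmilesError:
            continue
        kept.append((name, smiles, tuple(span)))
    if kept:
        hints = "; ".join(f"{n}: {s}" for n, s, _sp in kept)
        prompt = f"{text} {HINT_HEADER} {hints}"
    else:
        prompt = text
    return PromptedInput(
        item_id=item_id, text=text, annotations=tuple(kept), prompt=prompt
    )


def prompt_dialogue_turns(dialogue: Dialogue, lexicon: dict) -> List[PromptedInput]:
    """Prompted inputs for every turn of a dialogue.

    The answer set for leakage removal is every expected molecule of the
    dialogue (intermediate and final), so no turn's hints can contain any
    molecule the model is supposed to produce.
    """
    answers = [t.expected_smiles for t in dialogue.turns] + [dialogue.final_smiles]
    out = []
    for turn in dialogue.turns:
        annotations = annotate(turn.text, lexicon)
        out.append(
            build_prompt(
                turn.text,
                annotations,
                answers,
                item_id=f"{dialogue.dialogue_id}_t{turn.k}",
            )
        )
    return out
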