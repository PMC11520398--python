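"""Description sentence templates and their verification predicates.

Every sentence the synthetic corpus can emit is enumerated here, together
with a predicate that checks the stated fact against the molecular graph.
This makes the generator auditable: an automated fact checker can map any
generated sentence back to its template and verify the claim.

Templates are either ``fine`` (specific substructure claims, emitted first)
or ``general`` (overall property claims, emitted last). No template text
contains the character "-" (the dialogue builder rejects such sentences) or
a molecule name (descriptions say "The molecule ...").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Optional

from rdkit import Chem

from .chem_core import Molecule, smiles_similarity

FINE = "fine"
GENERAL = "general"

# similarity floor for the "structurally related" claim (RDK path Tanimoto)
RELATED_MIN_SIMILARITY = 0.4

_NUM_WORDS = {
    "three": 3, "four": 4, "five": 5, "six": 6, "seven": 7, "eight": 8,
}
_WORD_NUMS = {v: k for k, v in _NUM_WORDS.items()}

_HALOGENS = {"fluorine": "F", "chlorine": "Cl", "bromine": "Br"}


def _smarts(mol: Molecule, pattern: str) -> bool:
    return mol.rdkit_mol().HasSubstructMatch(Chem.MolFromSmarts(pattern))


def _has_element(mol: Molecule, symbol: str) -> bool:
    return any(el == symbol for _i, el, _ar in mol.atoms)


def _fully_saturated(mol: Molecule) -> bool:
    return all(order == "single" for _i, _j, order in mol.bonds)


def _ring_of_size(mol: Molecule, n: int) -> bool:
    return any(len(r) == n for r in mol.rings)


def _aromatic_six_ring(mol: Molecule) -> bool:
    return any(
        len(r) == 6 and all(mol.atoms[i][2] for i in r) for r in mol.rings
    )


@dataclass(frozen=True)
class Template:
    """One sentence template.

    ``render`` fills slots from a feature dict; ``pattern`` recognizes a
    rendered sentence and extracts the slots; ``check`` verifies the claim
    against the molecule (and, for cross-molecule claims, the lexicon).
    """

    template_id: str
    kind: str  # FINE or GENERAL
    text: str  # format string
    pattern: str  # regex with named groups matching rendered text
    check: Callable  # (mol, slots, lexicon) -> bool

    def render(self, **slots) -> str:
        return self.text.format(**slots)

    def match(self, sentence: str) -> Optional[dict]:
        m = re.fullmatch(self.pattern, sentence.strip())
        return m.groupdict() if m else None


TEMPLATES = [
    # -- fine-structure claims -------------------------------------------
    Template(
        "hydroxyl", FINE,
        "The molecule contains a hydroxyl group.",
        r"The molecule contains a hydroxyl group\.",
        lambda mol, s, lex: _smarts(mol, "[CX4][OX2H]"),
    ),
    Template(
        "carboxyl", FINE,
        "The molecule contains a carboxylic acid group.",
        r"The molecule contains a carboxylic acid group\.",
        lambda mol, s, lex: _smarts(mol, "[CX3](=O)[OX2H1]"),
    ),
    Template(
        "amino", FINE,
        "The molecule contains a primary amino group.",
        r"The molecule contains a primary amino group\.",
        lambda mol, s, lex: _smarts(mol, "[NX3;H2]"),
    ),
    Template(
        "halogen_atom", FINE,
        "The molecule contains a {halogen} atom.",
        r"The molecule contains a (?P<halogen>fluorine|chlorine|bromine) atom\.",
        lambda mol, s, lex: _has_element(mol, _HALOGENS[s["halogen"]]),
    ),
    Template(
        "aromatic_ring", FINE,
        "The molecule contains an aromatic ring of six atoms.",
        r"The molecule contains an aromatic ring of six atoms\.",
        lambda mol, s, lex: _aromatic_six_ring(mol),
    ),
    Template(
        "ring_size", FINE,
        "The molecule contains a ring of {size} atoms.",
        r"The molecule contains a ring of (?P<size>three|four|five|six|seven|eight) atoms\.",
        lambda mol, s, lex: _ring_of_size(mol, _NUM_WORDS[s["size"]]),
    ),
    Template(
        "heavy_atoms", FINE,
        "The molecule has {n} heavy atoms.",
        r"The molecule has (?P<n>\d+) heavy atoms\.",
        lambda mol, s, lex: mol.n_atoms == int(s["n"]),
    ),
    Template(
        "carbon_count", FINE,
        "The molecule contains {n} carbon atoms.",
        r"The molecule contains (?P<n>\d+) carbon atoms\.",
        lambda mol, s, lex: sum(el == "C" for _i, el, _a in mol.atoms) == int(s["n"]),
    ),
    # -- general-property claims -----------------------------------------
    Template(
        "org_acid", GENERAL,
        "The molecule is an organic acid.",
        r"The molecule is an organic acid\.",
        lambda mol, s, lex: _smarts(mol, "[CX3](=O)[OX2H1]"),
    ),
    Template(
        "org_base", GENERAL,
        "The molecule is an organic base.",
        r"The molecule is an organic base\.",
        lambda mol, s, lex: _smarts(mol, "[NX3;H2]"),
    ),
    Template(
        "alcohol_role", GENERAL,
        "The molecule is an alcohol.",
        r"The molecule is an alcohol\.",
        lambda mol, s, lex: _smarts(mol, "[CX4][OX2H]"),
    ),
    Template(
        "aromatic_role", GENERAL,
        "The molecule is an aromatic compound.",
        r"The molecule is an aromatic compound\.",
        lambda mol, s, lex: any(ar for _i, _el, ar in mol.atoms),
    ),
    Template(
        "saturated", GENERAL,
        "The molecule is a fully saturated compound.",
        r"The molecule is a fully saturated compound\.",
        lambda mol, s, lex: _fully_saturated(mol),
    ),
    Template(
        "halogenated", GENERAL,
        "The molecule is a halogenated compound.",
        r"The molecule is a halogenated compound\.",
        lambda mol, s, lex: any(_has_element(mol, x) for x in ("F", "Cl", "Br")),
    ),
    Template(
        "organic", GENERAL,
        "The molecule is an organic compound.",
        r"The molecule is an organic compound\.",
        lambda mol, s, lex: _has_element(mol, "C"),
    ),
    Template(
        "related", GENERAL,
        "The molecule is structurally related to {name}.",
        r"The molecule is structurally related to (?P<name>[a-z]+)\.",
        lambda mol, s, lex: (
            lex is not None
            and s["name"] in lex
            and smiles_similarity(mol.canonical_smiles, lex[s["name"]])
            >= RELATED_MIN_SIMILARITY
        ),
    ),
]

TEMPLATE_INDEX = {t.template_id: t for t in TEMPLATES}


def applicable_templates(mol: Molecule):
    """(template, slots) pairs whose claim is true of ``mol``.

    Slot-bearing templates are instantiated with every true slot filling.
    The open-ended ``related`` template is excluded (it needs a lexicon and
    is attached by the corpus generator).
    """
    out = []
    n_carbon = sum(el == "C" for _i, el, _a in mol.atoms)
    for t in TEMPLATES:
        if t.template_id == "halogen_atom":
            for word, sym in _HALOGENS.items():
                if _has_element(mol, sym):
                    out.append((t, {"halogen": word}))
        elif t.template_id == "ring_size":
            for r in {len(r) for r in mol.rings}:
                if r in _WORD_NUMS:
                    out.append((t, {"size": _WORD_NUMS[r]}))
        elif t.template_id == "heavy_atoms":
            out.append((t, {"n": str(mol.n_atoms)}))
        elif t.template_id == "carbon_count":
            if n_carbon:
                out.append((t, {"n": str(n_carbon)}))
        elif t.template_id == "related":
            continue
        elif t.check(mol, {}, None):
            out.append((t, {}))
    return out


def verify_sentence(sentence: str, mol: Molecule, lexicon: Optional[dict] = None):
    """Match ``sentence`` to a template and verify its claim.

    Returns (template_id, True/False), or (None, False) if no template
    matches the sentence at all.
    """
    for t in TEMPLATES:
        slots = t.match(sentence)
        if slots is not None:
            return t.template_id, bool(t.check(mol, slots, lexicon))
    return None, False


def verify_description(description: str, mol: Molecule, lexicon=None) -> bool:
    """True iff every sentence of ``description`` is a verified template claim."""
    from .dialogue_builder import split_sentences  # local import, no cycle

    for sentence in split_sentences(description):
        _tid, ok = verify_sentence(sentence, mol, lexicon)
        if not ok:
            return False
    return True
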