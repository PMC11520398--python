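"""Synthetic molecule–description corpora with known ground truth.

Emulates ChEBI-20-style parallel data: small organic molecules from a
closed structural grammar, multi-sentence descriptions ordered from fine
structural detail to general properties, a pseudo-name lexicon, and a
table of experimental properties. Because every description sentence comes
from :mod:`moldialog.templates`, every stated fact is mechanically
verifiable against the molecular graph — which is what makes the
downstream dialogue, knowledge-task, and prompting stages testable without
any external downloads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .chem_core import Molecule, parse_smiles, fingerprint, tanimoto, FingerprintScheme
from .records import (
    DescribedMolecule,
    read_jsonl,
    write_jsonl,
    read_lexicon,
    write_lexicon,
    read_property_table,
    write_property_table,
)
from . import templates as T

__all__ = [
    "SyntheticCorpus",
    "gen_molecules",
    "gen_description",
    "gen_corpus",
    "gen_snippets",
    "PROPERTY_VALUES",
]

# ---------------------------------------------------------------------------
# molecular grammar
#
# chain of 1-8 carbons, optional methyl/ethyl branch, functional group in
# {alkane, alcohol, amine, acid}, optional ring (benzene, cyclopropane,
# cyclohexane) fused at the chain head, optional halogen. Weights chosen so
# a realistic share of molecules carry rings and heteroatoms.
# ---------------------------------------------------------------------------

_GROUPS = {"alkane": "", "alcohol": "O", "amine": "N", "acid": "C(=O)O"}
_RINGS = {"benzene": "c1ccccc1", "cyclopropane": "C1CC1", "cyclohexane": "C1CCCCC1"}
_HALOGENS = ["F", "Cl", "Br"]

P_RING = 0.4
P_HALOGEN = 0.25
P_BRANCH = 0.35


def _random_smiles(rng: random.Random) -> str:
    length = rng.randint(1, 8)
    group = rng.choice(sorted(_GROUPS))
    ring = rng.choice(sorted(_RINGS)) if rng.random() < P_RING else None
    halogen = rng.choice(_HALOGENS) if rng.random() < P_HALOGEN else None
    branch_pos = (
        rng.randrange(length) if (length >= 2 and rng.random() < P_BRANCH) else None
    )
    branch = rng.choice(["(C)", "(CC)"]) if branch_pos is not None else ""

    chain = "".join(
        "C" + (branch if i == branch_pos else "") for i in range(length)
    )
    smiles = (halogen or "") + (_RINGS[ring] if ring else "") + chain + _GROUPS[group]
    return smiles


def gen_molecules(n: int, seed: int) -> list:
    """Generate ``n`` distinct valid molecules from the closed grammar.

    Deterministic for a fixed seed; distinctness is by canonical SMILES.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    seen: dict = {}
    attempts = 0
    while len(seen) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError(f"grammar exhausted after {attempts} attempts")
        mol = parse_smiles(_random_smiles(rng))
        seen.setdefault(mol.canonical_smiles, mol)
    return list(seen.values())[:n]


def gen_description(
    mol: Molecule,
    n_sentences: int,
    seed: int,
    extra_general: Optional[list] = None,
) -> str:
    """A 2–6 sentence description of ``mol`` from verified templates.

    Fine-structure sentences come first, general-property sentences last,
    mirroring how curated molecule descriptions are ordered. ``extra_general``
    lets the corpus generator append pre-verified general sentences (e.g.
    cross-molecule similarity claims). Deterministic per (mol, seed).
    """
    if not 2 <= n_sentences <= 6:
        raise ValueError("n_sentences must be in 2..6")
    rng = random.Random((seed, mol.canonical_smiles).__str__())
    pool = T.applicable_templates(mol)
    fine = [(t, s) for t, s in pool if t.kind == T.FINE]
    general = [(t, s) for t, s in pool if t.kind == T.GENERAL]
    rng.shuffle(fine)
    rng.shuffle(general)

    extra = list(extra_general or [])
    n_general_wanted = max(1, n_sentences // 2)
    n_fine = min(len(fine), n_sentences - n_general_wanted)
    n_general = min(len(general) + len(extra), n_sentences - n_fine)

    sentences = [t.render(**s) for t, s in fine[:n_fine]]
    general_sentences = [t.render(**s) for t, s in general[:]]
    # extras go in front of the generic role sentences
    general_block = extra + general_sentences
    sentences += general_block[:n_general]
    assert all("-" not in s for s in sentences)
    return " ".join(sentences)


# ---------------------------------------------------------------------------
# pseudo-names and properties
# ---------------------------------------------------------------------------

_NAME_STEMS = ["vel", "dor", "mek", "tal", "zun", "fir", "lob", "quen", "ras", "hyd", "cor", "pex"]
_NAME_MIDS = ["a", "o", "i", "u", "ar", "en", "ol", "ev", "ys", "um"]
_NAME_SUFFIXES = ["ine", "ol", "ane", "ium", "ate", "one"]


def _pseudo_name(index: int) -> str:
    """Deterministic pronounceable pseudo-name for molecule ``index``."""
    s = _NAME_STEMS[index % len(_NAME_STEMS)]
    index //= len(_NAME_STEMS)
    m = _NAME_MIDS[index % len(_NAME_MIDS)]
    index //= len(_NAME_MIDS)
    x = _NAME_SUFFIXES[index % len(_NAME_SUFFIXES)]
    index //= len(_NAME_SUFFIXES)
    extra = "".join(
        _NAME_MIDS[d % len(_NAME_MIDS)] for d in _digits(index, len(_NAME_MIDS))
    )
    return s + m + extra + x


def _digits(n: int, base: int):
    while n:
        yield n % base
        n //= base


# the 15 experimental property types with their admissible value texts
PROPERTY_VALUES = {
    "solubility": [
        "freely soluble in water", "slightly soluble in water",
        "insoluble in water", "soluble in ethanol",
    ],
    "color": ["white", "colorless", "pale yellow", "light brown"],
    "corrosivity": ["corrosive to metals", "noncorrosive", "mildly corrosive to skin"],
    "odor": ["odorless", "pungent odor", "sweet odor", "fruity odor"],
    "physical state": [
        "liquid at room temperature", "solid at room temperature",
        "gas at room temperature",
    ],
    "melting point": [
        "melts below zero degrees Celsius", "melts near room temperature",
        "melts above 100 degrees Celsius",
    ],
    "boiling point": [
        "boils below 50 degrees Celsius", "boils near 100 degrees Celsius",
        "boils above 200 degrees Celsius",
    ],
    "density": ["less dense than water", "denser than water"],
    "flammability": ["highly flammable", "flammable", "not flammable"],
    "toxicity": ["toxic if ingested", "harmful if inhaled", "of low toxicity"],
    "stability": ["stable under normal conditions", "unstable when heated"],
    "viscosity": ["of low viscosity", "of high viscosity"],
    "vapor pressure": ["of low vapor pressure", "of high vapor pressure"],
    "reactivity": ["reactive with strong oxidizers", "inert to most reagents"],
    "acidity": ["weakly acidic in solution", "weakly basic in solution", "neutral in solution"],
}

MIN_PROPERTIES = 3
MAX_PROPERTIES = 15

# chance that a description gains a cross-molecule similarity sentence
P_RELATED_SENTENCE = 0.3


@dataclass
class SyntheticCorpus:
    """A bundle of parallel records, a name lexicon, and a property table."""

    records: list  # of DescribedMolecule
    lexicon: dict  # name -> SMILES
    property_table: dict  # molecule_id -> {property -> value_text}
    seed: int

    def molecules(self) -> dict:
        return {r.molecule_id: parse_smiles(r.smiles) for r in self.records}

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        write_jsonl(out_dir / "corpus.jsonl", self.records)
        write_lexicon(out_dir / "lexicon.tsv", self.lexicon)
        write_property_table(out_dir / "properties.tsv", self.property_table)

    @classmethod
    def read(cls, in_dir: str | Path, seed: int = -1) -> "SyntheticCorpus":
        in_dir = Path(in_dir)
        return cls(
            records=read_jsonl(in_dir / "corpus.jsonl", DescribedMolecule),
            lexicon=read_lexicon(in_dir / "lexicon.tsv"),
            property_table=read_property_table(in_dir / "properties.tsv"),
            seed=seed,
        )


def gen_corpus(n: int, seed: int) -> SyntheticCorpus:
    """Generate a corpus of ``n`` described molecules plus lexicon and
    property table, bit-identical across runs for a fixed seed."""
    rng = random.Random(seed)
    mols = gen_molecules(n, seed)
    names = [_pseudo_name(i) for i in range(n)]
    lexicon = dict(zip(names, (m.canonical_smiles for m in mols)))

    # precompute RDK path fingerprints once for related-molecule claims
    fps = [fingerprint(m, FingerprintScheme.RDK_PATH) for m in mols]

    records = []
    property_table: dict = {}
    for i, mol in enumerate(mols):
        molecule_id = f"syn{i:05d}"
        extra_general = []
        if n > 1 and rng.random() < P_RELATED_SENTENCE:
            sims = [
                (tanimoto(fps[i], fps[j]), j) for j in range(n) if j != i
            ]
            best_sim, best_j = max(sims)
            if best_sim >= T.RELATED_MIN_SIMILARITY:
                extra_general.append(
                    T.TEMPLATE_INDEX["related"].render(name=names[best_j])
                )
        n_sentences = rng.randint(2, 6)
        description = gen_description(
            mol, n_sentences, seed, extra_general=extra_general
        )
        records.append(
            DescribedMolecule(
                molecule_id=molecule_id,
                smiles=mol.canonical_smiles,
                description=description,
            )
        )
        props = rng.sample(
            sorted(PROPERTY_VALUES), rng.randint(MIN_PROPERTIES, MAX_PROPERTIES)
        )
        property_table[molecule_id] = {
            p: rng.choice(PROPERTY_VALUES[p]) for p in props
        }
    return SyntheticCorpus(
        records=records, lexicon=lexicon, property_table=property_table, seed=seed
    )


_SNIPPET_TEMPLATES = [
    "The reaction of {a} with {b} was studied in detail.",
    "Trace amounts of {a} were detected alongside {b} in the extract.",
    "Researchers compared the stability of {a} and {b} under heating.",
    "A solution of {a} was titrated against {b}.",
    "The sample contained {a} as the major component.",
    "Purified {a} was characterized by spectroscopy.",
]


def gen_snippets(lexicon: dict, n: int, seed: int) -> list:
    """Literature-style text snippets mentioning lexicon names.

    Stand-ins for mined literature segments; inputs for the molecule
    mapping correlation task.
    """
    rng = random.Random(seed)
    names = sorted(lexicon)
    out = []
    for _ in range(n):
        tmpl = rng.choice(_SNIPPET_TEMPLATES)
        need = 2 if "{b}" in tmpl else 1
        picks = rng.sample(names, min(need, len(names)))
        if need == 2 and len(picks) == 1:
            picks = picks * 2
        out.append(tmpl.format(a=picks[0], b=picks[-1]))
    return out
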