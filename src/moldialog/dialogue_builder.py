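"""Multi-turn dialogue construction from molecule–description pairs.

A description is split into sentences and the sentence order reversed, so
that detail accumulates turn by turn. Each non-final turn gets an expected
intermediate molecule picked from five generated candidates whose RDK-path
fingerprint Tanimoto similarity to the final answer lies strictly inside a
gate (default (0.5, 1.0) — similar enough to be on track, but never the
answer itself). Items with a single turn, or with "-" in a sentence (a
proxy for systematic nomenclature that would reveal the answer), are
rejected. A small configurable fraction of turns whose candidate set fails
the gate is retained anyway, keeping low-similarity variety in the data.

The candidate generator is pluggable: the default produces structural
perturbations of the final molecule, and any external generator (e.g. a
large captioning model) can be substituted via the same interface.
"""

from __future__ import annotations

import hashlib
import random
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from rdkit import Chem

from .chem_core import (
    FingerprintScheme,
    InvalidSmilesError,
    canonicalize,
    fingerprint,
    parse_smiles,
    tanimoto,
)
from .records import DescribedMolecule, Dialogue, Turn

__all__ = [
    "BuilderConfig",
    "Rejection",
    "split_sentences",
    "split_and_reverse",
    "replace_synonyms",
    "select_intermediate",
    "make_turn_input",
    "default_candidate_generator",
    "build_dialogue",
    "build_corpus_dialogues",
    "split_dialogues",
]

N_CANDIDATES = 5

# sentence-final abbreviations that must not end a sentence split
_ABBREVIATIONS = ("e.g.", "i.e.", "etc.", "approx.", "cf.", "vs.")

_SENTENCE_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list:
    """Rule-based sentence segmentation on terminal punctuation.

    Splits after ./!/? followed by whitespace, re-joining pieces that end
    with a guarded abbreviation.
    """
    pieces = [p for p in _SENTENCE_BOUNDARY.split(text.strip()) if p]
    out: list = []
    for piece in pieces:
        if out and out[-1].lower().endswith(_ABBREVIATIONS):
            out[-1] = out[-1] + " " + piece
        else:
            out.append(piece)
    return out


def split_and_reverse(description: str) -> list:
    """Sentences of ``description`` in reversed order, so that specific
    structural detail arrives in later turns."""
    if not description.strip():
        raise ValueError("empty description")
    return list(reversed(split_sentences(description)))


def replace_synonyms(text: str, synonyms: Iterable[str]) -> str:
    """Replace each synonym by "the molecule" (case-insensitive, whole word,
    longest synonym first so nested names are not double-replaced)."""
    names = sorted({s for s in synonyms if s}, key=len, reverse=True)
    if not names:
        return text
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(n) for n in names) + r")\b", re.IGNORECASE
    )
    return pattern.sub("the molecule", text)


def select_intermediate(
    candidates: list,
    final: str,
    lo: float,
    hi: float,
    seed: int,
) -> Optional[str]:
    """Randomly pick a candidate whose RDK-path Tanimoto to ``final`` is
    strictly inside (lo, hi); None when no candidate qualifies.

    Unparseable candidates are silently ineligible.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    if not candidates:
        raise ValueError("empty candidate list")
    fp_final = fingerprint(parse_smiles(final), FingerprintScheme.RDK_PATH)
    eligible = []
    for smi in candidates:
        try:
            fp = fingerprint(parse_smiles(smi), FingerprintScheme.RDK_PATH)
        except InvalidSmilesError:
            continue
        if lo < tanimoto(fp, fp_final) < hi:
            eligible.append(smi)
    if not eligible:
        return None
    return random.Random((seed, final, tuple(candidates)).__str__()).choice(eligible)


def make_turn_input(cumulative_text: str, previous_molecule: Optional[str]) -> str:
    """Model input for a turn: the cumulative description, plus an
    "It looks like <SMILES>." sentence when a previous-round molecule exists."""
    if previous_molecule is None:
        return cumulative_text
    return f"{cumulative_text} It looks like {previous_molecule}."


# ---------------------------------------------------------------------------
# default candidate generator: structural perturbations of the final answer
# ---------------------------------------------------------------------------

_SUBSTITUTIONS = {"C": ["N", "O"], "N": ["C"], "O": ["C"], "F": ["Cl"], "Cl": ["F", "Br"], "Br": ["Cl"]}


def _perturb_once(rdmol: Chem.Mol, rng: random.Random) -> Optional[str]:
    """One random structural edit; canonical SMILES or None if invalid."""
    rw = Chem.RWMol(rdmol)
    n = rw.GetNumAtoms()
    if n == 0:
        return None
    op = rng.choice(["substitute", "add", "delete", "add", "substitute"])
    try:
        if op == "substitute":
            idx = rng.randrange(n)
            atom = rw.GetAtomWithIdx(idx)
            choices = _SUBSTITUTIONS.get(atom.GetSymbol())
            if not choices:
                return None
            atom.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(rng.choice(choices)))
        elif op == "add":
            idx = rng.randrange(n)
            new = rw.AddAtom(Chem.Atom(6))
            rw.AddBond(idx, new, Chem.BondType.SINGLE)
        else:  # delete a terminal heavy atom
            terminals = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
            if not terminals or n < 2:
                return None
            rw.RemoveAtom(rng.choice(terminals))
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def default_candidate_generator(
    cumulative_text: str, final: str, seed: int
) -> list:
    """Five parseable perturbations of ``final``, ordered by descending
    RDK-path similarity to it, none identical to it. Deterministic per seed.

    The cumulative text is accepted for interface compatibility with
    learned generators but is not used by the perturbation strategy.
    """
    mol = parse_smiles(final)
    rng = random.Random((seed, mol.canonical_smiles).__str__())
    fp_final = fingerprint(mol, FingerprintScheme.RDK_PATH)
    found: dict = {}
    for _ in range(60):
        smi = _perturb_once(mol.rdkit_mol(), rng)
        if smi is None or smi == mol.canonical_smiles or smi in found:
            continue
        try:
            fp = fingerprint(parse_smiles(smi), FingerprintScheme.RDK_PATH)
        except InvalidSmilesError:
            continue
        found[smi] = tanimoto(fp, fp_final)
        if len(found) >= 2 * N_CANDIDATES:
            break
    ranked = sorted(found, key=lambda s: (-found[s], s))[:N_CANDIDATES]
    if not ranked:  # pathological single-atom inputs
        ranked = [mol.canonical_smiles]
    base = len(ranked)
    while len(ranked) < N_CANDIDATES:  # duplicate when fewer distinct exist
        ranked.append(ranked[len(ranked) % base])
    return ranked[:N_CANDIDATES]


def jsonl_candidate_generator(path) -> Callable:
    """Candidate generator backed by a JSONL file of external proposals.

    Each line is {"final": <SMILES>, "candidates": [<SMILES>, ...]} —
    e.g. the output of a large text-to-molecule captioning model. Lookup
    is by canonical final SMILES; the default perturbation generator fills
    in for molecules absent from the file.
    """
    import json as _json

    table: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = _json.loads(line)
                table[canonicalize(d["final"])] = list(d["candidates"])[:N_CANDIDATES]

    def generate(cumulative_text: str, final: str, seed: int) -> list:
        stored = table.get(canonicalize(final))
        if stored and len(stored) == N_CANDIDATES:
            return list(stored)
        return default_candidate_generator(cumulative_text, final, seed)

    return generate


# ---------------------------------------------------------------------------
# dialogue assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BuilderConfig:
    """Thresholds for dialogue construction.

    lo/hi: the open similarity gate for intermediate molecules.
    retain_low_sim: probability of keeping a turn whose candidate set has no
    eligible molecule, using the most similar candidate instead.
    """

    lo: float = 0.5
    hi: float = 1.0
    retain_low_sim: float = 0.05

    def __post_init__(self):
        if not 0 <= self.lo < self.hi <= 1:
            raise ValueError("need 0 <= lo < hi <= 1")
        if not 0 <= self.retain_low_sim <= 1:
            raise ValueError("retain_low_sim must be a probability")


@dataclass(frozen=True)
class Rejection:
    """Why a record produced no dialogue."""

    molecule_id: str
    reason: str  # single_turn | hyphen | no_candidate


def build_dialogue(
    record: DescribedMolecule,
    candidate_generator: Callable,
    config: BuilderConfig,
    seed: int,
    synonyms: Iterable[str] = (),
):
    """Build one dialogue from a parallel record, or return a Rejection.

    Pipeline order: synonym masking → sentence split and reverse → "-"
    filter → single-turn filter → per-turn candidate generation and
    similarity-gated selection.
    """
    masked = replace_synonyms(record.description, synonyms)
    sentences = split_and_reverse(masked)
    if any("-" in s for s in sentences):
        return Rejection(record.molecule_id, "hyphen")
    if len(sentences) < 2:
        return Rejection(record.molecule_id, "single_turn")

    final = record.smiles
    rng = random.Random((seed, record.molecule_id).__str__())
    turns = []
    for k in range(1, len(sentences)):
        text_k = " ".join(sentences[:k])
        candidates = candidate_generator(text_k, final, seed + k)
        chosen = select_intermediate(candidates, final, config.lo, config.hi, seed + k)
        if chosen is None:
            if rng.random() < config.retain_low_sim:
                # keep variety: fall back to the most similar candidate
                chosen = _most_similar(candidates, final)
            if chosen is None:
                return Rejection(record.molecule_id, "no_candidate")
        turns.append(Turn(k=k, text=text_k, expected_smiles=chosen))
    turns.append(
        Turn(k=len(sentences), text=" ".join(sentences), expected_smiles=final)
    )
    return Dialogue(
        dialogue_id=f"dia_{record.molecule_id}",
        sentences=tuple(sentences),
        turns=tuple(turns),
        final_smiles=final,
    )


def _most_similar(candidates: list, final: str) -> Optional[str]:
    """Most similar parseable candidate that is not the final answer itself
    (retained low-similarity turns must still never leak the answer)."""
    final_mol = parse_smiles(final)
    fp_final = fingerprint(final_mol, FingerprintScheme.RDK_PATH)
    best, best_sim = None, -1.0
    for smi in candidates:
        try:
            mol = parse_smiles(smi)
        except InvalidSmilesError:
            continue
        if mol.canonical_smiles == final_mol.canonical_smiles:
            continue
        sim = tanimoto(fingerprint(mol, FingerprintScheme.RDK_PATH), fp_final)
        if sim > best_sim:
            best, best_sim = smi, sim
    return best


def build_corpus_dialogues(
    corpus,
    config: BuilderConfig,
    seed: int,
    candidate_generator: Optional[Callable] = None,
):
    """Build dialogues for every corpus record.

    Returns (dialogues, rejections); every record lands in exactly one of
    the two lists. Synonyms for masking are the lexicon names that resolve
    to the record's molecule.
    """
    generator = candidate_generator or default_candidate_generator
    by_smiles: dict = {}
    for name, smi in corpus.lexicon.items():
        by_smiles.setdefault(canonicalize(smi), []).append(name)
    dialogues, rejections = [], []
    for record in corpus.records:
        synonyms = by_smiles.get(canonicalize(record.smiles), [])
        result = build_dialogue(record, generator, config, seed, synonyms=synonyms)
        (dialogues if isinstance(result, Dialogue) else rejections).append(result)
    return dialogues, rejections


def split_dialogues(
    dialogues: list, proportions=(0.7, 0.15, 0.15)
) -> dict:
    """Deterministic train/validation/test split by molecule-id hash."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    edges = (proportions[0], proportions[0] + proportions[1])
    out = {"train": [], "validation": [], "test": []}
    for d in dialogues:
        h = int(hashlib.sha1(d.dialogue_id.encode()).hexdigest(), 16) % 10**6 / 10**6
        split = "train" if h < edges[0] else "validation" if h < edges[1] else "test"
        out[split].append(d)
    return out
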