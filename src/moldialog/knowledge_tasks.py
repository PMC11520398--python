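"""Knowledge-injection pretraining tasks.

Six task families, each emitted as (task, source, target) records whose
source begins with a task prefix so one multi-task model can be trained on
the mixture:

* ``mlm_text`` / ``mlm_smiles`` — span-corruption masked language modeling
  on descriptions and on SMILES (atom-level tokens);
* ``map_text2mol`` / ``map_mol2name`` — molecule mapping correlation:
  translate names found in text to SMILES, and SMILES back to names;
* ``property`` — generate an experimental-property sentence for a molecule;
* ``spatial`` — answer atom-level structure queries (neighbors,
  aromaticity, ring membership) computed from the molecular graph.

Every property and spatial target is mechanically verifiable; the fact
checker in this module re-derives the claims from the molecule.
"""

from __future__ import annotations

import random
import re
from typing import List, Optional, Tuple

from .chem_core import Molecule, atom_environment, parse_smiles
from .plugin_prompting import annotate
from .records import KnowledgeRecord
from .tokenization import SENTINELS, sentinel, tokenize_smiles, tokenize_words

__all__ = [
    "TASK_PREFIXES",
    "mask_spans",
    "reconstruct_spans",
    "make_mlm_record",
    "make_mapping_records",
    "make_property_records",
    "make_spatial_records",
    "build_knowledge_corpus",
    "verify_spatial_record",
    "verify_property_record",
]

TASK_PREFIXES = {
    "mlm_text": "[MLM text]",
    "mlm_smiles": "[MLM smiles]",
    "map_text2mol": "[text2mol]",
    "map_mol2name": "[mol2name]",
    "property": "[property]",
    "spatial": "[spatial]",
}

DEFAULT_MASK_RATE = 0.15
MEAN_SPAN_LENGTH = 3

DEFAULT_MIXTURE = {
    "mlm_text": 0.25,
    "mlm_smiles": 0.25,
    "map_text2mol": 0.125,
    "map_mol2name": 0.125,
    "property": 0.125,
    "spatial": 0.125,
}


# ---------------------------------------------------------------------------
# span-corruption MLM
# ---------------------------------------------------------------------------


def mask_spans(
    sequence: List[str], mask_rate: float, seed: int
) -> Tuple[List[str], List[str]]:
    """Corrupt ``sequence`` by replacing contiguous spans with sentinels.

    The number of masked tokens is round(mask_rate·len) (clamped to
    [1, len-1]); spans have mean length ~3 and are never adjacent, so each
    sentinel marks one unambiguous gap. The target lists each sentinel
    followed by the tokens it hides, terminated by one extra sentinel, which
    makes the corruption lossless (see :func:`reconstruct_spans`).
    """
    if not 0 < mask_rate < 1:
        raise ValueError("mask_rate must be in (0, 1)")
    n = len(sequence)
    if n < 2:
        raise ValueError("sequence must have at least 2 tokens")
    rng = random.Random((seed, n).__str__())
    m = max(1, min(round(mask_rate * n), n - 1))

    # split the masked budget into span lengths (mean ≈ 3), capped so the
    # number of spans never exceeds the sentinel inventory
    lengths: List[int] = []
    remaining = m
    while remaining > 0:
        if len(lengths) >= len(SENTINELS) - 2:
            lengths[-1] += remaining
            remaining = 0
            break
        length = min(remaining, rng.choice([1, 2, 3, 3, 4, 5]))
        lengths.append(length)
        remaining -= length

    masked = [False] * n
    placed: List[Tuple[int, int]] = []
    for length in sorted(lengths, reverse=True):
        starts = list(range(n - length + 1))
        rng.shuffle(starts)
        done = False
        for start in starts:
            lo, hi = max(0, start - 1), min(n, start + length + 1)
            if not any(masked[lo:hi]):
                for i in range(start, start + length):
                    masked[i] = True
                placed.append((start, length))
                done = True
                break
        if not done:
            # fragmented sequence: fall back to single free tokens
            free = [i for i in range(n) if not any(masked[max(0, i - 1) : i + 2])]
            rng.shuffle(free)
            for i in free[:length]:
                masked[i] = True
                placed.append((i, 1))

    placed.sort()
    corrupted: List[str] = []
    targets: List[str] = []
    span_idx = 0
    i = 0
    while i < n:
        if span_idx < len(placed) and placed[span_idx][0] == i:
            start, length = placed[span_idx]
            corrupted.append(sentinel(span_idx))
            targets.append(sentinel(span_idx))
            targets.extend(sequence[start : start + length])
            i = start + length
            span_idx += 1
        else:
            corrupted.append(sequence[i])
            i += 1
    targets.append(sentinel(span_idx))
    return corrupted, targets


def reconstruct_spans(corrupted: List[str], targets: List[str]) -> List[str]:
    """Invert :func:`mask_spans`: splice the target spans back into the
    corrupted sequence."""
    spans: dict = {}
    current: Optional[str] = None
    for tok in targets:
        if tok in SENTINELS:
            current = tok
            spans[current] = []
        elif current is not None:
            spans[current].append(tok)
    out: List[str] = []
    for tok in corrupted:
        if tok in spans:
            out.extend(spans[tok])
        else:
            out.append(tok)
    return out


def make_mlm_record(
    text: str, kind: str, mask_rate: float = DEFAULT_MASK_RATE, seed: int = 0
) -> KnowledgeRecord:
    """One span-corruption record for a description (kind="mlm_text") or a
    SMILES string (kind="mlm_smiles")."""
    if kind not in ("mlm_text", "mlm_smiles"):
        raise ValueError(kind)
    tokens = tokenize_smiles(text) if kind == "mlm_smiles" else tokenize_words(text)
    corrupted, targets = mask_spans(tokens, mask_rate, seed)
    return KnowledgeRecord(
        task=kind,
        source=f"{TASK_PREFIXES[kind]} " + " ".join(corrupted),
        target=" ".join(targets),
    )


# ---------------------------------------------------------------------------
# molecule mapping correlation
# ---------------------------------------------------------------------------


def make_mapping_records(text: str, lexicon: dict) -> List[KnowledgeRecord]:
    """Mapping-correlation records for one text segment.

    Detected entities (longest-match, textual order) yield one
    ``map_text2mol`` record whose target lists all matched SMILES in order
    of appearance, plus one ``map_mol2name`` record per distinct matched
    molecule. No matches → no records.
    """
    matches = annotate(text, lexicon)
    if not matches:
        return []
    records = [
        KnowledgeRecord(
            task="map_text2mol",
            source=f"{TASK_PREFIXES['map_text2mol']} {text}",
            target=" ".join(smiles for _n, smiles, _sp in matches),
        )
    ]
    seen = set()
    for name, smiles, _span in matches:
        if (name, smiles) in seen:
            continue
        seen.add((name, smiles))
        records.append(
            KnowledgeRecord(
                task="map_mol2name",
                source=f"{TASK_PREFIXES['map_mol2name']} {smiles}",
                target=name,
            )
        )
    return records


# ---------------------------------------------------------------------------
# experimental property knowledge
# ---------------------------------------------------------------------------

_VERB_VALUES = ("melts", "boils")


def _property_sentence(value: str) -> str:
    first = value.split()[0]
    if first in _VERB_VALUES:
        return f"The molecule {value}."
    return f"The molecule is {value}."


def make_property_records(
    molecule_id: str, smiles: str, property_table: dict
) -> List[KnowledgeRecord]:
    """One record per experimental property row of ``molecule_id``.

    Source asks for one property of the SMILES; target is a natural-language
    sentence built from the tabulated value text.
    """
    if molecule_id not in property_table:
        raise KeyError(f"unknown molecule id {molecule_id!r}")
    records = []
    for prop, value in sorted(property_table[molecule_id].items()):
        records.append(
            KnowledgeRecord(
                task="property",
                source=f"{TASK_PREFIXES['property']} What is the {prop} of {smiles}?",
                target=_property_sentence(value),
            )
        )
    return records


def verify_property_record(
    record: KnowledgeRecord, property_table: dict, smiles_to_id: Optional[dict] = None
) -> bool:
    """Check a property target against the table it was built from.

    With ``smiles_to_id`` (canonical SMILES → molecule id) the check is
    exact: the queried molecule's own tabulated value must render to the
    target sentence. Without it, any molecule carrying that (property,
    value) pair is accepted.
    """
    m = re.fullmatch(
        re.escape(TASK_PREFIXES["property"]) + r" What is the (.+) of (.+)\?",
        record.source,
    )
    if not m:
        return False
    prop, smiles = m.group(1), m.group(2)
    canon = parse_smiles(smiles).canonical_smiles
    if smiles_to_id is not None:
        props = property_table.get(smiles_to_id.get(canon, ""), {})
        return prop in props and record.target == _property_sentence(props[prop])
    return any(
        prop in props and record.target == _property_sentence(props[prop])
        for props in property_table.values()
    )


# ---------------------------------------------------------------------------
# spatial structure knowledge
# ---------------------------------------------------------------------------

_QUERY_KINDS = ("neighbors", "aromaticity", "ring")


def _neighbor_phrase(neighbors) -> str:
    if not neighbors:
        return "no other atoms"
    parts = [f"atom {j} ({el})" for j, el in neighbors]
    if len(parts) == 1:
        return parts[0]
    return ", ".join(parts[:-1]) + " and " + parts[-1]


def _spatial_target(mol: Molecule, atom_index: int, kind: str) -> str:
    neighbors, aromatic, ring_sizes = atom_environment(mol, atom_index)
    if kind == "neighbors":
        return f"Atom {atom_index} is connected to {_neighbor_phrase(neighbors)}."
    if kind == "aromaticity":
        if aromatic:
            return (
                f"Atom {atom_index} is aromatic and is part of a ring of "
                f"{ring_sizes[0]} atoms."
            )
        return f"Atom {atom_index} is not aromatic."
    if ring_sizes:
        sizes = " and ".join(str(s) for s in ring_sizes)
        return f"Atom {atom_index} is part of a ring of {sizes} atoms."
    return f"Atom {atom_index} is not part of any ring."


_QUERY_TEXT = {
    "neighbors": "Which atoms are connected to atom {i} in {smiles}?",
    "aromaticity": "Is atom {i} of {smiles} aromatic?",
    "ring": "Is atom {i} of {smiles} part of a ring?",
}


def make_spatial_records(
    mol: Molecule, n_queries: int, seed: int
) -> List[KnowledgeRecord]:
    """Atom-level structure queries with templated true answers.

    Each record picks one atom and one query kind (neighbors, aromaticity,
    ring membership); the target is derived from the molecular graph.
    """
    if n_queries < 1:
        raise ValueError("n_queries must be >= 1")
    rng = random.Random((seed, mol.canonical_smiles).__str__())
    records = []
    for _ in range(n_queries):
        atom_index = rng.randrange(mol.n_atoms)
        kind = rng.choice(_QUERY_KINDS)
        source = TASK_PREFIXES["spatial"] + " " + _QUERY_TEXT[kind].format(
            i=atom_index, smiles=mol.canonical_smiles
        )
        records.append(
            KnowledgeRecord(
                task="spatial",
                source=source,
                target=_spatial_target(mol, atom_index, kind),
            )
        )
    return records


_SPATIAL_SOURCE_RE = re.compile(
    r"\[spatial\] (?:Which atoms are connected to atom (?P<i1>\d+) in (?P<s1>\S+)\?"
    r"|Is atom (?P<i2>\d+) of (?P<s2>\S+) aromatic\?"
    r"|Is atom (?P<i3>\d+) of (?P<s3>\S+) part of a ring\?)"
)


def verify_spatial_record(record: KnowledgeRecord) -> bool:
    """Re-derive a spatial target from its source query and check the claims.

    Claims in the target (neighbor list, aromaticity, ring sizes) are parsed
    out and compared against :func:`moldialog.chem_core.atom_environment`.
    """
    m = _SPATIAL_SOURCE_RE.fullmatch(record.source)
    if not m:
        return False
    g = m.groupdict()
    if g["i1"] is not None:
        atom_index, smiles, kind = int(g["i1"]), g["s1"], "neighbors"
    elif g["i2"] is not None:
        atom_index, smiles, kind = int(g["i2"]), g["s2"], "aromaticity"
    else:
        atom_index, smiles, kind = int(g["i3"]), g["s3"], "ring"
    mol = parse_smiles(smiles)
    neighbors, aromatic, ring_sizes = atom_environment(mol, atom_index)

    if kind == "neighbors":
        claimed = [
            (int(j), el)
            for j, el in re.findall(r"atom (\d+) \((\w+)\)", record.target)
        ]
        if "no other atoms" in record.target:
            return neighbors == [] and claimed == []
        return claimed == neighbors
    if kind == "aromaticity":
        if "is not aromatic" in record.target:
            return not aromatic
        ring_claim = re.search(r"ring of (\d+) atoms", record.target)
        return bool(
            aromatic and ring_claim and int(ring_claim.group(1)) in ring_sizes
        )
    if "not part of any ring" in record.target:
        return ring_sizes == []
    claimed_sizes = [int(x) for x in re.findall(r"\d+", record.target.split("ring of")[-1])]
    return claimed_sizes == ring_sizes


# ---------------------------------------------------------------------------
# corpus-level mixing
# ---------------------------------------------------------------------------


def build_knowledge_corpus(
    corpus,
    n_records: int,
    seed: int,
    mixture: Optional[dict] = None,
    mask_rate: float = DEFAULT_MASK_RATE,
) -> List[KnowledgeRecord]:
    """Emit a mixed stream of all six task types.

    Per-task counts follow ``mixture`` weights (largest-remainder rounding,
    so each count is within ±1 of its exact share). Mapping records are
    built from synthetic literature snippets over the corpus lexicon.
    """
    from .synthetic_data import gen_snippets  # avoids import at module load

    mixture = dict(DEFAULT_MIXTURE if mixture is None else mixture)
    total_w = sum(mixture.values())
    quotas = {t: int(n_records * w / total_w) for t, w in mixture.items()}
    remainders = sorted(
        mixture,
        key=lambda t: (n_records * mixture[t] / total_w) - quotas[t],
        reverse=True,
    )
    for t in remainders[: n_records - sum(quotas.values())]:
        quotas[t] += 1

    rng = random.Random(seed)
    records: List[KnowledgeRecord] = []
    mols = {r.molecule_id: parse_smiles(r.smiles) for r in corpus.records}
    ids = sorted(mols)

    maskable = [
        r for r in corpus.records if len(tokenize_smiles(r.smiles)) >= 2
    ]  # single-token SMILES cannot be span-corrupted
    for i in range(quotas.get("mlm_text", 0)):
        rec = corpus.records[rng.randrange(len(corpus.records))]
        records.append(make_mlm_record(rec.description, "mlm_text", mask_rate, seed + i))
    for i in range(quotas.get("mlm_smiles", 0)):
        rec = maskable[rng.randrange(len(maskable))]
        records.append(
            make_mlm_record(rec.smiles, "mlm_smiles", mask_rate, seed + 10_000 + i)
        )

    want_t2m = quotas.get("map_text2mol", 0)
    want_m2n = quotas.get("map_mol2name", 0)
    t2m: List[KnowledgeRecord] = []
    m2n: List[KnowledgeRecord] = []
    snippet_seed = seed + 20_000
    while len(t2m) < want_t2m or len(m2n) < want_m2n:
        for text in gen_snippets(corpus.lexicon, 16, snippet_seed):
            for r in make_mapping_records(text, corpus.lexicon):
                (t2m if r.task == "map_text2mol" else m2n).append(r)
        snippet_seed += 1
    records.extend(t2m[:want_t2m])
    records.extend(m2n[:want_m2n])

    prop_pool: List[KnowledgeRecord] = []
    for rec in corpus.records:
        if rec.molecule_id in corpus.property_table:
            prop_pool.extend(
                make_property_records(
                    rec.molecule_id, rec.smiles, corpus.property_table
                )
            )
    rng.shuffle(prop_pool)
    want_prop = quotas.get("property", 0)
    while len(prop_pool) < want_prop:  # small corpora: sample with repetition
        prop_pool.extend(prop_pool[: want_prop - len(prop_pool)])
    records.extend(prop_pool[:want_prop])

    for i in range(quotas.get("spatial", 0)):
        mol = mols[ids[rng.randrange(len(ids))]]
        records.extend(make_spatial_records(mol, 1, seed + 30_000 + i))

    return records
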