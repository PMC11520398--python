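"""Shared record types and JSONL/TSV serialization.

All pipeline artifacts are plain text: corpora and dialogues as JSONL
(one record per line), lexicons and property tables as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class DescribedMolecule:
    """One parallel record: a molecule and its natural-language description."""

    molecule_id: str
    smiles: str
    description: str
    augmented: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "DescribedMolecule":
        return cls(**json.loads(line))


@dataclass(frozen=True)
class KnowledgeRecord:
    """One pretraining example: task tag plus source/target sequences."""

    task: str
    source: str
    target: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "KnowledgeRecord":
        return cls(**json.loads(line))


@dataclass(frozen=True)
class Turn:
    """One dialogue turn: cumulative text and its expected molecule."""

    k: int
    text: str
    expected_smiles: str


@dataclass(frozen=True)
class Dialogue:
    """A multi-turn molecule-design conversation.

    ``sentences`` are the description sentences in reversed order (detail
    increases turn by turn); turn k's text is the concatenation of the
    first k sentences; the final turn's expected molecule is the source
    molecule.
    """

    dialogue_id: str
    sentences: tuple
    turns: tuple  # of Turn
    final_smiles: str

    @property
    def n_turns(self) -> int:
        return len(self.turns)

    def to_json(self) -> str:
        return json.dumps(
            {
                "dialogue_id": self.dialogue_id,
                "sentences": list(self.sentences),
                "turns": [asdict(t) for t in self.turns],
                "final_smiles": self.final_smiles,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "Dialogue":
        d = json.loads(line)
        return cls(
            dialogue_id=d["dialogue_id"],
            sentences=tuple(d["sentences"]),
            turns=tuple(Turn(**t) for t in d["turns"]),
            final_smiles=d["final_smiles"],
        )


@dataclass(frozen=True)
class PromptedInput:
    """Model input text with entity-SMILES hints attached."""

    item_id: str
    text: str
    annotations: tuple  # of (name, smiles, (start, end))
    prompt: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "item_id": self.item_id,
                "text": self.text,
                "annotations": [
                    {"name": n, "smiles": s, "span": list(sp)}
                    for n, s, sp in self.annotations
                ],
                "prompt": self.prompt,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "PromptedInput":
        d = json.loads(line)
        return cls(
            item_id=d["item_id"],
            text=d["text"],
            annotations=tuple(
                (a["name"], a["smiles"], tuple(a["span"])) for a in d["annotations"]
            ),
            prompt=d["prompt"],
        )


def write_jsonl(path: str | Path, items: Iterable) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for item in items:
            fh.write(item.to_json() + "\n")


def read_jsonl(path: str | Path, cls) -> list:
    with open(path) as fh:
        return [cls.from_json(line) for line in fh if line.strip()]


def write_tsv(path: str | Path, rows: Iterable[tuple], header: tuple) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path) -> Iterator[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if line.strip():
                yield dict(zip(header, line.rstrip("\n").split("\t")))


def read_lexicon(path: str | Path) -> dict:
    """Read a name→SMILES lexicon TSV (columns: name, smiles)."""
    return {row["name"]: row["smiles"] for row in read_tsv(path)}


def write_lexicon(path: str | Path, lexicon: dict) -> None:
    write_tsv(path, sorted(lexicon.items()), header=("name", "smiles"))


def read_property_table(path: str | Path) -> dict:
    """Read a property TSV (molecule_id, property, value) into a nested map."""
    table: dict = {}
    for row in read_tsv(path):
        table.setdefault(row["molecule_id"], {})[row["property"]] = row["value"]
    return table


def write_property_table(path: str | Path, table: dict) -> None:
    rows = [
        (mid, prop, value)
        for mid in sorted(table)
        for prop, value in sorted(table[mid].items())
    ]
    write_tsv(path, rows, header=("molecule_id", "property", "value"))
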