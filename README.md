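# moldialog

A desk-scale toolkit for **conversational molecular design**: describing a
target molecule in natural language over several turns of dialogue and
asking a model to either *generate* a matching molecule (SMILES) or
*understand* a given molecule by writing a property description.

It is aimed at researchers who want to study the data construction,
training signals and evaluation of this task without GPU-scale
pretraining or external downloads. The package provides:

- a **synthetic corpus generator** producing molecule–description pairs
  with known ground truth (every sentence is mechanically verifiable
  against the molecular graph), plus a name lexicon and an
  experimental-property table;
- a **dialogue builder** that turns each description into a multi-turn
  conversation: sentences are split and reversed so detail accumulates,
  and each intermediate turn gets an expected molecule whose RDK-path
  Tanimoto similarity *s* to the final answer Mₙ satisfies
  0.5 < s(Mₖ, Mₙ) < 1 — on track, but never the answer (items with a
  single turn, or with "-" in a sentence, are filtered out);
- **knowledge-injection pretraining tasks**: span-corruption MLM on text
  and SMILES, name↔SMILES mapping correlation, experimental-property
  generation, and atom-level spatial-structure queries, all tagged with
  task prefixes;
- **plugin prompting**: entity SMILES hints appended to inputs, with any
  hint canonical-equal to an answer molecule removed;
- a **twin encoder–decoder seq2seq** (independent stacks for chemical and
  natural language, numpy implementation with its own autodiff) supporting
  multi-task pretraining, dialogue fine-tuning, dual augmentation and
  top-3 beam-search generation;
- the full **metric suite**: BLEU-2/4, ROUGE-1/2/L, METEOR for
  understanding; exact match (EM), hit@3, SMILES BLEU, Levenshtein
  distance, and fingerprint Tanimoto similarity (RDK / MACCS / Morgan,
  FTS = |A∩B|/|A∪B| on fingerprint bit sets) for generation.

## Worked example

Build a corpus, dialogues, and knowledge records from the command line:

```text
$ moldialog synth --n 12 --seed 7 --out corpus
wrote 12 records to corpus
$ moldialog dialogues --corpus corpus --seed 7 --out dia
built 11 dialogues, rejected 1
$ moldialog knowledge --corpus corpus --n 60 --seed 7 --out knowledge.jsonl
wrote 60 knowledge records to knowledge.jsonl
```

The first dialogue in `dia/dialogues.jsonl` reads:

```text
turn 1: The molecule is an aromatic compound.
  expected: CC(CO)CCC(C)Cc1ccccc1Br
turn 2: The molecule is an aromatic compound. The molecule contains a ring of six atoms.
  expected: CC(CO)CC(C)CCc1ccccc1Br
turn 3: ... The molecule has 15 heavy atoms.
  expected: CC(CO)CCCCc1ccccc1Br   (= the source molecule)
```

Detail accumulates turn by turn; the expected molecule of turn 1 has
RDK-path Tanimoto similarity 0.866 to the final answer — inside the
(0.5, 1.0) gate, so it is plausibly on track but not the answer itself.
For the one rejected record, none of the five generated candidates fell
inside the gate (reason `no_candidate` in `dia/rejections.tsv`).

Scoring ranked generation predictions against gold molecules:

```python
from moldialog.metrics import GenerationPrediction, evaluate

preds = [
    GenerationPrediction("d1", ("OCC", "CCN", "CC"), "CCO"),
    GenerationPrediction("d2", ("CCC", "CCCC", "CC"), "CCCC"),
    GenerationPrediction("d3", ("c1ccncc1", "CCO", "C"), "c1ccccc1"),
]
print(evaluate(preds, "generation").aggregate)
```

```text
{'EM': 0.333, 'hit@3': 0.667, 'BL': 0.615, 'Leven': 1.333,
 'RDK': 0.632, 'MAC': 0.625, 'Morgan': 0.611}
```

`d1` counts as an exact match: "OCC" and "CCO" are the same molecule
after canonicalization. `d2` misses at rank 1 but hits within the top 3,
so EM = 1/3 while hit@3 = 2/3. `d3` (pyridine for benzene) matches
nowhere, but its fingerprint similarities are high — the FTS columns
credit near-misses that share substructures, which exact match cannot.

Training runs the same way through the CLI (`moldialog train --stage
pretrain|finetune-gen|finetune-und`), or programmatically via
`moldialog.model`; `moldialog.experiments` bundles the reference
memorization and ablation experiments.

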