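# Methods

`moldialog` is a desk-scale toolkit for *conversational molecular design*:
the task of describing a target molecule in natural language over several
turns of dialogue, and asking a model either to **generate** a molecule
(SMILES) satisfying the accumulated requirements, or to **understand** a
molecule by producing a natural-language property description. This note
documents the models and procedures the package implements, the choices
made where the design was open, and what the synthetic-data experiments do
and do not show.

## Dialogue construction

The conversational dataset is derived from a parallel corpus of
⟨molecule M, description T⟩ pairs. For each pair:

1. **Synonym masking.** Names of the target molecule in T are replaced by
   the neutral phrase "the molecule" (case-insensitive whole-word matching,
   longest synonym first), so the text cannot name the answer.
2. **Split and reverse.** T is segmented into sentences S₁…Sₙ with a
   rule-based splitter (terminal punctuation with an abbreviation guard
   list) and the order reversed. Curated descriptions run from fine
   structural detail to general properties, so reversal makes detail
   *increase* turn by turn; the k-th turn's cumulative text is
   Tₖ = S₁ … Sₖ.
3. **Filters.** Items whose sentences contain the character "-" are
   rejected (a cheap proxy for systematic nomenclature, which would spell
   out the answer), as are items with a single sentence (one-turn
   "dialogues" are not conversations). Rejection reasons
   (`hyphen`, `single_turn`, `no_candidate`) are logged and partition the
   rejected records.
4. **Intermediate molecules.** For each non-final turn, a candidate
   generator proposes five molecules for Tₖ; one is picked uniformly at
   random among those whose RDK-path-fingerprint Tanimoto similarity to
   the final answer Mₙ lies strictly inside (0.5, 1.0) — similar enough to
   be "on track", but never the answer itself (similarity 1 is excluded to
   avoid information leakage). If no candidate qualifies, the item is
   rejected, except that with probability `retain_low_sim` (default 0.05)
   the most similar candidate is kept anyway, preserving some
   low-similarity variety in the data. The upper bound still applies to
   retained items: the fallback picks the most similar *eligible-or-not*
   candidate, which by construction is never the final molecule.
5. **Turn inputs.** From the second turn on, the model input appends
   "It looks like ⟨previous SMILES⟩." so generation can condition on the
   previous round's result.

The candidate generator is a pluggable interface. Production pipelines
would use a large text-to-molecule model; the default here perturbs the
final answer structurally (atom substitution, terminal-atom addition and
deletion), ranks perturbations by descending similarity, and pads by
duplication when fewer than five distinct valid structures exist. This
keeps the construction algorithm intact at desk scale; an external
generator's candidates can be substituted without touching the builder.

Train/validation/test splitting is by a hash of the dialogue id, so splits
are stable under corpus growth.

## Knowledge-injection pretraining tasks

Six task families are emitted as (task, source, target) records, the
source prefixed with a task token (e.g. `[spatial]`) so one multi-task
model can consume the mixture:

- **Span-corruption MLM** on descriptions (`mlm_text`) and on SMILES
  (`mlm_smiles`). Contiguous spans (mean length ≈ 3) are replaced by
  sentinel tokens; the target lists each sentinel with the hidden tokens,
  plus a terminating sentinel, making the corruption lossless. The mask
  rate defaults to 0.15 of tokens (within ±1 token of the exact share);
  spans are never adjacent. SMILES are tokenized at the atom level
  (bracket atoms, two-letter elements, ring digits) so masking never
  splits an atom symbol.
- **Molecule mapping correlation**: chemical names detected in text by
  longest-match lexicon lookup yield a text→SMILES record (all matched
  molecules, in order of appearance) and one SMILES→name record per
  matched molecule. The detector is a pluggable exact-match scan; a
  learned NER could be substituted behind the same interface.
- **Experimental properties**: one record per tabulated property row,
  asking for a named property of a SMILES and answering with a sentence
  built from the stored value text. The property inventory has 15 types
  (solubility, color, corrosivity, odor, physical state, melting and
  boiling behavior, density, flammability, toxicity, stability, viscosity,
  vapor pressure, reactivity, acidity).
- **Spatial structure**: atom-level queries (connected atoms, aromaticity,
  ring membership) answered from the molecular graph via RDKit.

Per-task record counts follow configurable mixture weights with
largest-remainder rounding (each count within ±1 of its exact share). All
spatial and property targets are mechanically verifiable; the package
ships the fact checker that re-derives each claim.

## Plugin prompting

At fine-tuning and inference time, names found in the input text are
annotated with their SMILES from the lexicon and appended as a hint block
("Known molecules: name: SMILES; …"). Any hint whose molecule is
**canonical-equal** to an answer molecule of the dialogue is removed
first. Structural rather than string equality is used deliberately: a
rewriting of the same molecule is still a leak, and string equality would
miss it.

## The twin seq2seq

Two fully independent transformer encoder–decoder stacks (nothing shared,
not even embeddings) process the two languages: the *molecule* route
decodes SMILES (span-corrupted SMILES reconstruction, text→molecule
mapping, dialogue generation), the *text* route decodes natural language
(description MLM, molecule→name mapping, property and spatial answers,
captioning). A training example is routed by the modality of its target.

Defaults: 2 encoder + 2 decoder layers per route, hidden size 128, 4
heads, feed-forward 256, learned positional embeddings, max length 96,
pre-layer-norm residual blocks. The network and its reverse-mode
autodiff are implemented directly on numpy; gradients are verified
against central finite differences in the test suite, and all training is
bit-reproducible given (seed, config, data).

Training uses Adam (default peak learning rate 2·10⁻³) with teacher
forcing; within each batch, per-task example counts follow the empirical
task mix with largest-remainder rounding (±1 example). The learning rate
decays linearly to 10% of its peak over a run — without decay, small
memorization runs orbit the optimum and decoding drifts (we observed
runaway `cccc…` repetitions on aromatic rings at constant rate). Dialogue
fine-tuning conditions each turn on the *reference* previous molecule
(teacher forcing); at inference the model's own previous rank-1 output can
be used instead. Top-3 generation uses beam search (width ≥ 4) with final
ranking by mean token log-probability; raw-sum ranking favors truncated
prefixes. Word-level text vocabularies (with a character-piece fallback
for unseen words) and atom-level SMILES vocabularies are fitted on the
training corpus; multi-molecule targets are joined by an explicit
separator token so they round-trip exactly.

**Dual augmentation.** The fine-tuned understanding route generates one
description per molecule; the pairs are flagged `augmented` and can be
merged into generation fine-tuning but are excluded from evaluation sets.

## Evaluation metrics

Understanding: BLEU-2/4, ROUGE-1/2/L (F1), METEOR on lowercased word
tokens. Generation: exact match and hit@3 on **canonical** SMILES (an
unparseable prediction is a non-match), character-level SMILES BLEU
(4-grams), Levenshtein distance on the raw strings (via edlib, checked
against an independent dynamic program), and Tanimoto similarity under
three fingerprint schemes — RDK path (max path 7, 2048 bits), MACCS (166
keys), Morgan (radius 2, 2048 bits). Similarity metrics score the rank-1
prediction: this matches the asymmetry of exact match and is the
conservative choice. An unparseable prediction scores 0 on fingerprint
similarity but still receives a string Levenshtein distance.

Numerical conventions:

- BLEU caps the n-gram order at the shorter sequence length (a perfect
  one-token prediction scores 1); zero higher-order precisions are
  floor-smoothed at 1/(2·count); a zero unigram precision scores 0.
- METEOR uses exact unigram matching (no external synonym source), recall
  weighted 9:1, and a fragmentation penalty of
  0.5·((chunks−1)/(matches−1))³. This variant of the usual
  (chunks/matches)³ penalty assigns exactly zero penalty to a perfectly
  ordered full alignment, so identical sentences score exactly 1 — a
  property the evaluation-sanity checks rely on; the classical penalty
  leaves identical sentences a hair below 1.
- Tanimoto of two empty fingerprints is defined as 0.0 (with a warning)
  rather than 0/0; single heavy atoms produce empty path fingerprints.

## Synthetic data: what it is and is not

The generator emulates curated chemistry-database records: molecules from
a closed grammar (carbon chains of 1–8 atoms with optional methyl/ethyl
branch, a hydroxyl/amino/carboxyl group or none, an optional benzene,
cyclopropane or cyclohexane ring, an optional halogen; ring probability
0.4, halogen 0.25, branch 0.35), descriptions of 2–6 sentences drawn from
an enumerated template table ordered fine-structure-first, a pseudo-name
lexicon, literature-style snippets mentioning those names, and a property
table with 3–15 rows per molecule. Every sentence template carries a
verification predicate, so the "no un-derivable facts" property is
mechanically checkable; a description may also claim structural
relatedness to another corpus molecule, which the checker verifies as
RDK-path Tanimoto ≥ 0.4. Pseudo-names never appear in their own
molecule's description, so synonym masking and leakage filters are
exercised non-vacuously.

What passing tests show: the construction algorithm, filters, similarity
gate, leakage removal, fact-grounded task generation, training loop and
metric suite behave exactly as specified on data with known ground truth.
What they do not show: linguistic robustness on real ChEBI-20/PCdes prose
(hyphenated nomenclature, abbreviations, hedged or erroneous curator
statements), chemistry beyond the small-molecule grammar (stereochemistry,
charged species, macromolecules), or any generalization claim for the toy
model.

## Reference experiment sizes

The memorization probes train on 20 dialogues (≈75 turn examples, 1100
steps, batch 16) and 20 molecule–description pairs (450 steps); both
finish in minutes on one CPU and are expected to reach ≥ 0.9 final-turn
exact match and ≥ 18/20 verbatim descriptions. The ablation comparison
(MLM-only vs MLM + mapping pretraining, 5 seeds, tiny 1-layer config)
checks only the weak order — adding mapping pretraining must not lower
mean held-out exact match. At this scale both conditions typically score
zero on held-out dialogues, so the check is a direction guard, not a
measurement of the gap; demonstrating the gap requires full-scale training
on real corpora, which is outside this package's scope.

## Known limitations

- The rule-based sentence splitter assumes clean terminal punctuation;
  the synthetic corpus guarantees it, real text does not.
- The default candidate generator perturbs the final answer, so candidate
  quality does not depend on the dialogue text; it exercises the
  selection gate, not text-conditioned generation.
- Whether the "-" filter should drop the whole item or single sentences
  is ambiguous in the construction recipe; the builder drops the item,
  which is the stricter reading.
- The similarity gate and the retained-low-similarity fraction (0.05) are
  configuration, not fitted quantities; the gate bounds (0.5, 1.0) follow
  the construction recipe, the fraction is a package default.
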