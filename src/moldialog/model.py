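"""Twin encoder–decoder seq2seq for conversational molecular design.

Two independent transformer encoder–decoder stacks share nothing: one
decodes chemical language (the *molecule* route — targets are SMILES), the
other natural language (the *text* route — targets are descriptions,
names, property and structure answers). A training example is routed by
the modality of its target. Task prefixes in the source string let one
stack serve several pretraining tasks at once.

The stacks are deliberately tiny (default 2+2 layers, 128 hidden): the
module's purpose is to exercise the full training loop — multi-task
pretraining on knowledge records, dual augmentation, dialogue fine-tuning
with teacher forcing, and beam-search top-3 generation — at a scale where
memorization experiments run on one CPU in minutes.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .dialogue_builder import make_turn_input
from .records import DescribedMolecule, Dialogue, KnowledgeRecord
from .tokenization import (
    BOS,
    EOS,
    PAD,
    SEP,
    SENTINELS,
    Vocab,
    detokenize,
    tokenize_mixed,
    tokenize_smiles,
    tokenize_words,
)

__all__ = [
    "ModelConfig",
    "TrainState",
    "Seq2Seq",
    "TwinSeq2Seq",
    "Trainer",
    "pretrain",
    "finetune_generation",
    "finetune_understanding",
    "dual_augment",
    "generate_molecules",
    "generate_description",
    "predict_dialogue",
]

PREFIX_GENERATE = "[generate]"
PREFIX_DESCRIBE = "[describe]"

MOLECULE_ROUTE_TASKS = {"mlm_smiles", "map_text2mol", "generate"}


def route_of(task: str) -> str:
    return "molecule" if task in MOLECULE_ROUTE_TASKS else "text"


@dataclass
class ModelConfig:
    """Twin seq2seq hyperparameters; vocab sizes are filled at build time."""

    layers: int = 2
    hidden: int = 128
    heads: int = 4
    ffn: int = 256
    max_len: int = 96
    seed: int = 0
    lr: float = 3e-3
    text_vocab_size: int = 0
    smiles_vocab_size: int = 0

    def __post_init__(self):
        if min(self.layers, self.hidden, self.heads, self.ffn, self.max_len) <= 0:
            raise ValueError("all size fields must be positive")
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")


# ---------------------------------------------------------------------------
# target tokenization per route
# ---------------------------------------------------------------------------

_SENTINEL_RE = re.compile(r"<extra_id_\d+>")


def tokenize_molecule_target(target: str) -> List[str]:
    """Whitespace-separated SMILES (or sentinels) → atom tokens with <sep>
    between the chunks, so multi-molecule targets round-trip."""
    tokens: List[str] = []
    for i, chunk in enumerate(target.split()):
        if i:
            tokens.append(SEP)
        if _SENTINEL_RE.fullmatch(chunk) or chunk in SENTINELS:
            tokens.append(chunk)
        else:
            tokens.extend(tokenize_smiles(chunk))
    return tokens


def detokenize_molecule_target(tokens: Iterable[str]) -> str:
    chunks: List[str] = [""]
    for tok in tokens:
        if tok == SEP:
            chunks.append("")
        else:
            chunks[-1] += tok
    return " ".join(c for c in chunks if c)


def tokenize_target(route: str, target: str) -> List[str]:
    return (
        tokenize_molecule_target(target) if route == "molecule" else tokenize_words(target)
    )


def detokenize_target(route: str, tokens: Iterable[str]) -> str:
    return (
        detokenize_molecule_target(tokens) if route == "molecule" else detokenize(tokens)
    )


# ---------------------------------------------------------------------------
# single-route seq2seq
# ---------------------------------------------------------------------------


class Seq2Seq(nn.Module):
    """One transformer encoder–decoder over a shared route vocabulary."""

    def __init__(self, vocab: Vocab, config: ModelConfig, rng: np.random.Generator):
        V, D = len(vocab), config.hidden
        self.vocab = vocab
        self.config = config
        self.tok_emb = nn.Tensor(rng.normal(0, 0.02, (V, D)), requires_grad=True)
        self.pos_emb = nn.Tensor(
            rng.normal(0, 0.02, (config.max_len, D)), requires_grad=True
        )
        self.enc_layers = [
            nn.EncoderLayer(D, config.heads, config.ffn, rng)
            for _ in range(config.layers)
        ]
        self.dec_layers = [
            nn.DecoderLayer(D, config.heads, config.ffn, rng)
            for _ in range(config.layers)
        ]
        self.enc_ln = nn.LayerNorm(D)
        self.dec_ln = nn.LayerNorm(D)
        self.out_proj = nn.Linear(D, V, rng)

    # -- helpers ------------------------------------------------------------

    def _pad(self, seqs: Sequence[List[int]]) -> Tuple[np.ndarray, List[int]]:
        pad_id = self.vocab.id(PAD)
        T = max(1, max(len(s) for s in seqs))
        T = min(T, self.config.max_len)
        out = np.full((len(seqs), T), pad_id, dtype=np.int64)
        lengths = []
        for b, s in enumerate(seqs):
            s = s[:T]
            out[b, : len(s)] = s
            lengths.append(len(s))
        return out, lengths

    def _embed(self, ids: np.ndarray) -> nn.Tensor:
        pos = nn.embedding(self.pos_emb, np.arange(ids.shape[1]))
        return nn.embedding(self.tok_emb, ids) + pos

    def encode(self, src: Sequence[List[int]]):
        ids, lengths = self._pad(src)
        mask = nn.padding_mask(lengths, ids.shape[1])
        x = self._embed(ids)
        for layer in self.enc_layers:
            x = layer(x, mask)
        return self.enc_ln(x), mask

    def _decode(self, memory, src_mask, tgt_ids: np.ndarray) -> nn.Tensor:
        T = tgt_ids.shape[1]
        x = self._embed(tgt_ids)
        self_mask = nn.causal_mask(T)
        for layer in self.dec_layers:
            x = layer(x, memory, self_mask, src_mask)
        return self.out_proj(self.dec_ln(x))

    # -- training and inference --------------------------------------------

    def loss(self, src: Sequence[List[int]], tgt: Sequence[List[int]]) -> nn.Tensor:
        """Teacher-forced mean cross-entropy over non-pad target tokens."""
        bos, eos, pad_id = (self.vocab.id(t) for t in (BOS, EOS, PAD))
        limit = self.config.max_len - 1
        dec_in = [[bos] + t[:limit] for t in tgt]
        dec_out = [t[:limit] + [eos] for t in tgt]
        memory, src_mask = self.encode(src)
        in_ids, _ = self._pad(dec_in)
        out_ids, _ = self._pad(dec_out)
        logits = self._decode(memory, src_mask, in_ids)
        mask = (out_ids != pad_id).astype(np.float64)
        # padded rows of dec_in vs dec_out line up because both share lengths
        return nn.cross_entropy(logits, out_ids, mask)

    def beam_search(
        self, src: List[int], k: int, beam_width: Optional[int] = None
    ) -> List[Tuple[List[int], float]]:
        """Deterministic beam search; returns ≥k (sequence, logprob) pairs
        sorted best-first (fewer only if the beam collapses)."""
        width = max(beam_width or 0, k, 4)
        bos, eos = self.vocab.id(BOS), self.vocab.id(EOS)
        memory, src_mask = self.encode([src])
        beams: List[Tuple[List[int], float]] = [([bos], 0.0)]
        done: List[Tuple[List[int], float]] = []
        for _ in range(self.config.max_len - 1):
            if not beams:
                break
            ids, _ = self._pad([b[0] for b in beams])
            B = len(beams)
            mem = nn.Tensor(np.repeat(memory.data, B, axis=0))
            msk = np.repeat(src_mask, B, axis=0)
            logits = self._decode(mem, msk, ids).data[:, -1, :]
            shifted = logits - logits.max(axis=-1, keepdims=True)
            logprobs = shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
            candidates: List[Tuple[List[int], float]] = []
            for (seq, score), lp in zip(beams, logprobs):
                top = np.argsort(-lp)[: width + 1]
                for tok in top:
                    candidates.append((seq + [int(tok)], score + float(lp[tok])))
            candidates.sort(key=lambda c: -c[1])
            # only the overall top-width expansions survive; finished ones
            # retire to the done pool without consuming a beam slot
            beams = []
            for seq, score in candidates[: 2 * width]:
                if seq[-1] == eos:
                    done.append((seq[1:-1], score))
                elif len(beams) < width:
                    beams.append((seq, score))
        done.extend((seq[1:], score) for seq, score in beams)
        # rank by mean token log-probability to remove the short-sequence bias
        done.sort(key=lambda c: -(c[1] / max(len(c[0]), 1)))
        return done

    def greedy(self, src: List[int]) -> List[int]:
        return self.beam_search(src, k=1, beam_width=1)[0][0]


class TwinSeq2Seq:
    """Two fully independent Seq2Seq stacks, routed by target modality."""

    def __init__(self, config: ModelConfig, mol_vocab: Vocab, text_vocab: Vocab):
        self.config = config
        rng = np.random.default_rng(config.seed)
        # one generator, fixed construction order → deterministic init
        self.routes: Dict[str, Seq2Seq] = {
            "molecule": Seq2Seq(mol_vocab, config, rng),
            "text": Seq2Seq(text_vocab, config, rng),
        }
        config.smiles_vocab_size = len(mol_vocab)
        config.text_vocab_size = len(text_vocab)

    @classmethod
    def from_data(
        cls,
        config: ModelConfig,
        knowledge_records: Iterable[KnowledgeRecord] = (),
        dialogues: Iterable[Dialogue] = (),
        caption_records: Iterable[DescribedMolecule] = (),
        generation_pairs: Iterable[DescribedMolecule] = (),
    ) -> "TwinSeq2Seq":
        """Build vocabularies from everything the model may train on.

        ``caption_records`` feed the understanding (text-out) route;
        ``generation_pairs`` feed description→molecule examples into the
        molecule route, as used when merging dual-augmented pairs into
        generation fine-tuning.
        """
        seqs: Dict[str, List[List[str]]] = {"molecule": [], "text": []}
        for rec in generation_pairs:
            seqs["molecule"].append(
                tokenize_mixed(f"{PREFIX_GENERATE} {rec.description}")
            )
            seqs["molecule"].append(tokenize_target("molecule", rec.smiles))
        for rec in knowledge_records:
            route = route_of(rec.task)
            seqs[route].append(tokenize_mixed(rec.source))
            seqs[route].append(tokenize_target(route, rec.target))
        for d in dialogues:
            prev = None
            for turn in d.turns:
                src = f"{PREFIX_GENERATE} {make_turn_input(turn.text, prev)}"
                seqs["molecule"].append(tokenize_mixed(src))
                seqs["molecule"].append(
                    tokenize_target("molecule", turn.expected_smiles)
                )
                prev = turn.expected_smiles
        for rec in caption_records:
            seqs["text"].append(tokenize_mixed(f"{PREFIX_DESCRIBE} {rec.smiles}"))
            seqs["text"].append(tokenize_target("text", rec.description))
        return cls(
            config,
            mol_vocab=Vocab.build(seqs["molecule"]),
            text_vocab=Vocab.build(seqs["text"]),
        )

    def parameters(self) -> Dict[str, Dict[str, nn.Tensor]]:
        return {name: s2s.parameters() for name, s2s in self.routes.items()}

    def n_parameters(self) -> int:
        return sum(
            p.data.size for route in self.parameters().values() for p in route.values()
        )

    # -- checkpointing ------------------------------------------------------

    def save(self, ckpt_dir: str | Path) -> None:
        ckpt_dir = Path(ckpt_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        with open(ckpt_dir / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
        for name, s2s in self.routes.items():
            np.savez(
                ckpt_dir / f"params_{name}.npz",
                **{k: p.data for k, p in s2s.parameters().items()},
            )
            with open(ckpt_dir / f"vocab_{name}.json", "w") as fh:
                json.dump(s2s.vocab.tokens(), fh)

    @classmethod
    def load(cls, ckpt_dir: str | Path) -> "TwinSeq2Seq":
        ckpt_dir = Path(ckpt_dir)
        with open(ckpt_dir / "config.json") as fh:
            config = ModelConfig(**json.load(fh))
        model = cls.__new__(cls)
        model.config = config
        model.routes = {}
        rng = np.random.default_rng(config.seed)
        for name in ("molecule", "text"):
            with open(ckpt_dir / f"vocab_{name}.json") as fh:
                tokens = json.load(fh)
            vocab = Vocab.__new__(Vocab)
            vocab._itos = list(tokens)
            vocab._stoi = {t: i for i, t in enumerate(tokens)}
            s2s = Seq2Seq(vocab, config, rng)
            data = np.load(ckpt_dir / f"params_{name}.npz")
            for key, param in s2s.parameters().items():
                param.data = data[key]
            model.routes[name] = s2s
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    """Step counter, per-task running mean losses, and sampler RNG state."""

    step: int = 0
    losses: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    history: List[Tuple[int, float]] = field(default_factory=list)

    def update(self, task: str, loss: float, n: int) -> None:
        total = self.counts.get(task, 0)
        prev = self.losses.get(task, 0.0)
        self.losses[task] = (prev * total + loss * n) / (total + n)
        self.counts[task] = total + n


TrainItem = Tuple[str, str, List[int], List[int]]  # (route, task, src_ids, tgt_ids)


def _mixture_counts(n_by_task: Dict[str, int], batch: int) -> Dict[str, int]:
    """Largest-remainder allocation of a batch across tasks (±1 of exact)."""
    total = sum(n_by_task.values())
    exact = {t: batch * n / total for t, n in n_by_task.items()}
    counts = {t: int(x) for t, x in exact.items()}
    rest = sorted(exact, key=lambda t: exact[t] - counts[t], reverse=True)
    for t in rest[: batch - sum(counts.values())]:
        counts[t] += 1
    return counts


class Trainer:
    """Mixture-sampled mini-batch training over both routes."""

    def __init__(self, model: TwinSeq2Seq, lr: Optional[float] = None, seed: int = 0):
        self.model = model
        lr = model.config.lr if lr is None else lr
        self.optimizers = {
            name: nn.Adam(s2s.parameters(), lr=lr)
            for name, s2s in model.routes.items()
        }
        self.rng = random.Random(seed)
        self.state = TrainState()

    def save_checkpoint(self, ckpt_dir: str | Path) -> None:
        """Model parameters plus optimizer and sampler state, so training
        can resume and reproduce the exact loss trajectory."""
        ckpt_dir = Path(ckpt_dir)
        self.model.save(ckpt_dir)
        for name, opt in self.optimizers.items():
            np.savez(
                ckpt_dir / f"adam_{name}.npz",
                t=np.array(opt.t),
                **{f"m.{k}": v for k, v in opt.m.items()},
                **{f"v.{k}": v for k, v in opt.v.items()},
            )
        state = self.rng.getstate()
        with open(ckpt_dir / "trainer_state.json", "w") as fh:
            json.dump(
                {
                    "step": self.state.step,
                    "losses": self.state.losses,
                    "counts": self.state.counts,
                    "rng": [state[0], list(state[1]), state[2]],
                },
                fh,
            )

    @classmethod
    def load_checkpoint(cls, ckpt_dir: str | Path) -> "Trainer":
        ckpt_dir = Path(ckpt_dir)
        model = TwinSeq2Seq.load(ckpt_dir)
        trainer = cls(model)
        for name, opt in trainer.optimizers.items():
            data = np.load(ckpt_dir / f"adam_{name}.npz")
            opt.t = int(data["t"])
            opt.m = {k[2:]: data[k] for k in data.files if k.startswith("m.")}
            opt.v = {k[2:]: data[k] for k in data.files if k.startswith("v.")}
        with open(ckpt_dir / "trainer_state.json") as fh:
            saved = json.load(fh)
        trainer.state.step = saved["step"]
        trainer.state.losses = dict(saved["losses"])
        trainer.state.counts = dict(saved["counts"])
        rng_state = saved["rng"]
        trainer.rng.setstate((rng_state[0], tuple(rng_state[1]), rng_state[2]))
        return trainer

    def train(
        self,
        items: Sequence[TrainItem],
        steps: int,
        batch: int,
        log_path: Optional[str | Path] = None,
        checkpoint_dir: Optional[str | Path] = None,
        checkpoint_interval: int = 0,
        lr_decay: float = 0.9,
    ) -> TrainState:
        """Run ``steps`` optimizer steps.

        The learning rate decays linearly to (1 - lr_decay) of its initial
        value over this call, which lets memorization runs settle instead of
        orbiting the optimum.
        """
        if not items:
            raise ValueError("empty training stream")
        lr0 = {name: opt.lr for name, opt in self.optimizers.items()}
        by_task: Dict[str, List[TrainItem]] = {}
        for item in items:
            by_task.setdefault(item[1], []).append(item)
        n_by_task = {t: len(v) for t, v in by_task.items()}
        log_rows: List[str] = []
        for step_i in range(steps):
            frac = step_i / max(steps - 1, 1)
            for name, opt in self.optimizers.items():
                opt.lr = lr0[name] * (1.0 - lr_decay * frac)
            counts = _mixture_counts(n_by_task, batch)
            chosen: List[TrainItem] = []
            for task, cnt in counts.items():
                pool = by_task[task]
                chosen.extend(
                    pool[self.rng.randrange(len(pool))] for _ in range(cnt)
                )
            step_loss = 0.0
            # one optimizer step per route, tasks batched route-wise
            for route in ("molecule", "text"):
                groups: Dict[str, List[TrainItem]] = {}
                for item in chosen:
                    if item[0] == route:
                        groups.setdefault(item[1], []).append(item)
                if not groups:
                    continue
                opt = self.optimizers[route]
                opt.zero_grad()
                for task, group in sorted(groups.items()):
                    src = [it[2] for it in group]
                    tgt = [it[3] for it in group]
                    loss = self.model.routes[route].loss(src, tgt)
                    # scale so the route loss is the example-weighted mean
                    (loss * (len(group) / sum(len(g) for g in groups.values()))).backward()
                    self.state.update(task, float(loss.data), len(group))
                    step_loss += float(loss.data) * len(group) / batch
                opt.step()
            self.state.step += 1
            self.state.history.append((self.state.step, step_loss))
            log_rows.append(f"{self.state.step}\t{step_loss:.6f}")
            if (
                checkpoint_dir
                and checkpoint_interval
                and self.state.step % checkpoint_interval == 0
            ):
                self.model.save(Path(checkpoint_dir) / f"step_{self.state.step}")
        if log_path is not None:
            Path(log_path).parent.mkdir(parents=True, exist_ok=True)
            header = "step\tloss\n"
            mode = "a" if Path(log_path).exists() else "w"
            with open(log_path, mode) as fh:
                if mode == "w":
                    fh.write(header)
                fh.write("\n".join(log_rows) + "\n")
        return self.state


# ---------------------------------------------------------------------------
# task-specific item builders and entry points
# ---------------------------------------------------------------------------


def _knowledge_items(model: TwinSeq2Seq, records: Iterable[KnowledgeRecord]):
    items: List[TrainItem] = []
    for rec in records:
        route = route_of(rec.task)
        vocab = model.routes[route].vocab
        items.append(
            (
                route,
                rec.task,
                vocab.encode(tokenize_mixed(rec.source)),
                vocab.encode(tokenize_target(route, rec.target)),
            )
        )
    return items


def dialogue_turn_items(model: TwinSeq2Seq, dialogues: Iterable[Dialogue]):
    """Per-turn generation examples with teacher-forced previous molecules."""
    vocab = model.routes["molecule"].vocab
    items: List[TrainItem] = []
    for d in dialogues:
        prev = None
        for turn in d.turns:
            src = f"{PREFIX_GENERATE} {make_turn_input(turn.text, prev)}"
            items.append(
                (
                    "molecule",
                    "generate",
                    vocab.encode(tokenize_mixed(src)),
                    vocab.encode(tokenize_target("molecule", turn.expected_smiles)),
                )
            )
            prev = turn.expected_smiles
    return items


def pair_generation_items(model: TwinSeq2Seq, records: Iterable[DescribedMolecule]):
    """Single-shot description→molecule examples (e.g. augmented pairs)."""
    vocab = model.routes["molecule"].vocab
    return [
        (
            "molecule",
            "generate",
            vocab.encode(tokenize_mixed(f"{PREFIX_GENERATE} {rec.description}")),
            vocab.encode(tokenize_target("molecule", rec.smiles)),
        )
        for rec in records
    ]


def caption_items(model: TwinSeq2Seq, records: Iterable[DescribedMolecule]):
    vocab = model.routes["text"].vocab
    return [
        (
            "text",
            "describe",
            vocab.encode(tokenize_mixed(f"{PREFIX_DESCRIBE} {rec.smiles}")),
            vocab.encode(tokenize_target("text", rec.description)),
        )
        for rec in records
    ]


def pretrain(
    model: TwinSeq2Seq,
    records: Iterable[KnowledgeRecord],
    steps: int,
    batch: int,
    seed: int = 0,
    **train_kwargs,
) -> TrainState:
    """Multi-task pretraining on mixed knowledge records."""
    trainer = Trainer(model, seed=seed)
    return trainer.train(_knowledge_items(model, records), steps, batch, **train_kwargs)


def finetune_generation(
    model: TwinSeq2Seq,
    dialogues: Iterable[Dialogue],
    steps: int,
    batch: int,
    seed: int = 0,
    trainer: Optional[Trainer] = None,
    augmented_records: Iterable[DescribedMolecule] = (),
    **train_kwargs,
) -> TrainState:
    """Fine-tune dialogue generation, optionally merging dual-augmented
    description→molecule pairs into the training stream."""
    trainer = trainer or Trainer(model, seed=seed)
    items = dialogue_turn_items(model, dialogues) + pair_generation_items(
        model, augmented_records
    )
    return trainer.train(items, steps, batch, **train_kwargs)


def finetune_understanding(
    model: TwinSeq2Seq,
    records: Iterable[DescribedMolecule],
    steps: int,
    batch: int,
    seed: int = 0,
    trainer: Optional[Trainer] = None,
    **train_kwargs,
) -> TrainState:
    trainer = trainer or Trainer(model, seed=seed)
    return trainer.train(caption_items(model, records), steps, batch, **train_kwargs)


def generate_description(model: TwinSeq2Seq, smiles: str) -> str:
    """Greedy molecule-understanding decode (molecule → description)."""
    if not smiles:
        raise ValueError("empty SMILES")
    s2s = model.routes["text"]
    src = s2s.vocab.encode(tokenize_mixed(f"{PREFIX_DESCRIBE} {smiles}"))
    ids = s2s.greedy(src)
    return detokenize_target("text", s2s.vocab.decode(ids))


def generate_molecules(model: TwinSeq2Seq, prompt: str, k: int = 3) -> List[str]:
    """Top-k distinct molecule predictions for a text prompt (beam search)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    s2s = model.routes["molecule"]
    src = s2s.vocab.encode(tokenize_mixed(f"{PREFIX_GENERATE} {prompt}"))
    results = s2s.beam_search(src, k=k)
    out: List[str] = []
    for ids, _score in results:
        smiles = detokenize_target("molecule", s2s.vocab.decode(ids))
        if smiles not in out:
            out.append(smiles)
        if len(out) == k:
            break
    while out and len(out) < k:  # beam collapse: pad with the best result
        out.append(out[-1])
    return out


def dual_augment(
    model: TwinSeq2Seq, molecules: Iterable[str]
) -> List[DescribedMolecule]:
    """Generate one augmented description per molecule with the
    understanding route; outputs are flagged ``augmented`` so they can be
    merged into generation fine-tuning but excluded from evaluation."""
    out = []
    for i, smiles in enumerate(molecules):
        out.append(
            DescribedMolecule(
                molecule_id=f"aug{i:05d}",
                smiles=smiles,
                description=generate_description(model, smiles),
                augmented=True,
            )
        )
    return out


def predict_dialogue(
    model: TwinSeq2Seq, dialogue: Dialogue, k: int = 3, teacher_force: bool = True
):
    """Top-k predictions per turn.

    ``teacher_force=True`` conditions each turn on the reference molecule of
    the previous turn (training-style); otherwise on the model's own rank-1
    output from the previous turn (inference-style).
    """
    from .metrics import GenerationPrediction

    preds = []
    prev: Optional[str] = None
    for turn in dialogue.turns:
        prompt = make_turn_input(turn.text, prev)
        top = generate_molecules(model, prompt, k=k)
        preds.append(
            GenerationPrediction(
                item_id=f"{dialogue.dialogue_id}_t{turn.k}",
                top3=tuple(top[:3]),
                gold=turn.expected_smiles,
            )
        )
        prev = turn.expected_smiles if teacher_force else top[0]
    return preds
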