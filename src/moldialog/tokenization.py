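"""Tokenizers and vocabularies for text and SMILES sequences.

SMILES are tokenized at the atom level (bracket atoms, two-letter
elements, ring-closure digits) so that masking or decoding never splits an
atom symbol. Text is tokenized into words and punctuation, with a
character-piece fallback for out-of-vocabulary words (a degenerate
word-piece scheme — the synthetic corpus has a closed vocabulary, so the
fallback only fires on unseen input). Mixed sources (text that embeds
SMILES, e.g. "It looks like CCO.") route embedded molecule strings through
the atom tokenizer between bracket markers.
"""

from __future__ import annotations

import re
from typing import Iterable, List

from rdkit import Chem

SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|@@|@|=|#|\(|\)|%\d{2}|\d|[BCNOPSFIbcnops]|[+\-\\/\.~\*])"
)

WORD_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")

MOL_OPEN, MOL_CLOSE = "<mol>", "</mol>"
PAD, BOS, EOS, UNK = "<pad>", "<s>", "</s>", "<unk>"
SEP = "<sep>"  # separates multiple SMILES in one molecule-route target
N_SENTINELS = 32

_STOPWORDS = {
    # words that would otherwise parse as SMILES ("In" = indium, "I" = iodine…)
    "i", "in", "it", "is", "no", "if", "of", "os", "as", "the", "a",
}


def sentinel(i: int) -> str:
    return f"<extra_id_{i}>"


SENTINELS = [sentinel(i) for i in range(N_SENTINELS)]
SPECIALS = [PAD, BOS, EOS, UNK, SEP, MOL_OPEN, MOL_CLOSE] + SENTINELS


def tokenize_smiles(smiles: str) -> List[str]:
    """Atom-level SMILES tokens; concatenation restores the string."""
    tokens = SMILES_TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        # unknown characters: fall back to single characters for those spans
        tokens = []
        pos = 0
        for m in SMILES_TOKEN_RE.finditer(smiles):
            tokens.extend(smiles[pos : m.start()])
            tokens.append(m.group(0))
            pos = m.end()
        tokens.extend(smiles[pos:])
    return tokens


def tokenize_words(text: str) -> List[str]:
    """Words and punctuation marks, case preserved."""
    return WORD_RE.findall(text)


def _is_embedded_smiles(chunk: str) -> bool:
    if len(chunk) < 2 or chunk.lower() in _STOPWORDS:
        return False
    if not re.fullmatch(r"[A-Za-z0-9@+\-\[\]()=#%\\/\.]+", chunk):
        return False
    if chunk.isalpha() and chunk.islower():
        return False  # ordinary lowercase words never count
    return Chem.MolFromSmiles(chunk, sanitize=True) is not None


def tokenize_mixed(text: str) -> List[str]:
    """Tokenize text that may embed SMILES strings.

    Whitespace chunks that parse as molecules become
    ``<mol> atom-tokens </mol>``; everything else is word-tokenized.
    """
    tokens: List[str] = []
    for chunk in text.split():
        if chunk in SPECIALS:
            tokens.append(chunk)
            continue
        core = chunk.rstrip(".,;:!?")
        trailing = chunk[len(core) :]
        if core and _is_embedded_smiles(core):
            tokens.append(MOL_OPEN)
            tokens.extend(tokenize_smiles(core))
            tokens.append(MOL_CLOSE)
        else:
            tokens.extend(tokenize_words(core))
        tokens.extend(tokenize_words(trailing))
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    """Inverse of tokenize_mixed up to whitespace: SMILES spans concatenate,
    words join with spaces, punctuation attaches to the previous token."""
    out: List[str] = []
    in_mol = False
    for tok in tokens:
        if tok == MOL_OPEN:
            in_mol = True
            out.append("")
        elif tok == MOL_CLOSE:
            in_mol = False
        elif in_mol:
            out[-1] = out[-1] + tok
        elif re.fullmatch(r"[^\sA-Za-z0-9]", tok) and out:
            out[-1] = out[-1] + tok
        else:
            out.append(tok)
    return " ".join(t for t in out if t != "")


class Vocab:
    """Token↔id table with specials, built from an iterable of sequences.

    Unknown words decompose into character pieces ("##x") when possible,
    otherwise map to <unk>.
    """

    def __init__(self, tokens: Iterable[str]):
        self._itos: List[str] = list(SPECIALS)
        seen = set(self._itos)
        for tok in tokens:
            if tok not in seen:
                seen.add(tok)
                self._itos.append(tok)
        # character pieces for OOV decomposition
        for ch in sorted({c for t in self._itos for c in t if len(t) < 24}):
            piece = f"##{ch}"
            if piece not in seen:
                seen.add(piece)
                self._itos.append(piece)
        self._stoi = {t: i for i, t in enumerate(self._itos)}

    @classmethod
    def build(cls, sequences: Iterable[List[str]]) -> "Vocab":
        counts: dict = {}
        for seq in sequences:
            for tok in seq:
                counts[tok] = counts.get(tok, 0) + 1
        return cls(sorted(counts, key=lambda t: (-counts[t], t)))

    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    def encode(self, tokens: List[str]) -> List[int]:
        ids: List[int] = []
        for tok in tokens:
            if tok in self._stoi:
                ids.append(self._stoi[tok])
            else:
                pieces = [f"##{c}" for c in tok]
                if all(p in self._stoi for p in pieces):
                    ids.extend(self._stoi[p] for p in pieces)
                else:
                    ids.append(self._stoi[UNK])
        return ids

    def decode(self, ids: Iterable[int]) -> List[str]:
        tokens: List[str] = []
        for i in ids:
            tok = self._itos[i]
            if tok.startswith("##") and tokens and tokens[-1] not in SPECIALS:
                tokens[-1] = tokens[-1] + tok[2:]
            elif tok.startswith("##"):  # piece at sequence start
                tokens.append(tok[2:])
            else:
                tokens.append(tok)
        return tokens

    def token(self, i: int) -> str:
        return self._itos[i]

    def id(self, token: str) -> int:
        return self._stoi.get(token, self._stoi[UNK])

    def tokens(self) -> List[str]:
        return list(self._itos)
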