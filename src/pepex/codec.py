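"""Sequence representation: vocabulary, base/extension split, tokenization.

A peptide is split into a fixed-length *base* (the parent motif, 15 residues
by default) and a variable-length terminal *extension*.  Both parts are mapped
onto integer tokens from a 24-symbol vocabulary: indices 0-3 are the start,
end, unknown-residue and padding specials, indices 4-23 the twenty natural
amino acids in alphabetical one-letter order.  Extensions are framed with
start/end tokens and padded with the pad token to a fixed total length of 35;
the base peptide is framed the same way (17 tokens for a 15-residue base).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: non-canonical one-letter codes mapped to the unknown token
AMBIGUOUS_RESIDUES = "BJOUXZ"

START, END, UNK, PAD = 0, 1, 2, 3
VOCAB_SIZE = 24

#: total tokenized length of an extension (start + content + end + padding)
EXT_PADDED_LEN = 35
#: residue length of the base peptide
BASE_LEN = 15
#: maximum residue content of an extension (start/end must fit within 35)
MAX_EXT_CONTENT = EXT_PADDED_LEN - 2


class CodecError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Bijective 24-symbol token map with reserved specials at indices 0-3."""

    token_to_index: dict = field(default_factory=lambda: _default_mapping())

    def __post_init__(self):
        if len(self.token_to_index) != VOCAB_SIZE:
            raise CodecError("vocabulary must contain exactly 24 symbols")
        if len(set(self.token_to_index.values())) != VOCAB_SIZE:
            raise CodecError("vocabulary indices must be unique")
        for sym, idx in (("<s>", START), ("</s>", END), ("<unk>", UNK), ("<pad>", PAD)):
            if self.token_to_index.get(sym) != idx:
                raise CodecError(f"special token {sym!r} must sit at index {idx}")

    def __len__(self) -> int:
        return len(self.token_to_index)

    @property
    def index_to_token(self) -> dict:
        return {v: k for k, v in self.token_to_index.items()}

    def to_json(self) -> str:
        return json.dumps(self.token_to_index)

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        return cls(token_to_index=json.loads(payload))


def _default_mapping() -> dict:
    mapping = {"<s>": START, "</s>": END, "<unk>": UNK, "<pad>": PAD}
    for i, aa in enumerate(AMINO_ACIDS):
        mapping[aa] = 4 + i
    return mapping


VOCAB = Vocabulary()
_AA_TO_IDX = {aa: 4 + i for i, aa in enumerate(AMINO_ACIDS)}
_IDX_TO_AA = {v: k for k, v in _AA_TO_IDX.items()}


@dataclass(frozen=True)
class TokenizedSequence:
    """Integer token array with its role ('base' or 'extension')."""

    tokens: np.ndarray
    role: str

    def __post_init__(self):
        tok = np.asarray(self.tokens, dtype=np.int64)
        object.__setattr__(self, "tokens", tok)
        if self.role not in ("base", "extension"):
            raise CodecError(f"unknown role {self.role!r}")
        if tok.min(initial=0) < 0 or tok.max(initial=0) >= VOCAB_SIZE:
            raise CodecError("token indices must lie in [0, 23]")
        if self.role == "extension" and tok.shape[0] != EXT_PADDED_LEN:
            raise CodecError(f"extension tokens must have length {EXT_PADDED_LEN}")

    @property
    def one_hot(self) -> np.ndarray:
        return one_hot(self.tokens)

    def __len__(self) -> int:
        return int(self.tokens.shape[0])


def split_base_extension(peptide: str, base: str):
    """Split ``peptide`` into the parent ``base`` plus a terminal extension.

    Returns ``(base, extension, terminus)`` where terminus is ``"N"`` when the
    extension precedes the base and ``"C"`` when it follows.  The base must
    occur as a prefix or suffix; an internal-only occurrence or residues on
    both sides are rejected.  ``peptide == base`` yields an empty C-terminal
    extension by convention.
    """
    if not base:
        raise CodecError("base peptide must be non-empty")
    if peptide == base:
        return base, "", "C"
    if peptide.startswith(base):
        return base, peptide[len(base):], "C"
    if peptide.endswith(base):
        return base, peptide[: len(peptide) - len(base)], "N"
    if base in peptide:
        raise CodecError(
            "base occurs internally: extensions on both termini are not supported"
        )
    raise CodecError("base peptide not found as a prefix or suffix of the peptide")


def tokenize(seq: str, role: str = "extension", base_len: int = BASE_LEN) -> TokenizedSequence:
    """Map a residue string to tokens: start, content, end (+ padding to 35).

    Unknown residue codes (B, J, O, U, X, Z) map to the unknown token; any
    other character is an error.  A base-role sequence must have exactly
    ``base_len`` residues; an extension may hold at most 33.
    """
    content = []
    for ch in seq.upper():
        if ch in _AA_TO_IDX:
            content.append(_AA_TO_IDX[ch])
        elif ch in AMBIGUOUS_RESIDUES:
            content.append(UNK)
        else:
            raise CodecError(f"character {ch!r} is not a recognised residue code")
    if role == "base":
        if len(content) != base_len:
            raise CodecError(f"base peptide must have exactly {base_len} residues")
        tokens = [START] + content + [END]
    elif role == "extension":
        if len(content) > MAX_EXT_CONTENT:
            raise CodecError(
                f"extension of {len(content)} residues exceeds capacity {MAX_EXT_CONTENT}"
            )
        tokens = [START] + content + [END]
        tokens += [PAD] * (EXT_PADDED_LEN - len(tokens))
    else:
        raise CodecError(f"unknown role {role!r}")
    return TokenizedSequence(np.array(tokens, dtype=np.int64), role)


def detokenize(tokens) -> str:
    """Inverse of :func:`tokenize`: stop at the first end token, strip specials.

    Lenient by contract: trailing tokens after the end token are ignored and
    the unknown token renders as ``'X'``.
    """
    if isinstance(tokens, TokenizedSequence):
        tokens = tokens.tokens
    out = []
    for t in np.asarray(tokens, dtype=np.int64):
        t = int(t)
        if t == END:
            break
        if t in (START, PAD):
            continue
        out.append("X" if t == UNK else _IDX_TO_AA[t])
    return "".join(out)


def one_hot(tokens) -> np.ndarray:
    """L x 24 one-hot matrix of a token array (each row sums to one)."""
    if isinstance(tokens, TokenizedSequence):
        tokens = tokens.tokens
    tok = np.asarray(tokens, dtype=np.int64)
    if tok.min(initial=0) < 0 or tok.max(initial=0) >= VOCAB_SIZE:
        raise CodecError("token indices must lie in [0, 23]")
    mat = np.zeros((tok.shape[0], VOCAB_SIZE), dtype=np.float64)
    mat[np.arange(tok.shape[0]), tok] = 1.0
    return mat


def sequence_lengths(tokens2d: np.ndarray) -> np.ndarray:
    """Per-row token count up to and including the end token."""
    tok = np.asarray(tokens2d)
    is_end = tok == END
    if not is_end.any(axis=1).all():
        raise CodecError("every tokenized sequence must contain an end token")
    return is_end.argmax(axis=1) + 1
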