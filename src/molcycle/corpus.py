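"""SMILES corpus handling: loading, vocabulary, integer encoding.

The generator is a character-level language model, so the corpus layer is
deliberately simple: each molecule is a raw character string, bracketed by a
start symbol ``G`` and an end symbol ``"\\n"``, and the whole corpus becomes
one long stream of integer token indices.  Two-letter element symbols such as
``Cl`` are therefore two tokens; this matches a vocabulary defined as the set
of unique *characters* in the data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

START = "G"
END = "\n"


class EncodingError(ValueError):
    """A string contains a character outside the vocabulary."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijection between SMILES characters (plus delimiters) and [0, V)."""

    symbols: tuple[str, ...]
    index_of: dict[str, int] = field(repr=False)

    def __init__(self, symbols):
        symbols = tuple(symbols)
        object.__setattr__(self, "symbols", symbols)
        object.__setattr__(self, "index_of", {s: i for i, s in enumerate(symbols)})
        if len(self.index_of) != len(symbols):
            raise ValueError("duplicate symbols in vocabulary")
        for required in (START, END):
            if required not in self.index_of:
                raise ValueError(f"vocabulary must contain {required!r}")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def start_index(self) -> int:
        return self.index_of[START]

    @property
    def end_index(self) -> int:
        return self.index_of[END]

    def encode_string(self, s: str) -> np.ndarray:
        """Map a string to its token indices (no delimiters added)."""
        try:
            return np.array([self.index_of[ch] for ch in s], dtype=np.int64)
        except KeyError as exc:
            raise EncodingError(
                f"character {exc.args[0]!r} is not in the vocabulary"
            ) from None

    def decode(self, indices) -> str:
        return "".join(self.symbols[int(i)] for i in indices)

    def to_json(self) -> str:
        return json.dumps({s: i for i, s in enumerate(self.symbols)})

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        mapping = json.loads(text)
        symbols = [None] * len(mapping)
        for sym, idx in mapping.items():
            symbols[int(idx)] = sym
        return cls(symbols)


@dataclass
class EncodedCorpus:
    """A delimited token stream plus the canonical forms of its molecules.

    ``token_stream`` is the concatenation ``G + molecule + \\n`` over all
    molecules.  ``source_canonical_set`` holds the canonical SMILES of the
    parseable training molecules and is the reference set for novelty checks.
    """

    token_stream: np.ndarray
    vocab: TokenVocabulary
    window_length: int
    source_canonical_set: frozenset[str]

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be positive")
        if self.token_stream.size and self.token_stream.max() >= self.vocab.size:
            raise ValueError("token index out of vocabulary range")

    def n_windows(self, stride: int | None = None) -> int:
        stride = stride or self.window_length
        usable = self.token_stream.size - 1  # last token has no next-token target
        if usable < self.window_length:
            return 0
        return 1 + (usable - self.window_length) // stride

    def windows(self, stride: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (inputs, targets), each of shape (n_windows, window_length).

        Targets are the inputs shifted by one position: next-character
        prediction with teacher forcing.  Windows are taken from the
        concatenated stream with the given stride (default: non-overlapping).
        """
        stride = stride or self.window_length
        n = self.n_windows(stride)
        L = self.window_length
        starts = np.arange(n) * stride
        idx = starts[:, None] + np.arange(L)[None, :]
        return self.token_stream[idx], self.token_stream[idx + 1]


def load_corpus(path, min_len: int = 1, max_len: int = 10**9) -> list[str]:
    """Read a SMILES line file, keeping lines whose raw length is in bounds.

    Bounds are inclusive on both ends; line order is preserved.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kept = []
    total = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            total += 1
            if min_len <= len(line) <= max_len:
                kept.append(line)
    if not kept:
        raise ValueError(
            f"no molecules within length bounds [{min_len}, {max_len}] in {path}"
        )
    logger.info("loaded %d/%d molecules from %s", len(kept), total, path)
    return kept


def build_vocabulary(molecules: list[str]) -> TokenVocabulary:
    """Character vocabulary of the corpus plus the G / newline delimiters.

    Symbols are ordered by Unicode code point so repeated runs produce the
    same index assignment.
    """
    if not molecules:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    chars = set()
    for m in molecules:
        chars.update(m)
    chars.update((START, END))
    return TokenVocabulary(sorted(chars))


def encode(
    molecules: list[str],
    vocab: TokenVocabulary,
    window_length: int = 75,
    canonicalizer=None,
) -> EncodedCorpus:
    """Encode molecules as one delimited token stream.

    ``canonicalizer`` maps a SMILES string to its canonical form or ``None``
    if unparseable; when omitted the RDKit-backed one from
    :mod:`molcycle.chem_eval` is used.  Unparseable lines still contribute to
    the language-model stream but are excluded from the novelty reference set.
    """
    if canonicalizer is None:
        from molcycle.chem_eval import canonical_smiles as canonicalizer

    pieces = []
    canon = set()
    g, nl = vocab.start_index, vocab.end_index
    for m in molecules:
        body = vocab.encode_string(m)
        pieces.append(np.concatenate(([g], body, [nl])))
        c = canonicalizer(m)
        if c is not None:
            canon.add(c)
    stream = np.concatenate(pieces) if pieces else np.array([], dtype=np.int64)
    return EncodedCorpus(
        token_stream=stream,
        vocab=vocab,
        window_length=window_length,
        source_canonical_set=frozenset(canon),
    )


def one_hot(indices: np.ndarray, vocab_size: int) -> np.ndarray:
    """Expand integer tokens to indicator vectors of length ``vocab_size``."""
    out = np.zeros(indices.shape + (vocab_size,), dtype=np.float32)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out
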