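"""The two sequence encoders used by the pipeline.

* A byte-pair-encoding (BPE) subword tokenizer, trained from scratch on the
  paired corpus, for the autoregressive chemical language model. Whitespace
  pre-tokenization keeps the protein field and the SMILES field from merging
  across their separator; the literal space is itself a vocabulary token so
  decoding is an exact inverse on corpus text.

* A character-to-integer vocabulary for the convolutional affinity
  regressor: each distinct character maps to an id in 1..70, id 0 is the
  pad, and encoded pairs are post-padded/truncated to exactly 800 positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .data_io import AffinityDataset, LigandProteinPair

BOS, EOS, PAD, UNK = "<bos>", "<eos>", "<pad>", "<unk>"
SPACE = " "

__all__ = [
    "BpeTokenizerSpec",
    "BpeTokenizer",
    "train_bpe",
    "encode_for_clm",
    "ClmEncoding",
    "CharVocab",
    "build_char_vocab",
    "encode_for_rcnn",
    "RCNN_INPUT_LENGTH",
]

RCNN_INPUT_LENGTH = 800


@dataclass(frozen=True)
class BpeTokenizerSpec:
    """Training hyperparameters for the subword tokenizer."""

    vocab_size: int = 30000
    min_frequency: int = 2
    max_length: int = 128


class BpeTokenizer:
    """A byte-pair-encoding tokenizer with whitespace pre-tokenization.

    Merges are learned greedily on space-separated words: starting from the
    character alphabet, the most frequent adjacent symbol pair is merged
    until the vocabulary budget is reached or no pair attains the minimum
    frequency. Unknown characters encode to ``<unk>``.
    """

    def __init__(
        self,
        vocab: dict[str, int],
        merges: list[tuple[str, str]],
        max_length: int = 128,
    ) -> None:
        self.vocab = vocab
        self.merges = merges
        self.max_length = max_length
        self._ranks = {pair: i for i, pair in enumerate(merges)}
        self._id_to_token = {i: t for t, i in vocab.items()}
        self._cache: dict[str, list[str]] = {}
        for tok in (BOS, EOS, PAD, UNK):
            if tok not in vocab:
                raise ValueError(f"special token {tok!r} missing from vocab")

    # -- id shortcuts -------------------------------------------------
    @property
    def bos_id(self) -> int:
        return self.vocab[BOS]

    @property
    def eos_id(self) -> int:
        return self.vocab[EOS]

    @property
    def pad_id(self) -> int:
        return self.vocab[PAD]

    @property
    def unk_id(self) -> int:
        return self.vocab[UNK]

    @property
    def space_id(self) -> int:
        return self.vocab[SPACE]

    def __len__(self) -> int:
        return len(self.vocab)

    # -- encoding -----------------------------------------------------
    def _bpe_word(self, word: str) -> list[str]:
        if word in self._cache:
            return self._cache[word]
        symbols = list(word)
        while len(symbols) > 1:
            best_rank, best_i = None, -1
            for i in range(len(symbols) - 1):
                rank = self._ranks.get((symbols[i], symbols[i + 1]))
                if rank is not None and (best_rank is None or rank < best_rank):
                    best_rank, best_i = rank, i
            if best_rank is None:
                break
            merged = symbols[best_i] + symbols[best_i + 1]
            # merge every occurrence of the chosen pair, left to right
            out: list[str] = []
            i = 0
            while i < len(symbols):
                if (
                    i < len(symbols) - 1
                    and symbols[i] + symbols[i + 1] == merged
                    and self._ranks.get((symbols[i], symbols[i + 1])) == best_rank
                ):
                    out.append(merged)
                    i += 2
                else:
                    out.append(symbols[i])
                    i += 1
            symbols = out
        self._cache[word] = symbols
        return symbols

    def tokenize(self, text: str) -> list[str]:
        """Split on whitespace, BPE each word, re-insert space tokens."""
        tokens: list[str] = []
        for w, word in enumerate(text.split(SPACE)):
            if w > 0:
                tokens.append(SPACE)
            if word:
                tokens.extend(self._bpe_word(word))
        return tokens

    def encode(self, text: str) -> list[int]:
        """Token ids of ``text`` (no special tokens added)."""
        return [self.vocab.get(t, self.unk_id) for t in self.tokenize(text)]

    def decode(self, ids: Iterable[int], skip_special: bool = True) -> str:
        specials = {self.bos_id, self.eos_id, self.pad_id}
        parts = []
        for i in ids:
            if skip_special and i in specials:
                continue
            parts.append(self._id_to_token.get(int(i), ""))
        return "".join(parts)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "vocab": self.vocab,
                    "merges": [list(m) for m in self.merges],
                    "max_length": self.max_length,
                }
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "BpeTokenizer":
        blob = json.loads(Path(path).read_text())
        return cls(
            vocab=blob["vocab"],
            merges=[tuple(m) for m in blob["merges"]],
            max_length=blob["max_length"],
        )


def train_bpe(lines: Sequence[str], spec: BpeTokenizerSpec | None = None) -> BpeTokenizer:
    """Train a BPE tokenizer from scratch on a text corpus.

    Raises
    ------
    ValueError
        If the corpus is empty (or all-whitespace).
    """
    if spec is None:
        spec = BpeTokenizerSpec()
    words: dict[tuple[str, ...], int] = {}
    for line in lines:
        for word in line.split():
            key = tuple(word)
            words[key] = words.get(key, 0) + 1
    if not words:
        raise ValueError("cannot train a tokenizer on an empty corpus")

    vocab_tokens: list[str] = [BOS, EOS, PAD, UNK, SPACE]
    alphabet = sorted({c for w in words for c in w})
    vocab_tokens.extend(alphabet)

    merges: list[tuple[str, str]] = []
    work = dict(words)
    while len(vocab_tokens) < spec.vocab_size:
        pair_counts: dict[tuple[str, str], int] = {}
        for w, cnt in work.items():
            for i in range(len(w) - 1):
                p = (w[i], w[i + 1])
                pair_counts[p] = pair_counts.get(p, 0) + cnt
        if not pair_counts:
            break
        best = max(pair_counts, key=lambda p: (pair_counts[p], p))
        if pair_counts[best] < spec.min_frequency:
            break
        merges.append(best)
        merged = best[0] + best[1]
        vocab_tokens.append(merged)
        new_work: dict[tuple[str, ...], int] = {}
        for w, cnt in work.items():
            out: list[str] = []
            i = 0
            while i < len(w):
                if i < len(w) - 1 and (w[i], w[i + 1]) == best:
                    out.append(merged)
                    i += 2
                else:
                    out.append(w[i])
                    i += 1
            key = tuple(out)
            new_work[key] = new_work.get(key, 0) + cnt
        work = new_work

    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    return BpeTokenizer(vocab=vocab, merges=merges, max_length=spec.max_length)


@dataclass(frozen=True)
class ClmEncoding:
    """Token ids for one CLM example plus bookkeeping flags."""

    ids: tuple[int, ...]
    truncated: bool
    is_prompt: bool


def encode_for_clm(
    protein: str,
    smiles: str,
    tokenizer: BpeTokenizer,
    max_length: int | None = None,
) -> ClmEncoding:
    """Encode a pair (or a generation prompt) for the language model.

    Full example layout: ``<bos> protein-tokens <space> smiles-tokens <eos>``
    padded/truncated to ``max_length``. With an empty ``smiles`` the
    *unpadded* generation prompt ``<bos> protein-tokens <space>`` is
    returned instead.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    if max_length is None:
        max_length = tokenizer.max_length
    ids = [tokenizer.bos_id] + tokenizer.encode(protein) + [tokenizer.space_id]
    if not smiles:
        return ClmEncoding(ids=tuple(ids), truncated=False, is_prompt=True)
    ids += tokenizer.encode(smiles) + [tokenizer.eos_id]
    truncated = len(ids) > max_length
    if truncated:
        ids = ids[:max_length]
    else:
        ids = ids + [tokenizer.pad_id] * (max_length - len(ids))
    return ClmEncoding(ids=tuple(ids), truncated=truncated, is_prompt=False)


@dataclass(frozen=True)
class CharVocab:
    """Character-to-integer map for the regression network; 0 is the pad."""

    char_to_id: dict[str, int] = field(default_factory=dict)
    pad_id: int = 0
    max_length: int = RCNN_INPUT_LENGTH

    @property
    def size(self) -> int:
        """Number of ids including the pad (embedding-table size)."""
        return len(self.char_to_id) + 1

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"char_to_id": self.char_to_id, "max_length": self.max_length})
        )

    @classmethod
    def load(cls, path: str | Path) -> "CharVocab":
        blob = json.loads(Path(path).read_text())
        return cls(char_to_id=blob["char_to_id"], max_length=blob["max_length"])


_MAX_CHARS = 70  # ids 1..70; 0 reserved for the pad


def build_char_vocab(ds: AffinityDataset) -> CharVocab:
    """Assign ids 1..K to the distinct characters of a dataset, first-seen order.

    Characters are collected protein-then-SMILES per pair, in dataset order.

    Raises
    ------
    ValueError
        On an empty dataset.
    OverflowError
        If the dataset holds more than 70 distinct characters (the surplus
        characters are named in the message).
    """
    if len(ds) == 0:
        raise ValueError("cannot build a vocabulary from an empty dataset")
    char_to_id: dict[str, int] = {}
    surplus: list[str] = []
    for pair in ds:
        for c in pair.protein_seq + pair.smiles:
            if c in char_to_id or c in surplus:
                continue
            if len(char_to_id) >= _MAX_CHARS:
                surplus.append(c)
            else:
                char_to_id[c] = len(char_to_id) + 1
    if surplus:
        raise OverflowError(
            f"more than {_MAX_CHARS} distinct characters; surplus: {surplus!r}"
        )
    return CharVocab(char_to_id=char_to_id)


def encode_for_rcnn(
    pair: LigandProteinPair,
    vocab: CharVocab,
    max_length: int | None = None,
) -> list[int]:
    """Character-encode protein+SMILES (no separator) to a fixed-length row.

    Unknown characters map to the pad id; the row is post-padded with 0 (or
    truncated) to exactly ``max_length`` (default 800).
    """
    if max_length is None:
        max_length = vocab.max_length
    text = pair.protein_seq + pair.smiles
    ids = [vocab.char_to_id.get(c, vocab.pad_id) for c in text[:max_length]]
    ids.extend([vocab.pad_id] * (max_length - len(ids)))
    return ids
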