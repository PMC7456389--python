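"""Character-level labeled corpora for treatment-entity normalization.

A clinical sentence is modeled as a sequence of unicode characters, each
carrying two aligned labels: a recognition (TER) tag marking mention
boundaries (BIO over characters) and a normalization (TEN) label that is
either ``"O"`` or the canonical name of the chemotherapy regimen the
enclosing mention denotes.  Corpora are serialized in a CoNLL-style TSV
dialect, one character per line.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Hard cap on sentence length; longer sentences are truncated with a warning.
MAX_SENTENCE_LEN = 256

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

#: The outside label / tag shared by TEN and TER.
OUTSIDE = "O"

#: Default recognition tag set: BIO over characters.  ``O`` must sit at
#: index 0 so the all-zero model decodes to "outside" everywhere.
TER_TAGS_BIO = (OUTSIDE, "B", "I")
#: Reduced tag set for configurations that do not mark mention starts.
TER_TAGS_IO = (OUTSIDE, "I")


class CorpusError(ValueError):
    """Base error for corpus construction and I/O."""


class ParseError(CorpusError):
    """Malformed corpus file; carries the offending line number."""


class VocabularyError(CorpusError):
    """A label or regimen name outside the controlled vocabulary."""


@dataclass(frozen=True)
class RegimenVocabulary:
    """Controlled vocabulary of canonical regimen names plus ``"O"``.

    The label set the CRF ranges over is ``("O", r_1, ..., r_j)``; ``"O"``
    is pinned at index 0.
    """

    regimens: tuple[str, ...]

    def __post_init__(self) -> None:
        regs = tuple(self.regimens)
        object.__setattr__(self, "regimens", regs)
        if len(set(regs)) != len(regs):
            raise VocabularyError("duplicate regimen names")
        for r in regs:
            if not r or not r.strip():
                raise VocabularyError("empty or whitespace-only regimen name")
            if r == OUTSIDE:
                raise VocabularyError('"O" is reserved for the outside label')

    @property
    def labels(self) -> tuple[str, ...]:
        return (OUTSIDE,) + self.regimens

    @property
    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    @property
    def o_index(self) -> int:
        return 0

    @property
    def n_labels(self) -> int:
        """|C| + 1: regimens plus the outside label."""
        return len(self.regimens) + 1

    def encode(self, label: str) -> int:
        try:
            return self.label_index[label]
        except KeyError:
            raise VocabularyError(f"unknown TEN label: {label!r}") from None

    def decode(self, index: int) -> str:
        return self.labels[index]

    def __contains__(self, name: str) -> bool:
        return name in self.label_index

    def __len__(self) -> int:
        return self.n_labels

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(list(self.regimens), ensure_ascii=False, indent=0) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RegimenVocabulary":
        names = json.loads(Path(path).read_text(encoding="utf-8"))
        if not isinstance(names, list):
            raise VocabularyError("regimen vocabulary file must be a JSON array of names")
        return cls(tuple(names))


@dataclass(frozen=True)
class LabeledSentence:
    """One sentence as aligned (character, TER tag, TEN label) triples."""

    chars: tuple[str, ...]
    ter_tags: tuple[str, ...]
    ten_labels: tuple[str, ...]
    sentence_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chars", tuple(self.chars))
        object.__setattr__(self, "ter_tags", tuple(self.ter_tags))
        object.__setattr__(self, "ten_labels", tuple(self.ten_labels))
        n = len(self.chars)
        if not (len(self.ter_tags) == len(self.ten_labels) == n):
            raise CorpusError(
                f"misaligned sentence {self.sentence_id!r}: "
                f"{n} chars, {len(self.ter_tags)} tags, {len(self.ten_labels)} labels"
            )
        if n < 1 or n > MAX_SENTENCE_LEN:
            raise CorpusError(
                f"sentence {self.sentence_id!r} has length {n}, outside [1, {MAX_SENTENCE_LEN}]"
            )
        for c in self.chars:
            if len(c) != 1:
                raise CorpusError(f"not a single character: {c!r}")

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)

    def validate_labels(self, vocab: RegimenVocabulary, ter_tags: Sequence[str] = TER_TAGS_BIO) -> None:
        tagset = set(ter_tags)
        for lab in self.ten_labels:
            if lab not in vocab:
                raise VocabularyError(
                    f"sentence {self.sentence_id!r}: unknown TEN label {lab!r}"
                )
        for tag in self.ter_tags:
            if tag not in tagset:
                raise VocabularyError(
                    f"sentence {self.sentence_id!r}: unknown TER tag {tag!r}"
                )


@dataclass
class Corpus:
    """A list of labeled sentences belonging to one split."""

    sentences: list[LabeledSentence] = field(default_factory=list)
    split_tag: str = "train"

    def __post_init__(self) -> None:
        ids = [s.sentence_id for s in self.sentences if s.sentence_id]
        if len(set(ids)) != len(ids):
            raise CorpusError("duplicate sentence_ids within corpus")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __eq__(self, other) -> bool:
        return isinstance(other, Corpus) and self.sentences == other.sentences


_META_RE = re.compile(r"#\s*sentence_id=([^,\s]*)\s*,\s*patient_id=(\S*)")


def read_corpus_tsv(
    path: str | Path,
    vocab: RegimenVocabulary,
    ter_tags: Sequence[str] = TER_TAGS_BIO,
    split_tag: str = "train",
) -> Corpus:
    """Read a character-per-line TSV corpus.

    Each non-blank data line holds ``char<TAB>ter_tag<TAB>ten_label``; a
    blank line terminates a sentence.  A tab-free ``#`` line immediately
    before a sentence may carry ``sentence_id=..., patient_id=...``.
    Sentences longer than :data:`MAX_SENTENCE_LEN` are truncated with a
    warning.  An empty file yields an empty corpus.
    """
    path = Path(path)
    sentences: list[LabeledSentence] = []
    chars: list[str] = []
    tags: list[str] = []
    labels: list[str] = []
    sid = pid = ""
    n_auto = 0

    def flush() -> None:
        nonlocal chars, tags, labels, sid, pid, n_auto
        if not chars:
            sid = pid = ""
            return
        if len(chars) > MAX_SENTENCE_LEN:
            warnings.warn(
                f"{path.name}: sentence {sid or n_auto} has {len(chars)} characters; "
                f"truncated to {MAX_SENTENCE_LEN}",
                stacklevel=3,
            )
            del chars[MAX_SENTENCE_LEN:], tags[MAX_SENTENCE_LEN:], labels[MAX_SENTENCE_LEN:]
        sent = LabeledSentence(tuple(chars), tuple(tags), tuple(labels), sid, pid)
        sent.validate_labels(vocab, ter_tags)
        sentences.append(sent)
        n_auto += 1
        chars, tags, labels = [], [], []
        sid = pid = ""

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip("\r"):
                flush()
                continue
            if line.startswith("#") and "\t" not in line:
                m = _META_RE.search(line)
                if m:
                    sid, pid = m.group(1), m.group(2)
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            ch, tag, lab = fields
            if len(ch) != 1:
                raise ParseError(f"{path.name}:{lineno}: first field must be one character, got {ch!r}")
            chars.append(ch)
            tags.append(tag)
            labels.append(lab)
    flush()
    return Corpus(sentences, split_tag=split_tag)


def write_corpus_tsv(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus in the TSV dialect of :func:`read_corpus_tsv`.

    Round-trip safe: reading the written file reproduces the corpus.
    """
    path = Path(path)
    lines: list[str] = []
    for i, sent in enumerate(corpus.sentences):
        if i:
            lines.append("")
        if sent.sentence_id or sent.patient_id:
            lines.append(f"# sentence_id={sent.sentence_id}, patient_id={sent.patient_id}")
        for ch, tag, lab in zip(sent.chars, sent.ter_tags, sent.ten_labels):
            if ch in ("\t", "\n", "\r"):
                raise CorpusError(f"character {ch!r} cannot be serialized in the TSV dialect")
            lines.append(f"{ch}\t{tag}\t{lab}")
    text = "\n".join(lines)
    path.write_text(text + ("\n" if text else ""), encoding="utf-8")
    return path


@dataclass(frozen=True)
class CharVocab:
    """Character→index bijection with reserved PAD=0 and UNK=1 rows.

    Index order follows first appearance in the corpus, which makes the
    vocabulary deterministic for a fixed corpus and ``min_count``.
    """

    char_index: dict[str, int]
    min_count: int = 1

    @property
    def size(self) -> int:
        return len(self.char_index) + 2

    def encode(self, ch: str) -> int:
        return self.char_index.get(ch, UNK_INDEX)

    def __contains__(self, ch: str) -> bool:
        return ch in self.char_index

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"min_count": self.min_count, "chars": list(self.char_index)}
        path.write_text(json.dumps(payload, ensure_ascii=False), encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "CharVocab":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        chars = payload["chars"]
        return cls({c: i + 2 for i, c in enumerate(chars)}, min_count=payload["min_count"])


def build_char_vocab(corpus: Corpus, min_count: int = 1) -> CharVocab:
    """Index every character with corpus frequency >= ``min_count``.

    Characters below the threshold map to UNK at encode time.  An empty
    corpus yields a vocabulary containing only PAD and UNK.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for sent in corpus:
        for ch in sent.chars:
            counts[ch] = counts.get(ch, 0) + 1
    index: dict[str, int] = {}
    nxt = 2  # 0 = PAD, 1 = UNK
    for ch, n in counts.items():  # insertion order == first appearance
        if n >= min_count:
            index[ch] = nxt
            nxt += 1
    return CharVocab(index, min_count=min_count)


def encode_batch(
    sentences: Sequence[LabeledSentence],
    char_vocab: CharVocab,
    vocab: RegimenVocabulary,
    max_len: int = MAX_SENTENCE_LEN,
    ter_tags: Sequence[str] = TER_TAGS_BIO,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode sentences to dense index/mask matrices of shape (batch, max_len).

    Returns ``(char_idx, mask, ten_idx, ter_idx)``.  Positions beyond a
    sentence's length carry PAD / mask 0; characters unknown to the
    vocabulary get UNK; sentences longer than ``max_len`` are truncated
    with a warning.
    """
    if not sentences:
        raise ValueError("encode_batch requires at least one sentence")
    tag_index = {t: i for i, t in enumerate(ter_tags)}
    B = len(sentences)
    idx = np.zeros((B, max_len), dtype=np.int64)
    mask = np.zeros((B, max_len), dtype=np.float32)
    ten = np.zeros((B, max_len), dtype=np.int64)
    ter = np.zeros((B, max_len), dtype=np.int64)
    for b, sent in enumerate(sentences):
        n = len(sent)
        if n > max_len:
            warnings.warn(
                f"sentence {sent.sentence_id!r} has {n} characters; truncated to {max_len}",
                stacklevel=2,
            )
            n = max_len
        for i in range(n):
            idx[b, i] = char_vocab.encode(sent.chars[i])
            ten[b, i] = vocab.encode(sent.ten_labels[i])
            ter[b, i] = tag_index[sent.ter_tags[i]]
        mask[b, :n] = 1.0
    return idx, mask, ten, ter
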