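"""Text cleaning, hashtag separation, dictionary building and encoding.

The processing pipeline mirrors how hashtag-driven platforms mix running
text and ``#``-tagged keywords inside one caption:

1. collection-stage duplicates are dropped (see :mod:`dealerscan.corpus_io`);
2. captions are lowercased, hyperlinks and special characters (emoji,
   punctuation) are removed, stop words are filtered, while ``#`` is kept
   as a token-leading marker;
3. a dictionary maps each distinct word to a positive integer index;
4. each caption is split into a text part and a hashtag part, each encoded
   to a fixed-length index vector (truncate long, zero-pad short);
5. three dataset variants are materialized for the ablation: text with
   hashtags, hashtags only, and text without hashtags, each deduplicated
   by its restricted token representation.

Index 0 is reserved for padding; tokens unseen at dictionary-build time map
to the reserved unknown index ``size + 1``.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import LabeledPost, RawPost

__all__ = [
    "CleanPost",
    "Vocabulary",
    "EncodedExample",
    "DatasetVariant",
    "VARIANT_NAMES",
    "load_stopwords",
    "clean_text",
    "split_text_hashtags",
    "clean_posts",
    "build_vocabulary",
    "encode",
    "make_variants",
]

VARIANT_NAMES = ("text_with_hashtags", "hashtags_only", "text_without_hashtags")

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_NON_ALLOWED_RE = re.compile(r"[^a-z0-9#\s]+")


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load the stop-word list (shipped standard English list by default)."""
    if path is None:
        text = (
            resources.files("dealerscan.data").joinpath("stopwords_en.txt").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def clean_text(
    caption: str, stopwords: frozenset[str] | set[str] | None = None
) -> list[str]:
    """Clean one caption into an ordered token sequence.

    Lowercases, strips hyperlinks, deletes every character outside
    ``[a-z0-9#]`` and whitespace (a whitelist, so behavior is stable across
    unicode versions), splits on whitespace, and removes stop words. ``#``
    survives only as a token-leading hashtag marker: a space is inserted
    before each ``#`` so run-together tags like ``#xanax#oxy`` separate,
    and a bare ``#`` is dropped.
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    text = caption.lower()
    text = _URL_RE.sub(" ", text)
    text = text.replace("#", " #")
    text = _NON_ALLOWED_RE.sub("", text)
    tokens: list[str] = []
    for tok in text.split():
        if tok.startswith("#"):
            body = tok.lstrip("#")
            if body:
                tokens.append("#" + body)
        elif tok not in stopwords:
            tokens.append(tok)
    return tokens


_STOPWORDS_CACHE: frozenset[str] | None = None


def _default_stopwords() -> frozenset[str]:
    global _STOPWORDS_CACHE
    if _STOPWORDS_CACHE is None:
        _STOPWORDS_CACHE = load_stopwords()
    return _STOPWORDS_CACHE


def split_text_hashtags(tokens: Sequence[str]) -> tuple[list[str], list[str]]:
    """Partition cleaned tokens into (text part, hashtag part).

    ``#``-prefixed tokens go to the hashtag part with the marker stripped
    for dictionary lookup; both parts preserve the original relative order,
    and the two parts together account for every input token exactly once.
    """
    text_part: list[str] = []
    hashtag_part: list[str] = []
    for tok in tokens:
        if tok.startswith("#"):
            hashtag_part.append(tok.lstrip("#"))
        else:
            text_part.append(tok)
    return text_part, hashtag_part


@dataclass(frozen=True)
class CleanPost:
    """A post after cleaning and text/hashtag separation.

    ``hashtag_tokens`` are stored in lookup form (leading ``#`` stripped);
    the display form is recovered by prefixing ``#``.
    """

    post_id: str
    text_tokens: tuple[str, ...]
    hashtag_tokens: tuple[str, ...]
    label: int | None = None

    @property
    def all_tokens(self) -> tuple[str, ...]:
        return self.text_tokens + self.hashtag_tokens


def clean_posts(
    posts: Iterable[RawPost | LabeledPost],
    stopwords: frozenset[str] | None = None,
    labels: Mapping[str, int] | None = None,
) -> list[CleanPost]:
    """Clean a corpus. Labels come from :class:`LabeledPost` wrappers or a
    ``post_id -> label`` mapping."""
    if stopwords is None:
        stopwords = _default_stopwords()
    out: list[CleanPost] = []
    for item in posts:
        if isinstance(item, LabeledPost):
            post, label = item.post, item.label
        else:
            post = item
            label = labels.get(item.post_id) if labels is not None else None
        tokens = clean_text(post.caption, stopwords)
        text_part, hashtag_part = split_text_hashtags(tokens)
        out.append(
            CleanPost(
                post_id=post.post_id,
                text_tokens=tuple(text_part),
                hashtag_tokens=tuple(hashtag_part),
                label=label,
            )
        )
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Corpus-derived dictionary: token -> index in ``1..size``.

    Index 0 is the padding value and is never assigned to a token; the
    unknown-token index is ``size + 1``, so an embedding table over this
    vocabulary needs ``size + 2`` rows.
    """

    word_to_index: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.word_to_index)

    @property
    def unknown_index(self) -> int:
        return self.size + 1

    def index(self, token: str) -> int:
        return self.word_to_index.get(token, self.unknown_index)

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["token", "index"])
            for token, idx in self.word_to_index.items():
                writer.writerow([token, idx])

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                mapping[row["token"]] = int(row["index"])
        return cls(mapping)


def build_vocabulary(corpus: Sequence[CleanPost]) -> Vocabulary:
    """Build the dictionary over all text and hashtag tokens.

    Indices are assigned in first-occurrence order (text part before
    hashtag part within a post), starting at 1, so rebuilding on the same
    corpus is deterministic.
    """
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    mapping: dict[str, int] = {}
    for post in corpus:
        for token in post.all_tokens:
            if token not in mapping:
                mapping[token] = len(mapping) + 1
    return Vocabulary(mapping)


def encode(tokens: Sequence[str], vocab: Vocabulary, length: int) -> np.ndarray:
    """Encode tokens to a fixed-length index vector.

    Keeps the first ``length`` tokens when the sequence is longer and
    zero-fills the remainder when shorter.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    vec = np.zeros(length, dtype=np.int64)
    for i, tok in enumerate(tokens[:length]):
        vec[i] = vocab.index(tok)
    return vec


@dataclass(frozen=True)
class EncodedExample:
    """Fixed-length index vectors for the text and hashtag parts plus label."""

    text_indices: np.ndarray
    hashtag_indices: np.ndarray
    label: int


@dataclass
class DatasetVariant:
    """One arm of the text/hashtag ablation.

    ``records`` keep the (restricted) token form so models that need
    untruncated features, or per-fold re-encoding with a training-only
    vocabulary, can rebuild their inputs; ``examples`` are the fixed-length
    encodings under the vocabulary passed to :func:`make_variants`.
    """

    name: str
    records: list[CleanPost]
    examples: list[EncodedExample] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def post_ids(self) -> list[str]:
        return [r.post_id for r in self.records]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stacked (X_text, X_hash, y) arrays over ``examples``."""
        x_text = np.stack([e.text_indices for e in self.examples])
        x_hash = np.stack([e.hashtag_indices for e in self.examples])
        y = np.array([e.label for e in self.examples], dtype=np.int64)
        return x_text, x_hash, y


def _restrict(post: CleanPost, name: str) -> CleanPost:
    if name == "text_with_hashtags":
        return post
    if name == "hashtags_only":
        return CleanPost(post.post_id, (), post.hashtag_tokens, post.label)
    if name == "text_without_hashtags":
        return CleanPost(post.post_id, post.text_tokens, (), post.label)
    raise ValueError(f"unknown variant {name!r}")


def make_variants(
    corpus: Sequence[CleanPost],
    vocab: Vocabulary,
    l_text: int = 50,
    l_hash: int = 15,
) -> dict[str, DatasetVariant]:
    """Materialize the three ablation variants from a cleaned corpus.

    Each variant keeps only posts with content under its restriction
    (hashtags-only drops posts with no hashtags; text-without-hashtags
    drops posts with no remaining words; the combined variant drops posts
    that cleaned to nothing), then deduplicates by the restricted cleaned
    token representation, keeping first occurrences.
    """
    variants: dict[str, DatasetVariant] = {}
    for name in VARIANT_NAMES:
        seen: set[tuple[str, ...]] = set()
        records: list[CleanPost] = []
        for post in corpus:
            restricted = _restrict(post, name)
            key = restricted.all_tokens
            if len(key) == 0 or key in seen:
                continue
            seen.add(key)
            records.append(restricted)
        examples = [
            EncodedExample(
                text_indices=encode(r.text_tokens, vocab, l_text),
                hashtag_indices=encode(r.hashtag_tokens, vocab, l_hash),
                label=0 if r.label is None else r.label,
            )
            for r in records
        ]
        variants[name] = DatasetVariant(name=name, records=records, examples=examples)
    return variants


def save_clean_corpus(corpus: Sequence[CleanPost], path: str | Path) -> None:
    """Cache a cleaned corpus as JSON Lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for post in corpus:
            fh.write(
                json.dumps(
                    {
                        "post_id": post.post_id,
                        "text_tokens": list(post.text_tokens),
                        "hashtag_tokens": list(post.hashtag_tokens),
                        "label": post.label,
                    }
                )
            )
            fh.write("\n")


def load_clean_corpus(path: str | Path) -> list[CleanPost]:
    out: list[CleanPost] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                CleanPost(
                    post_id=rec["post_id"],
                    text_tokens=tuple(rec["text_tokens"]),
                    hashtag_tokens=tuple(rec["hashtag_tokens"]),
                    label=rec["label"],
                )
            )
    return out
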