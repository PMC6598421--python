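"""Reading, writing, validating and deduplicating post corpora.

A corpus is a JSON Lines file, one post per line, with keys ``post_id``,
``user_id``, ``timestamp`` (ISO-8601, UTC), ``caption``, ``comments``
(array of ``{"user_id": ..., "text": ...}``) and ``image_refs`` (array of
strings). Labels travel separately as a two-column CSV ``post_id,label``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "RawPost",
    "LabeledPost",
    "Comment",
    "read_posts",
    "write_posts",
    "dedup_posts",
    "read_labels",
    "write_labels",
]


@dataclass(frozen=True)
class Comment:
    user_id: str
    text: str


@dataclass(frozen=True)
class RawPost:
    """One scraped record: caption with inline hashtags, comments, metadata."""

    post_id: str
    user_id: str
    timestamp: datetime
    caption: str
    comments: tuple[Comment, ...] = ()
    image_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.post_id:
            raise ValueError("post_id must be non-empty")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc)
            )
        else:
            object.__setattr__(
                self, "timestamp", self.timestamp.astimezone(timezone.utc)
            )


@dataclass(frozen=True)
class LabeledPost:
    """A post with its binary annotation (1 = drug-dealer post, 0 = not related)."""

    post: RawPost
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


class CorpusFormatError(ValueError):
    """A corpus file violates the JSON Lines contract."""


def _post_from_record(rec: dict, lineno: int) -> RawPost:
    for key in ("post_id", "user_id", "timestamp", "caption"):
        if key not in rec:
            raise CorpusFormatError(f"line {lineno}: missing required key {key!r}")
    try:
        ts = datetime.fromisoformat(str(rec["timestamp"]))
    except ValueError as exc:
        raise CorpusFormatError(f"line {lineno}: bad timestamp: {exc}") from exc
    comments = tuple(
        Comment(user_id=str(c["user_id"]), text=str(c["text"]))
        for c in rec.get("comments", [])
    )
    return RawPost(
        post_id=str(rec["post_id"]),
        user_id=str(rec["user_id"]),
        timestamp=ts,
        caption=str(rec["caption"]),
        comments=comments,
        image_refs=tuple(str(r) for r in rec.get("image_refs", [])),
    )


def read_posts(path: str | Path, format: Literal["jsonl"] = "jsonl") -> list[RawPost]:
    """Read a JSON Lines corpus, preserving file order.

    Raises :class:`CorpusFormatError` naming the offending line on any
    malformed record.
    """
    if format != "jsonl":
        raise ValueError(f"unsupported corpus format {format!r}")
    posts: list[RawPost] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            if not isinstance(rec, dict):
                raise CorpusFormatError(f"line {lineno}: record is not an object")
            try:
                posts.append(_post_from_record(rec, lineno))
            except ValueError as exc:
                if isinstance(exc, CorpusFormatError):
                    raise
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    return posts


def _post_to_record(post: RawPost) -> dict:
    return {
        "post_id": post.post_id,
        "user_id": post.user_id,
        "timestamp": post.timestamp.isoformat(),
        "caption": post.caption,
        "comments": [{"user_id": c.user_id, "text": c.text} for c in post.comments],
        "image_refs": list(post.image_refs),
    }


def write_posts(posts: Iterable[RawPost], path: str | Path) -> None:
    """Write posts as JSON Lines; :func:`read_posts` inverts it exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(_post_to_record(post), ensure_ascii=False))
            fh.write("\n")


def dedup_posts(
    posts: Sequence[RawPost],
    key: Literal["post_id", "caption_text"] = "post_id",
) -> list[RawPost]:
    """Drop later duplicates by the chosen key, keeping first occurrences.

    ``post_id`` is the collection-stage identity (the same post surfaces
    under several hashtag searches); ``caption_text`` is the
    processing-stage identity (distinct posts sharing one caption collapse
    to one training example). Order-preserving and idempotent.
    """
    if key not in ("post_id", "caption_text"):
        raise ValueError(f"unknown dedup key {key!r}")
    seen: set[str] = set()
    out: list[RawPost] = []
    for post in posts:
        k = post.post_id if key == "post_id" else post.caption
        if k not in seen:
            seen.add(k)
            out.append(post)
    return out


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a ``post_id,label`` CSV into a mapping."""
    labels: dict[str, int] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) != {"post_id", "label"}:
            raise CorpusFormatError(
                f"label file must have header 'post_id,label', got {reader.fieldnames}"
            )
        for row in reader:
            value = int(row["label"])
            if value not in (0, 1):
                raise CorpusFormatError(
                    f"label for post {row['post_id']!r} must be 0 or 1, got {value}"
                )
            labels[row["post_id"]] = value
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["post_id", "label"])
        for post_id, label in labels.items():
            writer.writerow([post_id, label])
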