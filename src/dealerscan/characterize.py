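"""Post-hoc characterization of detected dealer posts.

Three analyses run over the posts a classifier flagged:

* **drug hashtag taxonomy** — per-hashtag post counts and per-drug totals
  with union semantics: a drug's total is the number of *distinct* posts
  carrying at least one of its hashtag variants, so the total is at most
  (and usually below) the sum of the per-hashtag counts;
* **contact channels** — regex extraction of email addresses, phone
  numbers (at least 7 digits, so dosages like "2mg" never match) and
  messaging-app handles (Wickr, Telegram, Kik, WhatsApp) from captions
  and comments;
* **buyer-seller exchanges** — a dealer-labeled post advertising a
  contact channel together with a comment from a *different* user asking
  about price or offering to buy.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_io import RawPost
from .preprocess import CleanPost, clean_posts
from .synthetic import GroundTruthRecord

__all__ = [
    "HashtagLexicon",
    "DrugCountRow",
    "ContactRecord",
    "CharacterizationReport",
    "load_lexicon",
    "load_buy_phrases",
    "count_drug_hashtags",
    "extract_contacts",
    "detect_transactions",
    "summarize_detected",
    "score_contact_extraction",
]

_APP_NAMES = ("wickr", "telegram", "kik", "whatsapp")

_EMAIL_RE = re.compile(r"\b[a-z0-9._%+-]+@[a-z0-9.-]+\.[a-z]{2,}\b", re.IGNORECASE)
_PHONE_CANDIDATE_RE = re.compile(r"\+?\d[\d\s().\-]*\d")
_APP_RES = {
    app: re.compile(
        rf"\b{app}\b(?:\s+me)?\s*[:\-]?\s*(@?[a-z0-9_.+]{{3,}}|\+?[\d\s().\-]{{7,}})",
        re.IGNORECASE,
    )
    for app in _APP_NAMES
}
_HANDLE_TOKEN_RE = re.compile(r"^@?[a-z0-9_.]{4,}$", re.IGNORECASE)
_BUY_QUESTION_RE = re.compile(
    r"(how\s+much|price|cost|\border\b[^.!?]*\?|\bbuy\b[^.!?]*\?)", re.IGNORECASE
)


@dataclass(frozen=True)
class HashtagLexicon:
    """Drug name -> {hashtag variant -> category}, plus sale keywords.

    Categories: ``drug_name``, ``codeword_misspelling``,
    ``codeword_extended``, ``codeword_street``; sale keywords are tagged
    ``sale_or_shipping``. All entries lowercase without ``#``.
    """

    drugs: dict[str, dict[str, str]]
    sale_keywords: frozenset[str] = frozenset()

    def variants(self, drug: str) -> list[str]:
        return list(self.drugs[drug])


def load_lexicon(path: str | Path | None = None) -> HashtagLexicon:
    """Load a ``drug,hashtag,category`` CSV (shipped default lexicon)."""
    if path is None:
        text = resources.files("dealerscan.data").joinpath("drug_lexicon.csv").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    drugs: dict[str, dict[str, str]] = {}
    sale: set[str] = set()
    for row in csv.DictReader(text.splitlines()):
        tag = row["hashtag"].lower().lstrip("#")
        if row["category"] == "sale_or_shipping":
            sale.add(tag)
        else:
            drugs.setdefault(row["drug"], {})[tag] = row["category"]
    return HashtagLexicon(drugs=drugs, sale_keywords=frozenset(sale))


def load_buy_phrases(path: str | Path | None = None) -> tuple[str, ...]:
    if path is None:
        text = resources.files("dealerscan.data").joinpath("buy_phrases.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return tuple(line.strip().lower() for line in text.splitlines() if line.strip())


@dataclass(frozen=True)
class DrugCountRow:
    """Per-hashtag post counts and the distinct-post (union) total for one drug."""

    drug: str
    per_hashtag: dict[str, int]
    total: int


def count_drug_hashtags(
    posts: Sequence[CleanPost], lexicon: HashtagLexicon
) -> list[DrugCountRow]:
    """Count posts per hashtag variant and per drug.

    The per-drug total is the size of the union of the post sets matched
    by any variant of that drug — a post carrying both ``#xanax`` and
    ``#2mgxanax`` counts once in the Xanax total. A post may contribute to
    several drugs.
    """
    rows: list[DrugCountRow] = []
    for drug in lexicon.drugs:
        per_hashtag = {tag: 0 for tag in lexicon.drugs[drug]}
        matched: set[str] = set()
        for post in posts:
            tags = set(post.hashtag_tokens)
            for tag in per_hashtag:
                if tag in tags:
                    per_hashtag[tag] += 1
                    matched.add(post.post_id)
        rows.append(DrugCountRow(drug=drug, per_hashtag=per_hashtag, total=len(matched)))
    return rows


@dataclass(frozen=True)
class ContactRecord:
    """Contact channels found in one post; every channel has a matched span."""

    post_id: str
    channels: frozenset[str]  # "email", "phone", "app:<name>"
    raw_matches: tuple[tuple[str, str], ...] = ()  # (channel, matched text)


def _scan_text(text: str) -> list[tuple[str, str]]:
    found: list[tuple[str, str]] = []
    for m in _EMAIL_RE.finditer(text):
        found.append(("email", m.group(0)))
    emails = {m.group(0) for m in _EMAIL_RE.finditer(text)}
    for m in _PHONE_CANDIDATE_RE.finditer(text):
        digits = re.sub(r"\D", "", m.group(0))
        if 7 <= len(digits) <= 15 and not any(m.group(0) in e for e in emails):
            found.append(("phone", m.group(0)))
    lowered = text.lower()
    tokens = lowered.split()
    for app, pattern in _APP_RES.items():
        m = pattern.search(text)
        if m:
            found.append((f"app:{app}", m.group(0)))
            continue
        # fallback: app name within 3 tokens of a handle-like token
        for i, tok in enumerate(tokens):
            if tok.strip(".,:;!?") == app:
                window = tokens[max(0, i - 3) : i + 4]
                if any(_HANDLE_TOKEN_RE.match(w) and w.strip(".,:;!?") != app for w in window):
                    found.append((f"app:{app}", " ".join(window)))
                    break
    return found


def extract_contacts(post: RawPost) -> ContactRecord:
    """Detect contact channels in a post's caption and comments."""
    matches: list[tuple[str, str]] = _scan_text(post.caption)
    for comment in post.comments:
        matches.extend(_scan_text(comment.text))
    return ContactRecord(
        post_id=post.post_id,
        channels=frozenset(ch for ch, _ in matches),
        raw_matches=tuple(matches),
    )


def detect_transactions(
    post: RawPost,
    dealer_label: int,
    buy_phrases: Sequence[str] | None = None,
    contacts: ContactRecord | None = None,
) -> bool:
    """True iff a dealer-labeled post with a contact channel drew a
    buy-intent comment from a different user."""
    if dealer_label != 1:
        return False
    if contacts is None:
        contacts = extract_contacts(post)
    if not contacts.channels:
        return False
    if buy_phrases is None:
        buy_phrases = load_buy_phrases()
    for comment in post.comments:
        if comment.user_id == post.user_id:
            continue
        text = comment.text.lower()
        if any(phrase in text for phrase in buy_phrases) or _BUY_QUESTION_RE.search(text):
            return True
    return False


@dataclass
class CharacterizationReport:
    """Summary of the predicted-positive posts."""

    n_detected: int
    drug_rows: list[DrugCountRow]
    drug_percentages: dict[str, float]
    contact_channel_counts: dict[str, int]
    n_with_contact: int
    transaction_count: int
    unique_users: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for row in self.drug_rows:
            for tag, count in row.per_hashtag.items():
                rows.append({"drug": row.drug, "hashtag": "#" + tag, "posts": count})
            rows.append({"drug": row.drug, "hashtag": "total", "posts": row.total})
        return pd.DataFrame(rows)

    def text_summary(self) -> str:
        lines = [f"detected posts: {self.n_detected}",
                 f"unique users: {self.unique_users}"]
        for row in self.drug_rows:
            pct = self.drug_percentages[row.drug]
            lines.append(f"  {row.drug}: {row.total} posts ({pct:.1f}% of detected)")
        lines.append(f"posts with contact info: {self.n_with_contact}")
        for channel, count in sorted(self.contact_channel_counts.items()):
            lines.append(f"  {channel}: {count}")
        lines.append(f"buyer-seller exchanges: {self.transaction_count}")
        return "\n".join(lines)


def summarize_detected(
    posts: Sequence[RawPost],
    predictions: Mapping[str, int],
    lexicon: HashtagLexicon | None = None,
    buy_phrases: Sequence[str] | None = None,
) -> CharacterizationReport:
    """Characterize the predicted-positive subset of a corpus.

    ``predictions`` maps post_id to the predicted binary label; posts
    without a prediction are treated as negative.
    """
    lexicon = lexicon or load_lexicon()
    buy_phrases = buy_phrases or load_buy_phrases()
    detected = [p for p in posts if predictions.get(p.post_id, 0) == 1]
    clean = clean_posts(detected)
    drug_rows = count_drug_hashtags(clean, lexicon)
    n = len(detected)
    drug_pct = {
        row.drug: (100.0 * row.total / n if n else 0.0) for row in drug_rows
    }
    channel_counts: Counter[str] = Counter()
    n_with_contact = 0
    transaction_count = 0
    for post in detected:
        record = extract_contacts(post)
        if record.channels:
            n_with_contact += 1
            channel_counts.update(record.channels)
        if detect_transactions(post, 1, buy_phrases=buy_phrases, contacts=record):
            transaction_count += 1
    return CharacterizationReport(
        n_detected=n,
        drug_rows=drug_rows,
        drug_percentages=drug_pct,
        contact_channel_counts=dict(channel_counts),
        n_with_contact=n_with_contact,
        transaction_count=transaction_count,
        unique_users=len({p.user_id for p in detected}),
    )


def score_contact_extraction(
    posts: Sequence[RawPost], truth: Sequence[GroundTruthRecord]
) -> tuple[float, float]:
    """Per-post precision and recall of contact extraction against planted
    ground truth, matching on the base channel kind (email/phone/app)."""
    truth_by_id = {t.post_id: t for t in truth}
    tp = fp = fn = 0
    for post in posts:
        planted = truth_by_id[post.post_id].planted_contact
        extracted = extract_contacts(post).channels
        extracted_kinds = {ch.split(":")[0] for ch in extracted}
        if planted is None:
            if extracted:
                fp += 1
        else:
            if planted.split(":")[0] in extracted_kinds:
                tp += 1
            else:
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall
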