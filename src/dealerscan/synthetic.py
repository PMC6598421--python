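"""Synthetic labeled corpora with the structure of hashtag-driven drug-market posts.

The generator emulates the two post populations a classifier must
separate on an image/text platform:

* **dealer posts** — a drug mention and stock line, a sale-promotion
  phrase, contact information (email, phone, or a messaging-app handle,
  present with probability ``contact_prob``), and drug hashtags including
  deliberate misspellings ("zanax", "oxicotin") and extended codewords
  ("2mgxanax", "mdmaforsale");
* **background posts** — ordinary topical chatter; a configurable
  fraction are *hard negatives* that reuse drug hashtags (or mention a
  drug in an awareness context) without any dealer syntax.

Dealer prevalence defaults to 9.6%, matching the roughly one-in-ten rate
reported for manually annotated corpora of this kind. Generation is a pure
function of the seed; every post comes with a ground-truth record of what
was planted so extraction and detection stages can be scored exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import Comment, LabeledPost, RawPost

__all__ = [
    "SyntheticConfig",
    "GroundTruthRecord",
    "generate_corpus",
    "generate_hashtag_graph",
    "FixturePostSource",
    "default_drug_lexicon",
    "write_ground_truth",
    "read_ground_truth",
]

# Collection window of the emulated study corpus.
_BASE_TIME = datetime(2018, 10, 18, 12, 0, 0, tzinfo=timezone.utc)

_PROMO_PHRASES = (
    "order now for quick delivery",
    "interested in placing order without prescription",
    "fast and discreet shipping worldwide",
    "dm to place your order today",
    "overnight delivery guaranteed no signature needed",
    "no script needed quick and safe delivery",
    "bulk discounts available order before midnight",
    "serious buyers only fast shipping",
)

_STOCK_TEMPLATES = (
    "premium {drug} in stock",
    "{qty}mg {drug} available now",
    "top grade {drug} ready to ship",
    "{drug} pills on deck {qty} count",
    "fresh stock of {drug} just in",
    "quality {drug} at the best price",
)

_BACKGROUND_TOPICS: dict[str, tuple[str, ...]] = {
    "fitness": (
        "gym", "workout", "lifting", "cardio", "protein", "gains", "squat",
        "running", "marathon", "training", "sweat", "deadlift", "reps",
    ),
    "food": (
        "brunch", "coffee", "pasta", "vegan", "recipe", "baking", "tacos",
        "dinner", "homemade", "delicious", "kitchen", "chef", "dessert",
    ),
    "travel": (
        "sunset", "beach", "mountains", "wanderlust", "passport", "island",
        "roadtrip", "hiking", "adventure", "backpacking", "city", "ocean",
    ),
    "music": (
        "concert", "vinyl", "guitar", "festival", "playlist", "studio",
        "drums", "melody", "tour", "band", "singer", "acoustic",
    ),
    "art": (
        "sketch", "canvas", "painting", "gallery", "portrait", "charcoal",
        "mural", "sculpture", "watercolor", "exhibit", "drawing", "ink",
    ),
}

_BACKGROUND_COMMENTS = (
    "love this",
    "great shot",
    "amazing as always",
    "this made my day",
    "so cool",
    "where was this taken",
    "goals",
    "stunning",
)

_BUYER_COMMENTS = (
    "how much for {qty}",
    "price for {qty} please",
    "i want to buy dm me",
    "can i order some",
    "still available how much",
    "interested in buying can i get {qty}",
    "how do i order",
    "ill take {qty} send details",
)

_EMAIL_DOMAINS = ("gmail.com", "yahoo.com", "protonmail.com", "outlook.com")
_APP_NAMES = ("wickr", "telegram", "kik", "whatsapp")
# Channel mix: apps dominate, led by wickr, as observed in dealer posts.
_APP_WEIGHTS = (0.40, 0.25, 0.20, 0.15)

_AWARENESS_TEMPLATES = (
    "my recovery story one year clean from {drug}",
    "raising awareness about {drug} addiction please share",
    "documentary night learning about the {drug} crisis",
)


def default_drug_lexicon() -> dict[str, list[str]]:
    """Drug name -> hashtag variants, from the shipped lexicon file."""
    lexicon: dict[str, list[str]] = {}
    text = resources.files("dealerscan.data").joinpath("drug_lexicon.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        if row["category"] == "sale_or_shipping":
            continue
        lexicon.setdefault(row["drug"], []).append(row["hashtag"])
    return lexicon


@dataclass
class SyntheticConfig:
    """Knobs of the corpus generator; defaults are the study conditions."""

    n_posts: int = 2000
    dealer_fraction: float = 0.096
    seed: int = 7
    drug_lexicon: dict[str, list[str]] = field(default_factory=default_drug_lexicon)
    promo_phrases: tuple[str, ...] = _PROMO_PHRASES
    background_topics: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_BACKGROUND_TOPICS)
    )
    contact_prob: float = 0.9
    transaction_fraction: float = 0.25
    hard_negative_fraction: float = 0.15
    noise: float = 0.25
    sale_hashtags: tuple[str, ...] = ("forsale", "shipping")

    def validate(self) -> None:
        if not 0 < self.dealer_fraction < 1:
            raise ValueError("dealer_fraction must be in (0, 1)")
        if self.n_posts < 1:
            raise ValueError("n_posts must be positive")
        if not self.drug_lexicon or any(
            len(v) == 0 for v in self.drug_lexicon.values()
        ):
            raise ValueError("drug_lexicon must be non-empty with non-empty pools")
        if not self.promo_phrases or not self.background_topics:
            raise ValueError("promo_phrases and background_topics must be non-empty")


@dataclass(frozen=True)
class GroundTruthRecord:
    """What the generator planted in one post, for exact scoring."""

    post_id: str
    label: int
    planted_drug: str | None = None
    planted_contact: str | None = None  # "email", "phone" or "app:<name>"
    planted_transaction: bool = False


def _handle(rng: np.random.Generator) -> str:
    stems = ("pharm", "plug", "meds", "candy", "doc", "supply", "drop", "king")
    stem = stems[rng.integers(len(stems))]
    suffix = "".join(
        str(c)
        for c in rng.choice(list("abcdefghijklmnopqrstuvwxyz0123456789"), size=5)
    )
    return f"{stem}{suffix}"


def _phone(rng: np.random.Generator) -> str:
    d = rng.integers(0, 10, size=10)
    return f"+1 {d[0]}{d[1]}{d[2]} {d[3]}{d[4]}{d[5]} {d[6]}{d[7]}{d[8]}{d[9]}"


def _contact(rng: np.random.Generator) -> tuple[str, str]:
    """Return (contact sentence, planted kind)."""
    r = rng.random()
    if r < 0.60:
        app = str(rng.choice(_APP_NAMES, p=_APP_WEIGHTS))
        if app == "wickr":
            return f"wickr me: {_handle(rng)}", "app:wickr"
        if app == "telegram":
            return f"telegram: @{_handle(rng)}", "app:telegram"
        if app == "kik":
            return f"kik: {_handle(rng)}", "app:kik"
        return f"whatsapp: {_phone(rng)}", "app:whatsapp"
    if r < 0.85:
        return f"contact {_handle(rng)}@{_EMAIL_DOMAINS[rng.integers(4)]}", "email"
    return f"call or text {_phone(rng)}", "phone"


def _dealer_caption(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[str, str, str | None]:
    """Compose one dealer caption; returns (caption, drug, planted_contact)."""
    drugs = sorted(config.drug_lexicon)
    drug = drugs[rng.integers(len(drugs))]
    variants = config.drug_lexicon[drug]
    qty = int(rng.choice([10, 20, 25, 30, 50, 60, 100, 250]))
    stock = _STOCK_TEMPLATES[rng.integers(len(_STOCK_TEMPLATES))].format(
        drug=drug, qty=qty
    )
    promo = config.promo_phrases[rng.integers(len(config.promo_phrases))]
    parts = [stock, promo]
    planted_contact: str | None = None
    if rng.random() < config.contact_prob:
        sentence, planted_contact = _contact(rng)
        parts.append(sentence)
    n_tags = int(rng.integers(1, min(3, len(variants)) + 1))
    tags = [str(t) for t in rng.choice(variants, size=n_tags, replace=False)]
    if rng.random() < 0.3 and len(drugs) > 1:
        other = drugs[rng.integers(len(drugs))]
        if other != drug:
            tags.append(str(rng.choice(config.drug_lexicon[other])))
    if rng.random() < 0.6:
        tags.append(str(rng.choice(config.sale_hashtags)))
    if rng.random() < config.noise:
        topic = sorted(config.background_topics)[
            rng.integers(len(config.background_topics))
        ]
        tags.append(str(rng.choice(config.background_topics[topic])))
    caption = ". ".join(parts) + " " + " ".join("#" + t for t in tags)
    if rng.random() < 0.5:
        caption += " \U0001f48a\U0001f525"  # pill + fire emoji, exercises cleaning
    return caption, drug, planted_contact


def _background_caption(config: SyntheticConfig, rng: np.random.Generator) -> str:
    topics = sorted(config.background_topics)
    topic = topics[rng.integers(len(topics))]
    pool = config.background_topics[topic]
    n_words = int(rng.integers(5, 11))
    words = [str(w) for w in rng.choice(pool, size=min(n_words, len(pool)), replace=False)]
    caption = " ".join(words)
    if rng.random() < config.hard_negative_fraction:
        # Hard negative: drug hashtags / mentions without dealer syntax.
        drugs = sorted(config.drug_lexicon)
        drug = drugs[rng.integers(len(drugs))]
        if rng.random() < 0.5:
            caption = _AWARENESS_TEMPLATES[rng.integers(len(_AWARENESS_TEMPLATES))].format(
                drug=drug
            )
        n_tags = int(rng.integers(1, 3))
        tags = [str(t) for t in rng.choice(config.drug_lexicon[drug], size=n_tags)]
        caption += " " + " ".join("#" + t for t in dict.fromkeys(tags))
    else:
        n_tags = int(rng.integers(1, 4))
        tags = [str(t) for t in rng.choice(pool, size=n_tags, replace=False)]
        caption += " " + " ".join("#" + t for t in tags)
    if rng.random() < 0.15:
        caption += f" check www.blog{rng.integers(100)}.example/post"
    if rng.random() < 0.3:
        caption += " ✨\U0001f60d"
    return caption


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[LabeledPost], list[GroundTruthRecord]]:
    """Generate a labeled corpus plus its ground truth.

    The dealer count is exactly ``round(n_posts * dealer_fraction)``;
    dealer positions are a seeded permutation, so identical configs give
    byte-identical corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_dealer = int(round(config.n_posts * config.dealer_fraction))
    labels = np.zeros(config.n_posts, dtype=np.int64)
    labels[rng.permutation(config.n_posts)[:n_dealer]] = 1

    # Few dealers author many posts (~0.22 users per dealer post).
    n_dealer_users = max(1, int(round(n_dealer * 0.22)))
    posts: list[LabeledPost] = []
    truth: list[GroundTruthRecord] = []
    for i in range(config.n_posts):
        post_id = f"p{i:06d}"
        ts = _BASE_TIME - timedelta(days=float(rng.uniform(0.0, 90.0)))
        comments: list[Comment] = []
        if labels[i] == 1:
            caption, drug, planted_contact = _dealer_caption(config, rng)
            user_id = f"dealer{int(rng.integers(n_dealer_users)):04d}"
            planted_transaction = False
            if planted_contact is not None and rng.random() < config.transaction_fraction:
                qty = int(rng.choice([5, 10, 20, 30]))
                text = _BUYER_COMMENTS[rng.integers(len(_BUYER_COMMENTS))].format(qty=qty)
                comments.append(Comment(user_id=f"buyer{int(rng.integers(10000)):05d}", text=text))
                planted_transaction = True
            if rng.random() < 0.3:
                comments.append(
                    Comment(
                        user_id=user_id,
                        text="check bio for more",
                    )
                )
            truth.append(
                GroundTruthRecord(
                    post_id=post_id,
                    label=1,
                    planted_drug=drug,
                    planted_contact=planted_contact,
                    planted_transaction=planted_transaction,
                )
            )
        else:
            caption = _background_caption(config, rng)
            user_id = f"user{int(rng.integers(max(1, config.n_posts))):06d}"
            for _ in range(int(rng.integers(0, 3))):
                comments.append(
                    Comment(
                        user_id=f"user{int(rng.integers(max(1, config.n_posts))):06d}",
                        text=str(rng.choice(_BACKGROUND_COMMENTS)),
                    )
                )
            truth.append(GroundTruthRecord(post_id=post_id, label=0))
        image_refs = (f"img_{post_id}.jpg",) if rng.random() < 0.8 else ()
        posts.append(
            LabeledPost(
                post=RawPost(
                    post_id=post_id,
                    user_id=user_id,
                    timestamp=ts,
                    caption=caption,
                    comments=tuple(comments),
                    image_refs=image_refs,
                ),
                label=int(labels[i]),
            )
        )
    return posts, truth


def write_ground_truth(records: Sequence[GroundTruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["post_id", "label", "planted_drug", "planted_contact", "planted_transaction"]
        )
        for r in records:
            writer.writerow(
                [
                    r.post_id,
                    r.label,
                    r.planted_drug or "",
                    r.planted_contact or "",
                    int(r.planted_transaction),
                ]
            )


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    out: list[GroundTruthRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                GroundTruthRecord(
                    post_id=row["post_id"],
                    label=int(row["label"]),
                    planted_drug=row["planted_drug"] or None,
                    planted_contact=row["planted_contact"] or None,
                    planted_transaction=bool(int(row["planted_transaction"])),
                )
            )
    return out


class FixturePostSource:
    """In-memory snapshot post source for crawl tests and demos.

    Satisfies the crawler's source contract: ``query(hashtag)`` returns the
    posts carrying that hashtag, newest first; repeated queries return
    identical results.
    """

    def __init__(self, posts: Sequence[RawPost], now: datetime):
        self.now = now
        self._posts = list(posts)
        self._by_tag: dict[str, list[RawPost]] = {}
        for post in posts:
            for tag in _caption_hashtags(post.caption):
                self._by_tag.setdefault(tag, []).append(post)
        for tag in self._by_tag:
            self._by_tag[tag].sort(key=lambda p: (p.timestamp, p.post_id), reverse=True)

    def query(self, hashtag: str) -> list[RawPost]:
        return list(self._by_tag.get(hashtag.lstrip("#").lower(), []))

    @property
    def all_posts(self) -> list[RawPost]:
        return list(self._posts)

    @property
    def hashtags(self) -> list[str]:
        return sorted(self._by_tag)


def _caption_hashtags(caption: str) -> list[str]:
    from .preprocess import clean_text, split_text_hashtags

    _, tags = split_text_hashtags(clean_text(caption, stopwords=frozenset()))
    return tags


def generate_hashtag_graph(
    config: SyntheticConfig,
    n_hashtags: int = 30,
    n_posts: int = 500,
    window_days: float = 90.0,
    span_days: float = 180.0,
) -> FixturePostSource:
    """Build a queryable hashtag-graph fixture for the 2-loop crawl.

    Drug hashtags co-occur on dealer posts so that crawling one reveals
    others: within the recency window the drug tags are wired into a
    connected co-occurrence graph (a seeded cycle plus random extra tags).
    Timestamps span ``span_days`` (> the window) so the crawler's recency
    cutoff is exercised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    drug_tags = sorted({t for pool in config.drug_lexicon.values() for t in pool})
    if n_hashtags < len(drug_tags):
        raise ValueError(
            f"n_hashtags={n_hashtags} below the {len(drug_tags)} planted drug hashtags"
        )
    n_background = n_hashtags - len(drug_tags)
    background_pool = sorted({w for pool in config.background_topics.values() for w in pool})
    background_tags = [
        str(t) for t in rng.choice(background_pool, size=min(n_background, len(background_pool)), replace=False)
    ]
    while len(background_tags) < n_background:
        background_tags.append(f"misc{len(background_tags):03d}")

    cycle = [drug_tags[int(i)] for i in rng.permutation(len(drug_tags))]
    now = _BASE_TIME
    posts: list[RawPost] = []
    in_window_dealer_idx = 0
    for i in range(n_posts):
        post_id = f"g{i:05d}"
        is_dealer = rng.random() < 0.4
        age = float(rng.uniform(0.0, span_days))
        ts = now - timedelta(days=age)
        if is_dealer:
            if age <= window_days:
                # Consecutive cycle edges guarantee in-window connectivity.
                j = in_window_dealer_idx % len(cycle)
                tags = [cycle[j], cycle[(j + 1) % len(cycle)]]
                in_window_dealer_idx += 1
            else:
                tags = [str(t) for t in rng.choice(drug_tags, size=2, replace=False)]
            n_extra = int(rng.integers(0, 3))
            tags += [str(t) for t in rng.choice(drug_tags, size=n_extra)]
            if rng.random() < 0.3:
                tags.append(str(rng.choice(background_tags)))
            caption = (
                config.promo_phrases[rng.integers(len(config.promo_phrases))]
                + " "
                + " ".join("#" + t for t in dict.fromkeys(tags))
            )
            user = f"dealer{int(rng.integers(40)):03d}"
        else:
            n_tags = int(rng.integers(1, 4))
            tags = [str(t) for t in rng.choice(background_tags, size=n_tags)]
            if rng.random() < 0.1:
                tags.append(str(rng.choice(drug_tags)))
            caption = "just another day " + " ".join("#" + t for t in dict.fromkeys(tags))
            user = f"user{int(rng.integers(300)):04d}"
        posts.append(
            RawPost(
                post_id=post_id,
                user_id=user,
                timestamp=ts,
                caption=caption,
            )
        )
    return FixturePostSource(posts, now=now)
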