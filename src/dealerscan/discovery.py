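"""Two-loop hashtag-expansion crawl over a pluggable post source.

Posts on hashtag-driven platforms are found by searching tags, so a
corpus is grown by snowballing: query each seed hashtag, collect its
posts newest-to-oldest until one falls outside the recency window
(default 90 days ~ 3 months), harvest the hashtags those posts carry,
keep the ones passing a drug-keyword filter, and run one second loop over
the newly discovered tags. Collected posts are deduplicated by post id
across all queries.

The crawler talks to any object with a ``query(hashtag) -> posts
(newest first)`` method; the bundled synthetic fixture
(:class:`dealerscan.synthetic.FixturePostSource`) implements the contract
for tests and demos — no live-platform adapter is included. The keyword
filter is a shipped substring list standing in for a manual vetting step;
an ``interactive_review`` hook lets a human edit the candidate list
between the loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from importlib import resources
from pathlib import Path
from typing import Callable, Protocol, Sequence

from .corpus_io import RawPost
from .preprocess import clean_text, split_text_hashtags

__all__ = [
    "PostSource",
    "CrawlState",
    "load_keyword_filter",
    "crawl_loop1",
    "crawl_loop2",
    "crawl",
]


class PostSource(Protocol):
    """Snapshot source: identical queries return identical results."""

    def query(self, hashtag: str) -> list[RawPost]: ...


def load_keyword_filter(path: str | Path | None = None) -> tuple[str, ...]:
    """Load the drug-keyword substring list (shipped default)."""
    if path is None:
        text = resources.files("dealerscan.data").joinpath("drug_keywords.txt").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    return tuple(line.strip().lower() for line in text.splitlines() if line.strip())


@dataclass
class CrawlState:
    """Everything a crawl has seen so far."""

    seed_hashtags: list[str]
    cutoff: timedelta
    start_time: datetime
    discovered_hashtags: list[str] = field(default_factory=list)  # ordered, first-seen
    visited_hashtags: set[str] = field(default_factory=set)
    collected_posts: dict[str, RawPost] = field(default_factory=dict)
    loop_found: dict[str, int] = field(default_factory=dict)

    @property
    def oldest_allowed(self) -> datetime:
        return self.start_time - self.cutoff

    def report(self, source: PostSource) -> list[dict]:
        rows = []
        for tag in self.discovered_hashtags:
            in_window = [
                p for p in source.query(tag) if p.timestamp >= self.oldest_allowed
            ]
            rows.append(
                {
                    "hashtag": tag,
                    "loop_found": self.loop_found.get(tag, 0),
                    "post_count": len(in_window),
                }
            )
        return rows


def _post_hashtags(post: RawPost) -> list[str]:
    _, tags = split_text_hashtags(clean_text(post.caption, stopwords=frozenset()))
    return tags


def _passes(tag: str, keyword_filter: Sequence[str]) -> bool:
    return any(kw in tag for kw in keyword_filter)


def _collect_under(state: CrawlState, source: PostSource, tag: str) -> list[RawPost]:
    """Query one hashtag, walking newest-to-oldest and stopping at the first
    post older than the cutoff; new posts are added to the collection."""
    fresh: list[RawPost] = []
    for post in source.query(tag):
        if post.timestamp < state.oldest_allowed:
            break
        if post.post_id not in state.collected_posts:
            state.collected_posts[post.post_id] = post
            fresh.append(post)
    state.visited_hashtags.add(tag)
    return fresh


def _harvest(state: CrawlState, posts: Sequence[RawPost], keyword_filter: Sequence[str], loop: int) -> None:
    for post in posts:
        for tag in _post_hashtags(post):
            if (
                tag not in state.discovered_hashtags
                and tag not in state.seed_hashtags
                and _passes(tag, keyword_filter)
            ):
                state.discovered_hashtags.append(tag)
                state.loop_found[tag] = loop


def crawl_loop1(
    source: PostSource,
    seeds: Sequence[str],
    cutoff: timedelta = timedelta(days=90),
    keyword_filter: Sequence[str] | None = None,
    start_time: datetime | None = None,
) -> CrawlState:
    """First loop: collect recent posts under each seed hashtag and harvest
    filter-passing co-occurring hashtags in first-seen order.

    A seed with no posts is recorded as visited, not an error.
    """
    if not seeds:
        raise ValueError("seed hashtag list must be non-empty")
    seeds = [s.lstrip("#").lower() for s in seeds]
    if keyword_filter is None:
        keyword_filter = load_keyword_filter()
    if start_time is None:
        start_time = getattr(source, "now", None)
        if start_time is None:
            raise ValueError("source has no 'now'; pass start_time explicitly")
    state = CrawlState(seed_hashtags=list(seeds), cutoff=cutoff, start_time=start_time)
    for seed in seeds:
        fresh = _collect_under(state, source, seed)
        _harvest(state, fresh, keyword_filter, loop=1)
    return state


def crawl_loop2(
    source: PostSource,
    state: CrawlState,
    cutoff: timedelta | None = None,
    keyword_filter: Sequence[str] | None = None,
    expand_from_loop: int = 1,
) -> CrawlState:
    """Second loop: query every hashtag discovered in loop ``expand_from_loop``
    (and not yet visited) once under the same cutoff. Hashtags surfacing
    during this loop are recorded but never expanded, so running the loop
    again is a no-op."""
    if cutoff is not None:
        state.cutoff = cutoff
    if keyword_filter is None:
        keyword_filter = load_keyword_filter()
    pending = [
        t
        for t in state.discovered_hashtags
        if t not in state.visited_hashtags
        and state.loop_found.get(t, 0) <= expand_from_loop
    ]
    for tag in pending:
        fresh = _collect_under(state, source, tag)
        _harvest(state, fresh, keyword_filter, loop=expand_from_loop + 1)
    return state


def crawl(
    source: PostSource,
    seeds: Sequence[str],
    cutoff_days: float = 90.0,
    keyword_filter: Sequence[str] | None = None,
    start_time: datetime | None = None,
    interactive_review: Callable[[list[str]], list[str]] | None = None,
    max_loops: int = 2,
) -> CrawlState:
    """Run the full expansion crawl (two loops by default).

    ``interactive_review``, if given, receives the candidate hashtag list
    after loop 1 and returns the edited list — the hook for replacing the
    keyword filter with human vetting.
    """
    cutoff = timedelta(days=cutoff_days)
    state = crawl_loop1(source, seeds, cutoff, keyword_filter, start_time)
    if interactive_review is not None:
        state.discovered_hashtags = list(interactive_review(state.discovered_hashtags))
    for loop in range(1, max_loops):
        before = set(state.visited_hashtags)
        crawl_loop2(source, state, keyword_filter=keyword_filter, expand_from_loop=loop)
        if state.visited_hashtags == before:
            break
    return state
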