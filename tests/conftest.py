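from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, settings

import dealerscan as ds

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

_BASE = datetime(2018, 10, 1, tzinfo=timezone.utc)


def make_post(post_id: str, caption: str = "", user_id: str = "u1",
              days_ago: float = 0.0, comments=()) -> ds.RawPost:
    return ds.RawPost(
        post_id=post_id,
        user_id=user_id,
        timestamp=_BASE - timedelta(days=days_ago),
        caption=caption,
        comments=tuple(ds.Comment(*c) for c in comments),
    )


@pytest.fixture(scope="session")
def small_corpus():
    """300-post synthetic corpus shared by fast tests."""
    config = ds.SyntheticConfig(n_posts=300, seed=7)
    return ds.generate_corpus(config)


@pytest.fixture(scope="session")
def small_clean(small_corpus):
    posts, _ = small_corpus
    return ds.clean_posts(posts)
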