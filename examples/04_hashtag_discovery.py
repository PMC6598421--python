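"""Discover drug-related hashtags with the 2-loop expansion crawl.

Queries a snapshot post source for a seed hashtag, collects posts newer
than the 90-day cutoff, harvests co-occurring hashtags that pass the
drug-keyword filter, then crawls the harvested tags once.
"""

import dealerscan as ds
from dealerscan.discovery import crawl, load_keyword_filter

source = ds.generate_hashtag_graph(ds.SyntheticConfig(seed=11), n_hashtags=30, n_posts=500)

state = crawl(source, seeds=["xanax"], cutoff_days=90, keyword_filter=load_keyword_filter())

print(f"seed hashtags:        {state.seed_hashtags}")
print(f"discovered hashtags:  {len(state.discovered_hashtags)}")
print(f"visited hashtags:     {len(state.visited_hashtags)}")
print(f"collected posts:      {len(state.collected_posts)}")
print("\nfirst discoveries in order found:")
for tag in state.discovered_hashtags[:8]:
    print(f"  #{tag} (loop {state.loop_found[tag]})")
# Starting from one seed, co-occurrence on dealer posts reveals the other
# drug hashtag variants; every collected post is inside the recency window.
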