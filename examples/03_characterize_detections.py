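"""Characterize the posts a classifier flagged as dealer posts.

Counts drug hashtags per taxonomy group (union semantics: a post with two
Xanax variants counts once in the Xanax total), tallies contact channels,
and detects buyer-seller exchanges in the comments.
"""

import dealerscan as ds
from dealerscan.characterize import load_lexicon, summarize_detected

posts, _ = ds.generate_corpus(ds.SyntheticConfig(n_posts=1000, seed=11))
# Stand-in for classifier output: use the true labels as predictions.
predictions = {p.post.post_id: p.label for p in posts}

report = summarize_detected([p.post for p in posts], predictions, load_lexicon())
print(report.text_summary())
# Drug totals are distinct-post counts; channel rows count posts whose
# caption or comments matched that channel's pattern; an exchange is a
# dealer post with contact info plus a buy-intent comment from another user.
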