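# Methods

## Problem and pipeline

`dealerscan` detects posts that *sell* drugs — as opposed to posts that
merely mention them — on platforms where content is organized by
hashtags. The pipeline has five stages: corpus collection via hashtag
crawling, preprocessing into text and hashtag parts, supervised
classification, cross-validated evaluation over a text/hashtag ablation,
and post-hoc characterization of the detected posts. Every stage runs on
synthetic corpora shipped with the package; nothing touches a live
platform.

## Preprocessing

Captions are lowercased; hyperlinks are removed first (so their hosts do
not leak into tokens); every character outside `[a-z0-9#]` and whitespace
is deleted (a whitelist, deterministic across unicode versions); a space
is inserted before each `#` so run-together tags like `#xanax#oxy`
separate; tokens are produced by whitespace splitting; stop words are
removed from non-hashtag tokens. The stop-word list is a standard English
list shipped as a data file so results are reproducible bit-for-bit.
Tokenization is therefore: clean first, split on whitespace, treat any
`#`-leading token as a hashtag. One consequence of cleaning before
stop-word removal is that contracted stop words lose their apostrophe
("don't" → "dont") and survive; this affects a handful of function words
and none of the planted signal.

The dictionary maps each distinct token (text and hashtag parts pooled)
to an index in `1..size`, assigned in first-occurrence order — the
ordering is arbitrary but must be deterministic, and first-occurrence
needs no second pass. Index 0 is reserved for padding and `size + 1` for
unknown tokens, so embedding tables have `size + 2` rows. By default the
dictionary is built from the training folds only; a
`vocab_scope="full_corpus"` flag reproduces the alternative of building
it on all texts, which leaks test-set vocabulary into training and is
kept only for comparison.

Captions encode to fixed-length index vectors: 50 tokens for the text
part and 15 for the hashtag part (both configurable), truncating long
sequences from the end and zero-filling short ones. The hashtag length
is treated as a token count; treating it as a character count would make
the two branches incommensurable.

Three dataset variants implement the ablation. Each restricts a post to
the relevant token subset (both parts / hashtags only / text only),
drops posts left empty by the restriction, and deduplicates by the
restricted token sequence, keeping first occurrences — two posts that
differ only in their hashtags are one example in *text without
hashtags*.

## The classifier

The deep model is a two-branch network: each branch embeds its index
sequence (embedding dimension 400 at full scale), runs an LSTM (800
units, dropout 0.2, recurrent dropout 0.2) and compresses the final
hidden state through a sigmoid dense layer (200 units); the two branch
vectors are concatenated — the minimal merge consistent with "merged
together" — and passed through one more 200-unit sigmoid layer and a
single sigmoid output unit emitting the dealer probability. A post is
labeled dealer iff p strictly exceeds the 0.5 threshold.

The network is implemented directly in numpy (`dealerscan._nn`):
embedding lookup, gated recurrence, Gal-style (per-sequence) dropout
masks on inputs and recurrent connections, full backpropagation through
time, and Adam. Padding index 0 is masked out of the recurrence — state
carries through padded steps unchanged — so trailing zeros never dilute
short posts, and trailing all-pad columns can be trimmed per batch as a
pure speed-up. Gradient correctness is pinned by a finite-difference
check in the test suite (agreement to ~1e-11). Dense layers consume the
final hidden state rather than the full output sequence; with masked
padding the final state is the natural sequence summary.

Training minimizes mean binary cross-entropy with probabilities clipped
to `[1e-7, 1 - 1e-7]` (clipping is required for finiteness at saturated
predictions; the gradient uses the standard unclipped `p - y` form).
After each epoch the validation loss is recorded; training stops when the
most recent validation loss exceeds *each of* the previous 4 (the
conjunctive reading of "continually increasing"), or at `max_epochs`.
The weights of the best-validation-loss epoch are restored at the end,
matching the stated purpose of the validation set.

Two configuration scales are provided. The full scale (embedding 400,
LSTM 800, dense 200, Adam lr 1e-4, 50 epochs) matches the architecture
as specified for a ~30k-token vocabulary. The `desk_scale` flag
substitutes a ~25× narrower network (32/32/16) with lr 1e-3 and 15
epochs: at this width the loss surface is much better conditioned and
1e-4 would need far more epochs than it saves, so the learning rate and
epoch budget scale together with the architecture. The optimizer-step
budget is epochs × batches, so corpora much smaller than the default
2,000 posts need proportionally more epochs (the evaluation example uses
50 at n = 600). Batch size defaults to 32.

Baselines — decision tree, random forest (100 trees), and a
linear-kernel SVM — consume binary term-presence vectors over the shared
vocabulary (term frequency available by flag), untruncated by default
since classical models have no sequence-length constraint
(`baseline_truncated` applies the 50/15 truncation for a stricter
apples-to-apples comparison). All three expose a predicted probability —
leaf frequencies, tree vote fractions, or the SVM margin through a
logistic link — so AUC is computable for every model. The baselines are
fitted with scikit-learn behind the module's surface; the deep model and
the loss are authored in this package.

## Evaluation protocol

Each variant is shuffled under a seed and split into k = 10 near-equal
contiguous folds. For each iteration the model is reset, trained on the
other nine folds and applied to the held-out fold; the deep model
further splits its training folds 70/30, stratified by label (at ~10%
prevalence an unstratified split can produce validation sets with almost
no positives), for early stopping. Every example thus receives exactly
one out-of-fold prediction.

Precision, recall and F1 are computed from the pooled out-of-fold
predictions; per-fold averaging (`metric_aggregation="fold_mean"`) is
available but unstable at 10% prevalence, where a fold holds only ~20
positives. AUC — the probability that a random positive outranks a
random negative, ties counting one half — is computed by the Mann-Whitney
rank formula over the pooled out-of-fold probabilities of the whole
dataset; this is the reading of "whole-dataset AUC" that never scores a
model on its own training data. The literal alternative (train on
everything, score on everything) is available as
`auc_mode="resubstitution"`. All randomness flows from one top-level seed
expanded into per-fold seeds.

Metric implementations are formula-direct and are cross-checked in the
tests against brute-force pair enumeration and against scikit-learn's
implementations — two independent routes to the same numbers.

## Synthetic data

The generator emulates the statistical structure of an annotated
drug-market corpus, not its linguistic richness. Dealer posts (exactly
`round(n × 0.096)` of n posts, the prevalence of dealer posts in
annotated corpora of this kind) compose a drug stock line with a random
quantity, a sale-promotion phrase, contact information with probability
0.9 (apps 60% — led by Wickr — email 25%, phone 15%), one to three
hashtag variants of the advertised drug (occasionally a second drug, a
sale keyword like `#forsale`, or an off-topic stray tag), and sometimes
emoji. The drug lexicon ships as a data file covering four drug groups
(xanax, oxycodone/oxycontin, LSD, MDMA) with drug-name, misspelling,
extended and street-name variants. Background posts sample topical token
pools (fitness, food, travel, music, art); a 15% fraction are *hard
negatives* carrying drug hashtags or an awareness-style drug mention
without any dealer syntax — without them the hashtag-only task would be
trivial. A configurable fraction (default 0.25) of contact-bearing
dealer posts receives a seeded buy-intent comment from a different user.
Dealer posts are authored by a small user pool (~0.22 users per dealer
post) so unique-user counting is exercised. Generation is a pure
function of the seed, and every post comes with a ground-truth record
(label, planted drug, planted contact kind, seeded transaction flag).

What the generator does **not** emulate: natural language variation
beyond template mixing, adversarial obfuscation of contact info, images,
or temporal dynamics. Passing tests therefore demonstrate that the
pipeline recovers planted structure under realistic prevalence and
noise, not field performance on live platform data — template-composed
text is easier to separate than real captions, and near-ceiling scores
on the text variants reflect that.

The hashtag-graph fixture for the crawler plants all drug hashtags on
dealer posts such that, within the 90-day recency window, the
co-occurrence graph is connected by construction (consecutive in-window
dealer posts carry consecutive edges of a seeded cycle, plus random
extras); timestamps span 180 days so the cutoff is exercised.

## Discovery crawl

Loop 1 queries each seed hashtag, walking results newest-to-oldest and
stopping at the first post older than the cutoff (90 days ≈ 3 months,
configurable); hashtags harvested from collected posts that pass a
substring keyword filter join the candidate list in first-seen order.
Loop 2 queries each loop-1 candidate once under the same cutoff; posts
are deduplicated by id across all queries; tags surfacing in loop 2 are
recorded but never expanded (so re-running loop 2 is a no-op), with a
`max_loops` override for deeper crawls. The keyword filter is an
automated stand-in for manual vetting of candidate hashtags — a known
deviation — and an `interactive_review` hook lets a human edit the
candidate list between loops.

## Characterization

Drug counts use union semantics: a drug's total is the number of
distinct posts carrying at least one of its variants, so the total is at
most the sum of per-hashtag counts. Contact extraction is regex-based:
emails (`local@domain.tld`), phone numbers (7–15 digits with separators
and optional `+` — the 7-digit floor keeps dosages like "2mg" and batch
names like "80s" from matching), and app mentions (app name followed by
a colon/handle pattern, or within three tokens of a handle-like token),
scanning caption and comments. A buyer–seller exchange is a
dealer-labeled post with a nonempty contact set plus a comment from a
*different* user matching a shipped buy-intent phrase list or a
price/order interrogative. Users are deduplicated by `user_id` equality.

## Numerical and degenerate-input choices

- Probability clipping 1e-7 in the loss; threshold comparisons strict
  (`p > 0.5`; exactly 0.5 → negative).
- Precision/recall/F1 with a zero denominator report 0 with a warning;
  AUC on single-class labels is reported as missing rather than guessed.
- Fold sizes differ by at most one; `n < k` is an error.
- Empty captions clean to empty token lists; posts that clean to nothing
  are dropped from every variant.
- Weight initialization is Glorot-uniform (embeddings small-normal,
  forget-gate bias 1); two builds with the same config and seed are
  bit-identical, and training is reproducible run-to-run on one
  platform.

## Problem sizes used in the shipped checks

The test suite and the acceptance script evaluate the 10-fold model ×
variant table on a 2,000-post corpus with the desk-scale network,
characterization scores on a 10,000-post corpus, and the crawl on a
30-hashtag / 500-post fixture — sizes at which every check is exact or
tightly bounded while the whole suite stays a desk-scale computation.
The full-scale architecture remains available via the default
`ModelConfig()` for fidelity runs on real corpora.

## Known limitations

- Template-based synthetic text overstates separability relative to real
  captions; the hashtags-only variant is the only arm with substantial
  irreducible confusion.
- The crawler has no live-platform adapter, by design; rate limiting,
  authentication and HTML parsing are out of scope.
- No image modeling: detection uses text and hashtags only.
- Baseline features ignore word order entirely; the comparison isolates
  what sequence modeling adds only insofar as the planted syntax is
  order-insensitive, which on synthetic data it largely is.
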