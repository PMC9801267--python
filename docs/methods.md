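# Methods

This note records the modelling choices behind `pmir`, the defaults and why
they were chosen, and what the synthetic benchmark does and does not
establish about behaviour on real literature.

## Retrieval model

Documents are MEDLINE-like records; title and abstract are indexed as
separate fields with separate length statistics, so a term hit in an
8-token title is normalized against mean title length, not mean abstract
length. Tokenization is lowercased maximal alphanumeric runs — no stemming,
no stop words, no phrase positions. Multiword expressions (synonyms are
frequently multiword) are matched as bags of tokens, mirroring engine
"match" semantics; phrase matching is out of scope.

BM25 uses k1 = 1.2 and b = 0.75, the common engine defaults, with the
non-negative idf variant ln(1 + (N − df + ½)/(df + ½)). The non-negative
form matters here: boolean `must` semantics define a clause match as a
strictly positive score, and a signed idf would silently un-match documents
containing very common terms.

Query scoring semantics, chosen to match Lucene-style engines:

* a clause matches iff its score is > 0;
* `dis_max` scores max(s) + tie_breaker · (Σs − max(s)); tie_breaker 0.8
  keeps the best synonym dominant while still crediting corroborating
  synonyms;
* a boolean query is a hit iff every `must` clause matches; `should`
  clauses only add score — except when `must` is empty, in which case at
  least one `should` clause has to match (otherwise the query would match
  the whole collection with score 0);
* ties in the final ranking break by ascending article id, everywhere, so
  runs are bit-reproducible.

Candidate enumeration walks postings to build an exact superset of matching
documents before scoring; this is an optimization only and is tested for
exact agreement (membership, order, scores) with a score-every-document
reference.

## Synonym weighting

Synonym weights are normalized document frequencies,
w(sᵢ) = df(sᵢ)/max_j df(sⱼ), where the df of a multiword synonym counts
documents containing all of its tokens in either field. The design intent
is to *lower the ranks of rare terms*: weights must be increasing in df,
and max-normalization is the simplest such scheme that gives the
best-attested synonym full weight. If every synonym has df 0 all weights
fall back to 1. A synonym with df 0 (but a positive maximum) receives
weight 0; its clause can never match anyway, since the term occurs nowhere.
Treatment terms are never expanded.

Keyword `should` clauses ("trial", "patient") are plain term clauses with
boost 1.0 in each field. They act as a weak prior toward evidence-bearing
papers and, being should-only, provably never change which documents match.

## Reranking features and combiners

* **es** — raw retrieval score of the candidate (per-topic scale).
* **pb** — a pluggable text-pair score in [0,1]. The default backend is a
  fixed lexical overlap scorer (fraction of distinct query tokens present
  in the article). It stands in for a pair-relevance model pretrained on
  earlier assessment campaigns; any object with the `fit`/`score` contract
  can replace it.
* **ty** — max over the article's publication-type labels of a manually
  rated evidence score in [−2,2] (comment/editorial −1, erratum/retraction
  −2, journal article/review/letter/abstract 0, case report/observational
  study +1, clinical trial/meta-analysis/systematic review +2). Max
  aggregation: an article that is both "journal article" and
  "meta-analysis" scores as its strongest form. Unknown labels score 0.
* **ct** — empirical CDF of the citation count over the whole corpus, ties
  counted in (so a degenerate corpus gives every article 1.0).

Automatic presets score Σ_f w_f · f/f_max with per-topic feature maxima; a
zero maximum drops that term. Full presets score
r = w_LR · LR + w_FB · FB. The shipped full presets carry frozen LR
coefficients (−0.465, −0.141, −0.617, −0.005) as their fallback linear
model; in the active-learning loop the LR is refit to the collected
annotations at every iteration by default (a flag freezes it), because at
desk scale a refitted model dominates fixed coefficients tuned on a
different corpus. The OLS fit is ordinary least squares on raw features,
including an intercept; rank-deficient designs give the minimum-norm
solution rather than an error.

The default trainable FB backend hashes the tokens shared by query and
article into 4,096 crc32 buckets, appends the matched-fraction, and fits a
ridge regression (α = 1) to the normalized labels, clipping predictions to
[0,1]. It honors the mean-squared-error objective, is deterministic, and is
insensitive to training-example order — properties the loop's tests rely
on. An optional transformer backend (sigmoid regression head on a
biomedical BERT, Adam, learning rate 4×10⁻⁵, batch size 16, 10 epochs per
refit) documents the intended production scorer; it requires `torch` and
`transformers` and is not exercised by the test suite.

## Active learning loop

Top-1 active feedback: each iteration annotates, for every topic, the
highest-ranked candidate not yet annotated (tiers 0–4, normalized by /4 to
match the [0,1] objective), refits FB on *all* annotations, refits LR,
and re-ranks the cached candidate pool with the full combiner. Retrieval
stays outside the loop. The first ranking, before any scorer exists, comes
from the automatic combiner (auto-1) as a cold start.

Stop rule: the running mean of annotated labels is a pure
annotation-quality signal needing no held-out judgments. It is tracked
against its running maximum; once it has been strictly below that maximum
for `stop_window` (default 3) consecutive iterations, further annotation
is only surfacing documents worse than the best already seen, and the loop
stops. The budget is 22 iterations at 1 annotation per topic per
iteration. The patience value is this package's operationalization of
"stop when the mean annotated relevance has peaked".

## Evaluation

DCG discounts rank i by log2(i+1) (no discount at rank 1), the dominant
convention for graded TREC-style evaluation with these gain vectors. The
ideal DCG reorders *all* judged documents for the topic, so omitting a
judged relevant document costs score. Unjudged documents contribute gain 0.
P@10 and R-prec binarize at tier ≥ 1 (configurable).

Inferred NDCG follows the stratified protocol: ranks 1–30 fully judged,
ranks 31–100 judged with probability p = 0.25. The estimator imputes each
unjudged sampled-stratum position with the mean gain of the stratum's
judged documents and builds the ideal DCG from judged gains with
sampled-stratum counts inflated by 1/p, filling fractional rank slots
best-first. Its contract is the defining pair of properties, which the
tests enforce: at p = 1 with complete judgments it equals exact NDCG at the
pooled depth bit for bit, and over repeated pool draws its mean tracks the
exact value (within two Monte-Carlo standard errors over 2,000 resamples
on a 100-document ranking). Like all count-inflation estimators it is not
hard-bounded by 1: on very short, near-ceiling rankings (tiny sampled
stratum) single draws can exceed 1, which is why reported values average
over draws rather than clamping.

One textbook-sounding property is deliberately *not* asserted: NDCG is not
weakly decreasing when an arbitrary judged document's tier is lowered with
the ranking held fixed — lowering the tier of a document outside the
evaluated prefix lowers the ideal DCG only, raising the ratio. The tests
assert the true monotonicity (DCG in ranked tiers) instead.

## Synthetic benchmark

The reference benchmark is 5,000 documents, 10 topics, ~50 topic-bearing
documents per topic, 2 non-canonical synonyms per disease/gene concept, a
0.3 synonym-substitution rate, MEDLINE-like publication-type frequencies,
and discretized log-normal citation counts (median ≈ 4, heavy right tail).
Topic-bearing documents always mention the treatment, mention the disease
with probability 0.9 and the gene with probability 0.7. The simulated
expert assigns tier 0 unless both disease and treatment are present, then
rounds a monotone score in match quality (weight 3.0), publication-type
score (1.2 across its 4-point range), and citation quantile (0.6); the
weights were chosen once so that generated tiers span all five levels with
most mass in the middle, and are deliberately dominated by match quality —
evidence without topical match is worthless. The annotation oracle returns
the truth tier (optionally with clamped gaussian noise) and recomputes the
expert judgment from document content for off-truth pairs.

What the benchmark emulates: synonymy-driven vocabulary mismatch, the
evidence ordering of publication types, citation skew, and a consistent
expert. What it does not: linguistic structure (documents are token bags),
topic drift, ambiguous or contradictory judgments, inter-annotator
disagreement, and corpus scale (5,000 documents vs tens of millions).
Passing tests therefore demonstrate mechanism correctness and directional
behaviour — expansion raises recall, keywords are near-neutral, the loop's
learning curve rises then plateaus, full presets beat automatic ones — not
absolute performance on real literature, where all reported metrics would
be far lower.

Problem sizes in the test suite were chosen to keep the full run desk-scale:
the query-engine equivalence check uses 1,000 random corpora of at most 20
documents; OLS recovery uses n = 500 over 100 seeds; loop efficacy uses 20
seeds of the 5,000-document benchmark with 10 iterations (stop rule
disabled there so "after 10 iterations" is well defined, and exercised
separately under the default configuration).

## Known limitations

* The record-lines dialect and the MEDLINE XML subset cover the fields the
  pipeline consumes; they are not general MEDLINE parsers. Citation counts
  are not part of MEDLINE records and must come from a sidecar table whose
  provenance is the caller's responsibility.
* The lexical pb/FB backends cannot see signals absent from the token
  overlap (e.g. study size buried in prose); on real data the transformer
  backend is the intended FB.
* must-clauses contribute their scores to the total (engine default); a
  filter-only variant would change absolute scores but not membership.
* The inferred-NDCG estimator targets the protocol's defining properties;
  it is not a re-implementation of any specific official evaluation
  toolkit estimator.
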