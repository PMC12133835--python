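# Methods

This note documents the models, parameters, numerical conventions and design
choices behind `exsel`, and what the synthetic-data experiments do and do not
demonstrate.

## Hybrid explanation selection

**Relevance probabilities.** A candidate explanation's raw relevance is
`(1 − w) · mean(clip01 cos(e, ·)) over {query} ∪ demonstrations
+ w · max(clip01 cos(e, ·)) over criteria statements`, with `w =
criteria_weight` (default 0.5). The mean over query and demonstrations says
an explanation should speak to the whole in-context set; the max over
criteria says matching *one* diagnostic criterion well is enough — criteria
enumerate alternative symptoms, so averaging over them would punish
specificity. Negative cosines are clipped to 0 before use: a probability
semantics needs non-negative inputs, and anti-similarity carries no useful
relevance signal here. Raw scores are sum-normalized; the all-zero corner
falls back to the uniform distribution.

**ERR.** The cascade model scores an ordered list as
`Σ_k (1/k) Π_{i<k} (1 − γ p_i) · γ p_k`. The decay `γ ∈ (0, 1]`
(default 0.85) is the probability a relevant item actually satisfies the
user, so later positions are discounted by the chance the search already
ended. The per-item `err_contribution` is that sum's k-th term given the
already-selected prefix; contributions along any ordering sum exactly to the
list's ERR (checked to 1e-12 over 1,000 random instances).

**MMR.** `λ · sim(e, q) − (1 − λ) · max_j sim(e, e_j)` over already-selected
`e_j`, with the empty-set max defined as 0 and `λ = 0.5` by default.

**Aggregation.** ERR is a list-level functional while MMR scores items, so
"combine ERR and MMR" needs a concrete reading before `argmax` over
candidates is well-defined. We use the greedy per-position sum
`S_comb = err_contribution + mmr_score`, both terms bounded by [0, 1]-scaled
quantities, unweighted. At each rank the argmax candidate is taken; ties
break to the lowest candidate index (determinism). This greedy decomposition
is the only reading under which a per-candidate argmax exists at every step;
it is a documented choice, not a claim that the greedy selection is globally
optimal. A brute-force re-scoring oracle in the test suite verifies that
each selected item's recorded `S_comb` equals an independent recomputation
from raw parts.

## Embedding backends

The default backend is a hash embedding: each normalized token maps to a
64-dimensional Gaussian vector seeded by a BLAKE2b digest of
`(backend seed, token)`, and a text embeds as the unit-normalized mean over
its *unique* tokens. Properties that matter downstream: byte-level
determinism across processes and platforms; identical token sets embed
identically (consistent with the set semantics used by the factuality
metric); expected cosine between two texts grows with token overlap
(≈ `|A∩B| / √(|A||B|)` plus O(1/√64) noise). Dimension 64 keeps the noise
floor (~0.12 per token pair) well below the overlap signal used in the
tests. The sentence-transformers adapter satisfies the same contract
(unit-norm, fixed dimension, deterministic) using the encoder's default
pooling, and is exercised only by a smoke test when the library and a cached
checkpoint are available.

## Explanation validation

**Factuality** uses set (not multiset) token semantics:
`max_g |tokens(e) ∩ tokens(g)| / |tokens(e)|`. Tokenization is
whitespace-split, edge-punctuation-stripped, lowercased. Set semantics makes
the metric invariant to candidate token duplication and monotone in gold
growth — both property-tested. The max binds over gold references per
candidate: a candidate is factual if *some* expert rationale supports it.

**Consistency** is a BERTScore-style greedy token alignment: recall is the
mean over reference tokens of the best (clipped-cosine) match among
candidate tokens, precision the mirror image, F1 their harmonic mean (0 when
both vanish). Token vectors come from the same backend (`embed_token`);
with the hash backend unrelated tokens score near 0 and identical tokens
exactly 1, so identical texts yield F1 = 1 and disjoint texts F1 ≲ 0.3. No
stop-word removal by default (a flag exists); removal changes the operand
sets, so the default stays closest to the raw definition.

## Prompting and classification

Templates follow `[CLS] <demo blocks> <query utterances joined by " | ">
p1 [SEP] p2 [EOS]`. The snippets `p1, p2` are literal text standing in for
trained soft-prompt embeddings — training them is out of scope, and literal
snippets preserve the template structure at desk scale. Two snippets are the
default; more are accepted (the tail beyond the first joins after `[SEP]`).
The whitespace-token budget defaults to 3000; overflow drops demonstration
blocks from the end of the demo list and never touches the query (a query
that alone overflows raises).

The verbalizer maps classes to disjoint label-word lists; the shipped
default pairs `normal` (joy, happy, elation, contentment) against
`depression` (hurt, anger, moody, bored, sadness, broken, shocking). Class
score is the sum of per-word mask probabilities, sum-normalized — the
aggregation `f` is not prescribed anywhere upstream, and sum-then-normalize
is the simplest form that is monotone in every word's probability. Ties
predict `normal`: a screening tool should not default to the clinical
label. The default provider is a lexicon counter,
`count(word) / (1 + total label-word occurrences)`; the `+1` keeps values
strictly below 1 and hands zero-evidence contexts a zero score rather than
an arbitrary confidence. A real masked-LM provider slots in behind the same
`(context, label_word) → [0, 1]` contract.

## Downstream tasks

DUC pools 10 utterances with exactly one gold-depressed member; a pool is a
hit when the top-scored candidate is the depressed one (ties → lowest
index); R10@1 is the hit rate. DSI flags a speaker as depressed when any of
their utterances scores ≥ 0.5 (threshold configurable); F1 is computed over
(conversation, speaker) pairs against speakers with ≥ 1 gold-depressed
utterance. Candidate pools are drawn cross-conversation within the corpus.
Losses: per-utterance binary cross-entropy for DUC, and cross-entropy summed
over same-speaker positive pairs for DSI (0 when no positive pairs exist),
with probabilities clamped to `[1e-12, 1 − 1e-12]` and natural logs.

The default scorer concatenates the candidate text with the prompt's
demonstration/explanation blocks and returns the verbalizer's depression
probability. Within a pool this ordering is reliable — the depressed
candidate's own label words always add strictly positive evidence — but the
*absolute* score level shifts with the prompt's label-word composition.
Consequently DSI's fixed 0.5 threshold is miscalibrated for long prompts:
five-shot DSI F1 can drop to 0 while five-shot DUC R10@1 sits at 1.0 on the
same corpus. This is a property of the lexicon mock, not of the harness;
the acceptance report includes both DSI arms uncorrected.

## Synthetic corpus generator

The generator emulates corpus *structure*, not language: conversations of
exactly 5/10/15 utterances over ≥ 2 speakers; an utterance is depressed with
probability `depressed_utterance_fraction` (default 0.2) and then carries
1–2 depression label words, attributed to a designated depressed speaker
with probability 0.95; normal utterances carry only neutral distractor
words, with a 0.3 chance of one normal label word. An optional
`label_flip_rate` (default 0) models annotation noise. Demonstrations
(default 12, balanced) each carry 1–2 class-indicative label words — they
are exemplary labeled examples, which is what makes them demonstrations.

Gold explanations restate the demonstration's own content words and append a
short criteria-echoing verdict ("signals depressed mood and distress" /
"shows ordinary neutral daily content"), mimicking expert rationales that
quote the post as evidence. This is load-bearing: because gold tokens are
mostly demonstration tokens, a candidate that copies more of the gold is
also more similar to the ranking query, so overlap quality is recoverable by
the ranker and the ranking-vs-factuality experiments measure something real.

Candidate explanations hit their quality targets by construction: candidate
`i` keeps `round(q_i · m)` of the gold's `m` unique tokens and pads to `m`
with distractors disjoint from the gold, so its factuality is `q_i` up to
rounding (golds shorter than 5 tokens are rejected). Default
`quality_levels = (1.0, 0.5, 0.0)` with 3 candidates per demonstration.
With probability `redundancy_rate` (default 0.15) a later candidate is a
token-shuffle of an earlier one — the same token set, so set-based
similarity sees a perfect duplicate and the MMR penalty is exercised
maximally.

What passing the synthetic experiments shows: the selection machinery
prefers high-overlap, non-redundant explanations when relevance is encoded
lexically, and informative prompts never hurt the lexicon scorer. What it
does not show: anything about linguistically realistic depressive text,
real encoder geometry, or real LLM scorers — the lexicon classifier is
perfect on noiseless synthetic labels by construction, so downstream
metrics sit near ceiling and comparisons there are directional only.

## Problem sizes and numerics

The shipped experiments use 12-demonstration bundles over 100 seeds for the
factuality-lift trials, and 200-conversation corpora × 20 candidate pools ×
50 paired seeded runs for the zero-shot vs five-shot comparison; the random
scorer calibration uses 1,000 pools drawn from a 10,000-utterance corpus
against the exact binomial 99% interval around 0.1 — the pool is large so
candidate sets share few utterances; with smaller corpora the same utterance
(hence the same hash score) recurs across sets and inflates the variance
roughly threefold beyond the iid binomial. Greedy ties use an absolute epsilon of 1e-15 (first/lowest index
wins); float serialization uses `repr` round-tripping, so re-reading ranked
output reproduces scores exactly.

## Known limitations

- A demonstration is modeled as a single text span; threaded posts are out
  of scope.
- The learned demonstration retriever, LLM explanation generation, and soft
  prompt/verbalizer training are contracts only; their default
  implementations are deterministic mocks.
- The DSI threshold interacts poorly with prompt-shifted mock scores (see
  above); real scorers should be calibrated before thresholding.
- The factuality metric's max-over-golds reading of the overlap definition
  is one of two typographically plausible bindings; it is fixed here and
  flagged rather than silently varied.
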