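"""Factuality and consistency metrics for free-text explanations.

Factuality is lexical: the fraction of a candidate explanation's token set
that also appears in the best-matching gold (expert-written) explanation,
    factuality(e) = max_g |tokens(e) ∩ tokens(g)| / |tokens(e)|.
Set semantics — duplicated tokens in the candidate neither help nor hurt.

Consistency is semantic: a BERTScore-style greedy token alignment between a
candidate explanation and its reference context (the demonstration plus its
label description, or a gold explanation), using per-token embeddings from
the configured backend.  Recall averages, over reference tokens, each token's
best match in the candidate; precision is the mirror image; F1 is their
harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import Explanation, GoldExplanation
from .embeddings import clip01, cosine_similarity
from .tokens import TokenSet, tokenize

__all__ = ["TokenSet", "tokenize", "factuality", "consistency", "ConsistencyReport"]

_STOP_WORDS = frozenset(
    "a an the and or but of to in on at for with is are was were be been it "
    "its this that these those i you he she they we".split()
)


@dataclass(frozen=True)
class ConsistencyReport:
    precision: float
    recall: float
    f1: float
    matched_pairs: tuple[tuple[str, str, float], ...]


def _text_of(obj) -> str:
    return obj.text if hasattr(obj, "text") else str(obj)


def factuality(candidate, golds) -> float:
    """Max token-overlap of the candidate with any gold reference, in [0, 1]."""
    if isinstance(golds, (GoldExplanation, str)):
        golds = [golds]
    if not golds:
        raise ValueError("need at least one gold explanation")
    cand_tokens = tokenize(_text_of(candidate)).tokens
    if not cand_tokens:
        raise ValueError("candidate tokenizes to an empty set (overlap undefined)")
    best = 0.0
    for gold in golds:
        gold_tokens = tokenize(_text_of(gold)).tokens
        best = max(best, len(cand_tokens & gold_tokens) / len(cand_tokens))
    return best


def consistency(
    candidate,
    reference,
    backend,
    remove_stop_words: bool = False,
) -> ConsistencyReport:
    """Greedy token-matching precision/recall/F1 between candidate and reference.

    Token-level embeddings come from the backend (``embed_token`` when
    available, else ``embed`` on the single token); similarities are clipped
    to [0, 1] before averaging.
    """
    cand_tokens = sorted(tokenize(_text_of(candidate)).tokens)
    ref_tokens = sorted(tokenize(_text_of(reference)).tokens)
    if remove_stop_words:
        cand_tokens = [t for t in cand_tokens if t not in _STOP_WORDS] or cand_tokens
        ref_tokens = [t for t in ref_tokens if t not in _STOP_WORDS] or ref_tokens
    if not cand_tokens or not ref_tokens:
        raise ValueError("both candidate and reference must tokenize non-empty")

    embed_token = getattr(backend, "embed_token", backend.embed)
    cand_vecs = {t: embed_token(t) for t in cand_tokens}
    ref_vecs = {t: embed_token(t) for t in ref_tokens}

    def best_match(token_vec, pool):
        best_tok, best_sim = None, -1.0
        for tok, vec in pool.items():
            sim = clip01(cosine_similarity(token_vec, vec))
            if sim > best_sim:
                best_tok, best_sim = tok, sim
        return best_tok, best_sim

    pairs = []
    precision_terms = []
    for tok in cand_tokens:
        match, sim = best_match(cand_vecs[tok], ref_vecs)
        precision_terms.append(sim)
        pairs.append((tok, match, sim))
    recall_terms = []
    for tok in ref_tokens:
        _, sim = best_match(ref_vecs[tok], cand_vecs)
        recall_terms.append(sim)

    precision = sum(precision_terms) / len(precision_terms)
    recall = sum(recall_terms) / len(recall_terms)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return ConsistencyReport(
        precision=precision, recall=recall, f1=f1, matched_pairs=tuple(pairs)
    )
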