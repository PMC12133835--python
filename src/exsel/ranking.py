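"""Hybrid explanation ranking: expected reciprocal rank + maximal marginal
relevance.

Candidate free-text explanations are scored for relevance against the query,
the retrieved demonstrations, and a list of diagnostic-criteria statements
(DSM-5-style), all in one embedding space.  Raw relevance scores are
sum-normalized into relevance probabilities p_i.  Selection is a greedy loop:
at each rank the candidate maximizing

    S_comb = ERR-contribution(p, already-selected) + MMR(candidate)

is taken, where the ERR contribution at position k is the cascade-model term
(1/k) * prod_{i<k} (1 - gamma * p_i) * gamma * p_k (discounting candidates by
the probability an earlier pick already satisfied the user), and MMR is
lambda * sim(candidate, query) - (1 - lambda) * max sim(candidate, selected)
(penalizing redundancy with what is already chosen).

Defaults gamma=0.85, lambda=0.5, k=2 select the top two explanations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .corpus import Conversation, Demonstration, Explanation, RankedItem, RankedSelection
from .embeddings import clip01, cosine_similarity


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of the hybrid selector.

    gamma: ERR decay in (0, 1] — the chance a relevant item at an earlier
        rank already satisfied the user.
    lam: MMR relevance/diversity trade-off in [0, 1] (1 = pure relevance).
    k: number of explanations to select.
    criteria_weight: mixing weight in [0, 1] between similarity to the
        query+demonstrations (weight 1-w) and the best-matching diagnostic
        criterion (weight w).
    """

    gamma: float = 0.85
    lam: float = 0.5
    k: int = 2
    criteria_weight: float = 0.5
    tie_break: Literal["lowest_index"] = "lowest_index"

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not (0.0 <= self.criteria_weight <= 1.0):
            raise ValueError(f"criteria_weight must be in [0, 1], got {self.criteria_weight}")


@dataclass(frozen=True)
class RelevanceProfile:
    """Normalized relevance probabilities over a candidate pool."""

    candidate_ids: tuple[str, ...]
    probs: tuple[float, ...]
    normalization: Literal["sum", "softmax", "none"] = "sum"

    def __post_init__(self):
        if len(self.candidate_ids) != len(self.probs):
            raise ValueError("candidate_ids and probs must align")
        for p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"relevance probability {p} outside [0, 1]")

    def prob_of(self, candidate_id: str) -> float:
        return self.probs[self.candidate_ids.index(candidate_id)]


def _query_text(query) -> str:
    if isinstance(query, Conversation):
        return query.joined_text()
    if hasattr(query, "text"):
        return query.text
    return str(query)


def relevance_probabilities(
    candidates: Sequence[Explanation],
    query,
    demos: Sequence[Demonstration],
    criteria: Sequence[str],
    backend,
    config: RankingConfig = RankingConfig(),
) -> RelevanceProfile:
    """Relevance probabilities p_i for each candidate explanation.

    Raw score of candidate e:
        (1-w) * mean over {query} + demos of clip01(cos(e, .))
        +  w  * max over criteria of clip01(cos(e, .))
    then sum-normalized (uniform when every raw score is 0).
    """
    if not candidates:
        raise ValueError("need at least one candidate explanation")
    w = config.criteria_weight
    if w > 0 and not criteria:
        raise ValueError("criteria_weight > 0 requires at least one criteria string")

    context_vecs = [backend.embed(_query_text(query))]
    context_vecs += [backend.embed(d.text) for d in demos]
    criteria_vecs = [backend.embed(c) for c in criteria] if criteria else []

    raw = []
    for cand in candidates:
        e = backend.embed(cand.text)
        ctx = float(np.mean([clip01(cosine_similarity(e, v)) for v in context_vecs]))
        if criteria_vecs:
            crit = max(clip01(cosine_similarity(e, v)) for v in criteria_vecs)
        else:
            crit = 0.0
        raw.append((1.0 - w) * ctx + w * crit)

    total = sum(raw)
    if total > 0.0:
        probs = tuple(min(r / total, 1.0) for r in raw)
    else:
        probs = tuple(1.0 / len(raw) for _ in raw)
    return RelevanceProfile(
        candidate_ids=tuple(c.expl_id for c in candidates),
        probs=probs,
        normalization="sum",
    )


def err_score(probs: Sequence[float], gamma: float) -> float:
    """Expected reciprocal rank of an ordered relevance-probability list.

    ERR = sum_{k=1..n} (1/k) * prod_{i<k} (1 - gamma*p_i) * gamma*p_k.
    Empty list -> 0.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    score = 0.0
    not_satisfied = 1.0
    for k, p in enumerate(probs, start=1):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
        score += (1.0 / k) * not_satisfied * gamma * p
        not_satisfied *= 1.0 - gamma * p
    return score


def err_contribution(p_cand: float, selected_probs: Sequence[float], gamma: float) -> float:
    """ERR term a candidate would add at position len(selected_probs) + 1.

    Summing contributions along any ordering reproduces err_score exactly.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if not (0.0 <= p_cand <= 1.0):
        raise ValueError(f"probability {p_cand} outside [0, 1]")
    discount = 1.0
    for p in selected_probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
        discount *= 1.0 - gamma * p
    k = len(selected_probs) + 1
    return (1.0 / k) * discount * gamma * p_cand


def mmr_score(cand_query_sim: float, cand_selected_sims: Sequence[float], lam: float) -> float:
    """Maximal marginal relevance of one candidate.

    lambda * sim(candidate, query) - (1 - lambda) * max sim(candidate,
    selected); the max over an empty selected set is 0.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if not (0.0 <= cand_query_sim <= 1.0):
        raise ValueError(f"similarity {cand_query_sim} outside [0, 1] (clip first)")
    for s in cand_selected_sims:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"similarity {s} outside [0, 1] (clip first)")
    redundancy = max(cand_selected_sims, default=0.0)
    return lam * cand_query_sim - (1.0 - lam) * redundancy


def hybrid_select(
    candidates: Sequence[Explanation],
    profile: RelevanceProfile,
    query,
    backend,
    config: RankingConfig = RankingConfig(),
) -> RankedSelection:
    """Greedy top-k selection by combined ERR-contribution + MMR score.

    Ties break to the lowest candidate index; stops early when the pool is
    exhausted.  Each selected item records its combined score and the two
    components at the moment of selection.
    """
    if config.k < 1:
        raise ValueError(f"k must be >= 1, got {config.k}")
    ids = {c.expl_id for c in candidates}
    if ids - set(profile.candidate_ids) or len(ids) != len(candidates):
        raise ValueError("profile must cover every candidate exactly once")

    q_vec = backend.embed(_query_text(query))
    cand_vecs = [backend.embed(c.text) for c in candidates]
    query_sims = [clip01(cosine_similarity(v, q_vec)) for v in cand_vecs]
    probs = [profile.prob_of(c.expl_id) for c in candidates]

    selected: list[RankedItem] = []
    selected_idx: list[int] = []
    selected_probs: list[float] = []
    remaining = list(range(len(candidates)))
    for _ in range(min(config.k, len(candidates))):
        best = None
        for j in remaining:
            err_term = err_contribution(probs[j], selected_probs, config.gamma)
            sims_to_sel = [
                clip01(cosine_similarity(cand_vecs[j], cand_vecs[i])) for i in selected_idx
            ]
            mmr_term = mmr_score(query_sims[j], sims_to_sel, config.lam)
            s_comb = err_term + mmr_term
            if best is None or s_comb > best[0] + 1e-15:
                best = (s_comb, err_term, mmr_term, j)
        s_comb, err_term, mmr_term, j = best
        selected.append(
            RankedItem(
                expl_id=candidates[j].expl_id,
                s_comb=s_comb,
                err_term=err_term,
                mmr_term=mmr_term,
            )
        )
        selected_idx.append(j)
        selected_probs.append(probs[j])
        remaining.remove(j)
    return RankedSelection(selected=tuple(selected), pool_size=len(candidates))


def read_criteria(path) -> list[str]:
    """Plain-text criteria file: one statement per line, '#' comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
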