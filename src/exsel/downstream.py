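"""Downstream depression-screening tasks and their evaluation harnesses.

Two tasks:

* DUC (depressed utterance classification) — among candidate pools of 10
  utterances containing exactly one gold-depressed utterance, score every
  candidate and check whether the top-ranked one is the depressed one.  The
  metric is R10@1, the hit rate over pools.
* DSI (depressed speaker identification) — flag a speaker as depressed when
  any of their utterances scores at or above a threshold; the metric is F1
  over (conversation, speaker) pairs against gold speakers (those who uttered
  at least one gold-depressed utterance).

Training losses mirror the matching-probability formulation: binary
cross-entropy per utterance for DUC, and cross-entropy summed over
same-speaker positive pairs for DSI.

Scorers are pluggable: anything mapping (prompt, candidate text) -> [0, 1]
deterministically.  The default mock scorer reuses the verbalizer classifier
on the candidate text concatenated with the prompt's demonstration and
explanation blocks, which closes the loop with the synthetic corpus.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Protocol, Sequence

from sklearn.metrics import f1_score

from .corpus import Conversation, Demonstration, Explanation, GoldExplanation, Utterance
from .prompting import (
    LexiconProvider,
    Verbalizer,
    classify_utterance,
    default_verbalizer,
    render_demo_block,
    select_explanation_texts,
)
from .ranking import RankingConfig, hybrid_select, relevance_probabilities

_EPS = 1e-12


class ContractViolation(RuntimeError):
    """A scorer returned a value outside [0, 1]."""


@dataclass(frozen=True)
class CandidateSet:
    """Ten utterances, exactly one gold-depressed."""

    set_id: str
    candidates: tuple[Utterance, ...]
    positive_id: str

    def __post_init__(self):
        if len(self.candidates) != 10:
            raise ValueError(f"candidate set must have exactly 10 utterances, got {len(self.candidates)}")
        if self.positive_id not in {u.utterance_id for u in self.candidates}:
            raise ValueError("positive_id must reference a candidate")


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment arm: shots x explanations x ranking x order."""

    shots: int = 5
    use_explanations: bool = True
    n_explanations: int = 2
    explanation_order: Literal["most_to_least", "least_to_most"] = "most_to_least"
    use_ranking: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.shots < 0:
            raise ValueError(f"shots must be >= 0, got {self.shots}")
        if not (1 <= self.n_explanations <= 3):
            raise ValueError(f"n_explanations must be in 1..3, got {self.n_explanations}")


@dataclass(frozen=True)
class EvaluationReport:
    metric: str
    value: float
    n_items: int
    config: Mapping[str, object] = field(default_factory=dict)
    per_item: tuple[Mapping[str, object], ...] = ()


class Scorer(Protocol):
    name: str

    def __call__(self, prompt: str, text: str) -> float: ...


class MockScorer:
    """Depression class-probability of candidate text + prompt blocks."""

    name = "verbalizer-mock"

    def __init__(self, verbalizer: Verbalizer | None = None):
        self.verbalizer = verbalizer or default_verbalizer()
        self._provider = LexiconProvider(self.verbalizer)

    def __call__(self, prompt: str, text: str) -> float:
        context = f"{text} {prompt}".strip()
        result = classify_utterance(context, self.verbalizer, self._provider)
        return result.class_probs.get("depression", 0.0)


class OracleScorer:
    """U = 1 exactly for gold-depressed utterances (testing aid)."""

    name = "oracle"

    def __init__(self, invert: bool = False):
        self.invert = invert

    def score_utterance(self, u: Utterance) -> float:
        hit = 1.0 if u.gold_label == "depression" else 0.0
        return 1.0 - hit if self.invert else hit

    def __call__(self, prompt: str, text: str) -> float:  # pragma: no cover
        raise NotImplementedError("oracle scores Utterance objects, use score_utterance")


class RandomScorer:
    """Seeded hash-uniform scorer: deterministic given (seed, prompt, text)."""

    name = "hash-uniform"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def __call__(self, prompt: str, text: str) -> float:
        digest = hashlib.blake2b(
            f"{self.seed}|{prompt}|{text}".encode("utf-8"), digest_size=8
        ).digest()
        return int.from_bytes(digest, "big") / float(2**64)


# ---------------------------------------------------------------------------
# Losses


def duc_loss(u: float, z: int) -> float:
    """Binary cross-entropy of a matching probability against its label."""
    if z not in (0, 1):
        raise ValueError(f"z must be 0 or 1, got {z!r}")
    u = min(max(float(u), _EPS), 1.0 - _EPS)
    return -(z * math.log(u) + (1 - z) * math.log(1.0 - u))


def dsi_loss(pair_probs: Sequence[tuple[float, int]]) -> float:
    """Cross-entropy over same-speaker positive pairs: -sum log(u_ij).

    Pairs with same_speaker = 0 contribute nothing; an empty list returns 0
    with a warning.
    """
    if not pair_probs:
        warnings.warn("dsi_loss called with no pairs", stacklevel=2)
        return 0.0
    total = 0.0
    for u, same in pair_probs:
        if same not in (0, 1):
            raise ValueError(f"same_speaker must be 0 or 1, got {same!r}")
        if same:
            total += -math.log(min(max(float(u), _EPS), 1.0 - _EPS))
    return total


# ---------------------------------------------------------------------------
# Metrics


def _score_candidate(scorer, prompt: str, u: Utterance) -> float:
    if isinstance(scorer, OracleScorer):
        val = scorer.score_utterance(u)
    else:
        val = scorer(prompt, u.text)
    if not (0.0 <= val <= 1.0):
        raise ContractViolation(f"scorer {getattr(scorer, 'name', scorer)!r} returned {val}")
    return float(val)


def recall_at_1_of_10(
    sets: Sequence[CandidateSet], scorer, prompt: str = ""
) -> EvaluationReport:
    """R10@1: fraction of pools whose top-scored candidate is the depressed one.

    Ties rank by lowest candidate index within the pool.
    """
    if not sets:
        raise ValueError("need at least one candidate set")
    per_item = []
    hits = 0
    for cs in sets:
        scored = [
            (-_score_candidate(scorer, prompt, u), idx, u.utterance_id)
            for idx, u in enumerate(cs.candidates)
        ]
        top_id = min(scored)[2]
        hit = top_id == cs.positive_id
        hits += hit
        per_item.append({"set_id": cs.set_id, "top": top_id, "hit": bool(hit)})
    return EvaluationReport(
        metric="R10@1",
        value=hits / len(sets),
        n_items=len(sets),
        per_item=tuple(per_item),
    )


def gold_depressed_speakers(conversations: Sequence[Conversation]) -> set[tuple[str, str]]:
    """Speakers with at least one gold-depressed utterance, keyed per conversation."""
    gold = set()
    for conv in conversations:
        for u in conv.utterances:
            if u.gold_label == "depression":
                gold.add((conv.conversation_id, u.speaker_id))
    return gold


def dsi_f1(
    conversations: Sequence[Conversation],
    scorer,
    prompt: str = "",
    threshold: float = 0.5,
) -> EvaluationReport:
    """Speaker-level F1: predict depressed iff any utterance scores >= threshold."""
    gold = gold_depressed_speakers(conversations)
    if not gold:
        raise ValueError("no gold depressed speakers in the conversations")
    y_true, y_pred, per_item = [], [], []
    for conv in conversations:
        best: dict[str, float] = {}
        for u in conv.utterances:
            val = _score_candidate(scorer, prompt, u)
            best[u.speaker_id] = max(best.get(u.speaker_id, 0.0), val)
        for speaker, val in sorted(best.items()):
            key = (conv.conversation_id, speaker)
            y_true.append(key in gold)
            y_pred.append(val >= threshold)
            per_item.append(
                {
                    "conversation_id": conv.conversation_id,
                    "speaker_id": speaker,
                    "max_score": val,
                    "gold": key in gold,
                    "predicted": bool(val >= threshold),
                }
            )
    value = float(f1_score(y_true, y_pred, zero_division=0))
    return EvaluationReport(
        metric="DSI-F1",
        value=value,
        n_items=len(y_true),
        config={"threshold": threshold},
        per_item=tuple(per_item),
    )


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass(frozen=True)
class Bundle:
    """Everything one experiment needs, loaded or synthesized."""

    conversations: tuple[Conversation, ...]
    demonstrations: tuple[Demonstration, ...]
    explanations: tuple[Explanation, ...]
    golds: tuple[GoldExplanation, ...]
    candidate_sets: tuple[CandidateSet, ...] = ()

    def explanations_for(self, demo_id: str) -> list[Explanation]:
        return [e for e in self.explanations if e.demo_id == demo_id]


def build_prompt(
    bundle: Bundle,
    config: ExperimentConfig,
    ranking_config: RankingConfig,
    backend,
    criteria: Sequence[str],
) -> str:
    """Serialize the demonstration/explanation blocks for one experiment arm.

    Demos are drawn (seeded) from the bundle; per demo, explanations are
    either the hybrid-ranked top-n (ranked against the demo text as query)
    or the first n candidates in generation order for the "w/o ranking" arm.
    """
    import numpy as np

    if config.shots > len(bundle.demonstrations):
        raise ValueError(
            f"shots={config.shots} exceeds available demonstrations ({len(bundle.demonstrations)})"
        )
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(bundle.demonstrations), size=config.shots, replace=False)
    blocks = []
    rcfg = RankingConfig(
        gamma=ranking_config.gamma,
        lam=ranking_config.lam,
        k=config.n_explanations,
        criteria_weight=ranking_config.criteria_weight,
    )
    for i in sorted(int(j) for j in idx):
        demo = bundle.demonstrations[i]
        chosen: Sequence[Explanation] = ()
        if config.use_explanations:
            pool = bundle.explanations_for(demo.demo_id)
            if pool:
                if config.use_ranking:
                    profile = relevance_probabilities(
                        pool, demo.text, [demo], criteria, backend, rcfg
                    )
                    selection = hybrid_select(pool, profile, demo.text, backend, rcfg)
                    chosen = select_explanation_texts(
                        selection, pool, n=config.n_explanations, order=config.explanation_order
                    )
                else:
                    chosen = pool[: config.n_explanations]
                    if config.explanation_order == "least_to_most":
                        chosen = list(chosen)[::-1]
        blocks.append(render_demo_block(demo, chosen))
    return " ".join(blocks)


def run_experiment(
    bundle: Bundle,
    config: ExperimentConfig,
    ranking_config: RankingConfig,
    backend,
    criteria: Sequence[str],
    task: Literal["duc", "dsi"] = "duc",
    scorer=None,
    verbalizer: Verbalizer | None = None,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Run one fully-seeded experiment arm and report its metric."""
    scorer = scorer or MockScorer(verbalizer)
    prompt = build_prompt(bundle, config, ranking_config, backend, criteria)
    if task == "duc":
        if not bundle.candidate_sets:
            raise ValueError("bundle has no DUC candidate sets")
        report = recall_at_1_of_10(bundle.candidate_sets, scorer, prompt)
    elif task == "dsi":
        report = dsi_f1(bundle.conversations, scorer, prompt, threshold=threshold)
    else:
        raise ValueError(f"unknown task {task!r}")
    echo = {
        "task": task,
        "shots": config.shots,
        "use_explanations": config.use_explanations,
        "n_explanations": config.n_explanations,
        "explanation_order": config.explanation_order,
        "use_ranking": config.use_ranking,
        "seed": config.seed,
        "scorer": getattr(scorer, "name", str(scorer)),
    }
    return EvaluationReport(
        metric=report.metric,
        value=report.value,
        n_items=report.n_items,
        config={**report.config, **echo},
        per_item=report.per_item,
    )
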