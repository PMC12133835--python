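"""Synthetic corpus generator: conversations, demonstrations, gold
explanations, and candidate explanations with controlled quality and
redundancy.

The generator emulates the *structure* of social-media depression corpora —
multi-speaker conversations of 5/10/15 utterances in which a minority of
utterances (and speakers) carry depressive lexicon words — not their
linguistic content.  Its two contracts close the test loop for the rest of
the package:

* label/lexicon consistency — an utterance is gold-labeled "depression"
  exactly when its text was seeded with a depressive label word, so the
  lexicon verbalizer classifier recovers gold labels perfectly at zero noise;
* controlled explanation quality — candidate i for a demonstration copies a
  ``quality_levels[i]`` fraction of the gold explanation's tokens and pads
  with neutral distractors, so its token-overlap factuality lands on the
  target by construction, and near-duplicates (token shuffles) exercise the
  redundancy penalty of the ranker maximally under set-based similarity.

Everything is driven by one numpy Generator seeded from the config, so a
given (config, seed) reproduces byte-identical JSONL output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .corpus import (
    Conversation,
    Demonstration,
    Explanation,
    GoldExplanation,
    Utterance,
)
from .downstream import Bundle, CandidateSet
from .prompting import Verbalizer, default_verbalizer
from .tokens import tokenize


class GenerationError(ValueError):
    """Raised when a generation target cannot be met."""


def load_distractors() -> tuple[str, ...]:
    text = resources.files("exsel.data").joinpath("distractors.txt").read_text("utf-8")
    return tuple(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_conversations: int = 50
    session_length: int = 5
    n_speakers: int = 3
    depressed_utterance_fraction: float = 0.2
    depressed_speaker_fraction: float = 0.33
    candidates_per_demo: int = 3
    quality_levels: tuple[float, ...] = (1.0, 0.5, 0.0)
    redundancy_rate: float = 0.15
    n_demonstrations: int = 12
    label_flip_rate: float = 0.0

    def __post_init__(self):
        for name in (
            "depressed_utterance_fraction",
            "depressed_speaker_fraction",
            "redundancy_rate",
            "label_flip_rate",
        ):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.candidates_per_demo < 1:
            raise ValueError("candidates_per_demo must be >= 1")
        if len(self.quality_levels) != self.candidates_per_demo:
            raise ValueError(
                "quality_levels length must equal candidates_per_demo "
                f"({len(self.quality_levels)} vs {self.candidates_per_demo})"
            )
        if any(not (0.0 <= q <= 1.0) for q in self.quality_levels):
            raise ValueError("quality_levels must lie in [0, 1]")
        if self.n_speakers < 2:
            raise ValueError("n_speakers must be >= 2")
        if self.n_speakers > self.session_length:
            raise ValueError(
                f"n_speakers ({self.n_speakers}) cannot exceed session_length "
                f"({self.session_length})"
            )


def _lexicons(verbalizer: Verbalizer | None) -> tuple[tuple[str, ...], tuple[str, ...]]:
    v = verbalizer or default_verbalizer()
    normal = v.words_of("normal")
    depressed = v.words_of("depression")
    if not normal or not depressed:
        raise GenerationError("lexicons must contain at least one word per class")
    return normal, depressed


def _neutral_text(rng: np.random.Generator, distractors: Sequence[str], n: int) -> list[str]:
    return [distractors[i] for i in rng.choice(len(distractors), size=n, replace=False)]


def generate_conversations(
    config: GeneratorConfig,
    verbalizer: Verbalizer | None = None,
    rng: np.random.Generator | None = None,
) -> list[Conversation]:
    """Deterministic multi-speaker conversations with seeded gold labels.

    Each conversation has exactly ``session_length`` utterances over
    ``n_speakers`` speakers.  An utterance is depressed with probability
    ``depressed_utterance_fraction``; depressed utterances contain 1-2
    depressive label words and are attributed to a designated depressed
    speaker with probability 0.95.  Normal utterances contain only neutral
    distractor words, occasionally one normal-class label word.
    """
    normal_words, dep_words = _lexicons(verbalizer)
    distractors = load_distractors()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    conversations = []
    for ci in range(config.n_conversations):
        speakers = [f"c{ci}_s{si}" for si in range(config.n_speakers)]
        if config.depressed_utterance_fraction > 0:
            n_dep_speakers = max(
                1, round(config.depressed_speaker_fraction * config.n_speakers)
            )
        else:
            n_dep_speakers = 0
        dep_speakers = speakers[:n_dep_speakers]
        normal_speakers = speakers[n_dep_speakers:] or speakers
        utterances = []
        for pos in range(config.session_length):
            depressed = bool(rng.random() < config.depressed_utterance_fraction)
            words = _neutral_text(rng, distractors, int(rng.integers(4, 8)))
            if depressed:
                n_seed = int(rng.integers(1, 3))
                seeds = [dep_words[i] for i in rng.choice(len(dep_words), size=n_seed, replace=False)]
                for w in seeds:
                    words.insert(int(rng.integers(0, len(words) + 1)), w)
                if dep_speakers and rng.random() < 0.95:
                    speaker = dep_speakers[int(rng.integers(0, len(dep_speakers)))]
                else:
                    speaker = normal_speakers[int(rng.integers(0, len(normal_speakers)))]
            else:
                if rng.random() < 0.3:
                    w = normal_words[int(rng.integers(0, len(normal_words)))]
                    words.insert(int(rng.integers(0, len(words) + 1)), w)
                speaker = speakers[int(rng.integers(0, len(speakers)))]
            label = "depression" if depressed else "normal"
            if config.label_flip_rate > 0 and rng.random() < config.label_flip_rate:
                label = "normal" if label == "depression" else "depression"
            utterances.append(
                Utterance(
                    utterance_id=f"c{ci}_u{pos}",
                    speaker_id=speaker,
                    text=" ".join(words) + ".",
                    position=pos,
                    gold_label=label,
                )
            )
        conversations.append(
            Conversation(conversation_id=f"c{ci}", utterances=tuple(utterances))
        )
    return conversations


def generate_demonstrations(
    config: GeneratorConfig,
    verbalizer: Verbalizer | None = None,
    rng: np.random.Generator | None = None,
) -> list[Demonstration]:
    """Balanced labeled demonstrations shaped like single utterances."""
    normal_words, dep_words = _lexicons(verbalizer)
    distractors = load_distractors()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    demos = []
    for di in range(config.n_demonstrations):
        depressed = di % 2 == 1
        words = _neutral_text(rng, distractors, int(rng.integers(5, 9)))
        # demonstrations are exemplary labeled examples: each carries 1-2
        # class-indicative lexicon words for its own class, never the other's
        lexicon = dep_words if depressed else normal_words
        n_seed = int(rng.integers(1, 3))
        for w in (lexicon[i] for i in rng.choice(len(lexicon), size=n_seed, replace=False)):
            words.insert(int(rng.integers(0, len(words) + 1)), w)
        demos.append(
            Demonstration(
                demo_id=f"d{di}",
                text=" ".join(words) + ".",
                label="depression" if depressed else "normal",
                source="synthetic",
            )
        )
    return demos


def generate_gold_explanation(
    demo: Demonstration, rng: np.random.Generator
) -> GoldExplanation:
    """A synthetic expert rationale for one demonstration.

    Mimics how expert annotators justify a label: quote the utterance's own
    evidence words, then give a short verdict echoing diagnostic-criteria
    vocabulary.  Reusing the demonstration's tokens is what lets a
    high-overlap candidate also be the most query-relevant one, so ranking
    quality is measurable against factuality.
    """
    content = [t for t in demo.text.rstrip(".").split() if t]
    if demo.label == "depression":
        tail = "signals depressed mood and distress"
    else:
        tail = "shows ordinary neutral daily content"
    text = " ".join(content) + " " + tail
    return GoldExplanation(gold_id=f"g_{demo.demo_id}", text=text, demo_id=demo.demo_id)


def generate_explanation_candidates(
    demo: Demonstration,
    gold: GoldExplanation,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[Explanation]:
    """Candidates whose token-overlap factuality hits ``quality_levels``.

    Candidate i keeps round(q_i * m) of the gold's m unique tokens and pads
    with distractors disjoint from the gold, so |cand ∩ gold| / |cand| = q_i
    up to rounding.  With probability ``redundancy_rate`` a later candidate
    is a token-shuffle of an earlier one (same token set, same factuality).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gold_tokens = sorted(tokenize(gold.text).tokens)
    if len(gold_tokens) < 5:
        raise GenerationError(
            f"gold explanation {gold.gold_id!r} has {len(gold_tokens)} tokens; "
            "need >= 5 to hit overlap targets"
        )
    if len(config.quality_levels) != config.candidates_per_demo:
        raise GenerationError("quality_levels length must equal candidates_per_demo")
    pad_pool = [w for w in load_distractors() if w not in set(gold_tokens)]
    m = len(gold_tokens)
    candidates: list[Explanation] = []
    token_lists: list[list[str]] = []
    for i, q in enumerate(config.quality_levels):
        if candidates and rng.random() < config.redundancy_rate:
            src = token_lists[int(rng.integers(0, len(token_lists)))]
            words = list(src)
            rng.shuffle(words)
        else:
            n_gold = int(round(q * m))
            keep = [gold_tokens[j] for j in rng.choice(m, size=n_gold, replace=False)]
            n_pad = m - n_gold
            pads = [pad_pool[j] for j in rng.choice(len(pad_pool), size=n_pad, replace=False)]
            words = keep + pads
            rng.shuffle(words)
        token_lists.append(words)
        candidates.append(
            Explanation(
                expl_id=f"{demo.demo_id}_e{i}",
                text=" ".join(words),
                demo_id=demo.demo_id,
                generator="mock",
            )
        )
    return candidates


def generate_duc_candidate_sets(
    conversations: Sequence[Conversation],
    n_sets: int,
    seed: int,
) -> list[CandidateSet]:
    """Pools of 10 utterances, exactly one gold-depressed, drawn cross-conversation."""
    rng = np.random.default_rng(seed)
    depressed = [
        u for c in conversations for u in c.utterances if u.gold_label == "depression"
    ]
    normal = [u for c in conversations for u in c.utterances if u.gold_label == "normal"]
    if n_sets > 0 and (len(depressed) < 1 or len(normal) < 9):
        raise GenerationError(
            f"need >= 1 depressed and >= 9 normal utterances, have "
            f"{len(depressed)} / {len(normal)}"
        )
    sets = []
    for si in range(n_sets):
        pos = depressed[int(rng.integers(0, len(depressed)))]
        negs = [normal[i] for i in rng.choice(len(normal), size=9, replace=False)]
        members = [pos] + negs
        order = rng.permutation(10)
        members = [members[i] for i in order]
        sets.append(
            CandidateSet(
                set_id=f"set{si}",
                candidates=tuple(members),
                positive_id=pos.utterance_id,
            )
        )
    return sets


def generate_bundle(
    config: GeneratorConfig,
    verbalizer: Verbalizer | None = None,
    n_candidate_sets: int = 0,
) -> Bundle:
    """Full synthetic bundle: conversations, demos, golds, candidates, pools."""
    rng = np.random.default_rng(config.seed)
    conversations = generate_conversations(config, verbalizer, rng)
    demos = generate_demonstrations(config, verbalizer, rng)
    golds = [generate_gold_explanation(d, rng) for d in demos]
    explanations: list[Explanation] = []
    for demo, gold in zip(demos, golds):
        explanations.extend(generate_explanation_candidates(demo, gold, config, rng))
    candidate_sets: tuple[CandidateSet, ...] = ()
    if n_candidate_sets > 0:
        candidate_sets = tuple(
            generate_duc_candidate_sets(conversations, n_candidate_sets, config.seed + 1)
        )
    return Bundle(
        conversations=tuple(conversations),
        demonstrations=tuple(demos),
        explanations=tuple(explanations),
        golds=tuple(golds),
        candidate_sets=candidate_sets,
    )
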