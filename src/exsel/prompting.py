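"""Prompt assembly and verbalizer-based utterance classification.

A soft template wraps an input utterance (or whole conversation) as

    [CLS] <demo blocks> <query> <p1> [SEP] <p2> [EOS]

where p1, p2 are prompt snippets standing in for trained soft-prompt
embeddings, and demonstration blocks serialize each in-context example with
its label and selected explanations.  When the assembled prompt exceeds the
template's token budget, demonstration blocks are dropped from the end —
the query itself is never truncated.

Classification maps mask-fill probabilities of label words onto class
probabilities: p(c|x) = sum over the class's label words v of p([MASK]=v | x),
sum-normalized.  The default provider is a lexicon counter — the relative
frequency of each label word among all label-word occurrences in the context
— which keeps the whole pipeline runnable without a language model while
preserving the contract a masked-LM provider would satisfy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Protocol, Sequence

from .corpus import Conversation, Demonstration, Explanation, RankedSelection, Utterance
from .tokens import token_list


class PromptLengthError(ValueError):
    """The query alone exceeds the template's token budget."""


@dataclass(frozen=True)
class SoftTemplate:
    cls_token: str = "[CLS]"
    sep_token: str = "[SEP]"
    eos_token: str = "[EOS]"
    prompt_snippets: tuple[str, ...] = ()
    max_length: int = 3000

    def __post_init__(self):
        markers = [self.cls_token, self.sep_token, self.eos_token]
        if any(not m for m in markers) or len(set(markers)) != 3:
            raise ValueError("cls/sep/eos markers must be distinct and non-empty")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")


@dataclass(frozen=True)
class Verbalizer:
    """Ordered classes and disjoint label-word lists (class -> words)."""

    classes: tuple[str, ...] = ("normal", "depression")
    label_words: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[str] = set()
        for cls in self.classes:
            words = tuple(self.label_words.get(cls, ()))
            if not words:
                raise ValueError(f"class {cls!r} has no label words")
            lowered = {w.lower() for w in words}
            if lowered & seen:
                raise ValueError(f"label words overlap across classes: {lowered & seen}")
            seen |= lowered

    def words_of(self, cls: str) -> tuple[str, ...]:
        return tuple(self.label_words[cls])

    @property
    def all_words(self) -> tuple[str, ...]:
        return tuple(w for c in self.classes for w in self.label_words[c])


def default_verbalizer() -> Verbalizer:
    """The shipped two-class verbalizer (normal vs depression label words)."""
    payload = json.loads(
        resources.files("exsel.data").joinpath("verbalizer_default.json").read_text("utf-8")
    )
    return verbalizer_from_mapping(payload)


def verbalizer_from_mapping(payload: Mapping[str, Sequence[str]]) -> Verbalizer:
    return Verbalizer(
        classes=tuple(payload.keys()),
        label_words={c: tuple(ws) for c, ws in payload.items()},
    )


class MaskProbabilityProvider(Protocol):
    name: str

    def __call__(self, context: str, label_word: str) -> float: ...


class LexiconProvider:
    """Mask-probability stand-in: relative label-word frequency in the context.

    p(word | context) = count(word) / (1 + total label-word occurrences),
    always in [0, 1); deterministic and case-insensitive.
    """

    name = "lexicon-count"

    def __init__(self, verbalizer: Verbalizer):
        self.verbalizer = verbalizer
        self._vocabulary = {w.lower() for w in verbalizer.all_words}

    def __call__(self, context: str, label_word: str) -> float:
        toks = token_list(context)
        total = sum(1 for t in toks if t in self._vocabulary)
        count = sum(1 for t in toks if t == label_word.lower())
        return count / (1 + total)


@dataclass(frozen=True)
class ClassificationResult:
    utterance_id: str
    class_probs: Mapping[str, float]
    predicted: str


def classify_utterance(
    x: Utterance | str,
    verbalizer: Verbalizer,
    provider: MaskProbabilityProvider,
) -> ClassificationResult:
    """Class probabilities via the verbalizer; argmax prediction.

    Scores sum-normalize across classes; when every label word scores zero
    the distribution is uniform and the tie rule predicts the first class in
    order ("normal" for the default verbalizer — a screening tool should not
    default to the clinical label).
    """
    text = x.text if isinstance(x, Utterance) else str(x)
    utt_id = x.utterance_id if isinstance(x, Utterance) else ""
    scores = {
        cls: sum(provider(text, w) for w in verbalizer.words_of(cls))
        for cls in verbalizer.classes
    }
    total = sum(scores.values())
    if total > 0:
        probs = {c: s / total for c, s in scores.items()}
    else:
        probs = {c: 1.0 / len(verbalizer.classes) for c in verbalizer.classes}
    best = max(probs.values())
    predicted = next(c for c in verbalizer.classes if probs[c] >= best - 1e-12)
    return ClassificationResult(utterance_id=utt_id, class_probs=probs, predicted=predicted)


# ---------------------------------------------------------------------------
# Template assembly


def render_demo_block(
    demo: Demonstration, explanations: Sequence[Explanation] = ()
) -> str:
    parts = [f"[demo label={demo.label}] {demo.text}"]
    for e in explanations:
        parts.append(f"[explanation] {e.text}")
    return " ".join(parts)


def _token_count(text: str) -> int:
    return len(text.split())


def assemble_template(
    x: Utterance | Conversation | str,
    template: SoftTemplate,
    demos: Sequence[Demonstration] = (),
    explanations_by_demo: Mapping[str, Sequence[Explanation]] | None = None,
) -> str:
    """Assemble the full prompt string for input ``x``.

    Demonstration blocks precede the query; blocks are dropped from the end
    of the demo list until the whitespace-token count fits ``max_length``.
    The query and snippet tail are never truncated — a query that alone
    overflows the budget raises :class:`PromptLengthError`.
    """
    if isinstance(x, Conversation):
        query = x.joined_text()
    elif isinstance(x, Utterance):
        query = x.text
    else:
        query = str(x)

    snippets = list(template.prompt_snippets)
    p1 = snippets[0] if len(snippets) >= 1 else ""
    p2 = " ".join(snippets[1:]) if len(snippets) >= 2 else ""

    def build(blocks: Sequence[str]) -> str:
        head = [template.cls_token, *blocks, query]
        if p1:
            head.append(p1)
        tail = [template.sep_token]
        if p2:
            tail.append(p2)
        tail.append(template.eos_token)
        return " ".join(head + tail)

    if _token_count(build([])) > template.max_length:
        raise PromptLengthError(
            f"query alone exceeds max_length={template.max_length} tokens"
        )

    expl_map = explanations_by_demo or {}
    blocks = [render_demo_block(d, expl_map.get(d.demo_id, ())) for d in demos]
    while blocks and _token_count(build(blocks)) > template.max_length:
        blocks.pop()  # drop from the demonstration end, never the query
    return build(blocks)


def select_explanation_texts(
    selection: RankedSelection,
    pool: Sequence[Explanation],
    n: int | None = None,
    order: str = "most_to_least",
) -> list[Explanation]:
    """Resolve a ranked selection back to explanation objects, in rank order."""
    by_id = {e.expl_id: e for e in pool}
    chosen = [by_id[item.expl_id] for item in selection.selected]
    if n is not None:
        chosen = chosen[:n]
    if order == "least_to_most":
        chosen = chosen[::-1]
    elif order != "most_to_least":
        raise ValueError(f"unknown explanation order {order!r}")
    return chosen
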