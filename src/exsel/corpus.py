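"""Domain types for multi-party conversations, demonstrations and
explanations, plus line-oriented JSONL readers and writers.

A conversation is an ordered list of utterances from two or more speakers;
utterances optionally carry a gold label ("normal", "depression", or
"unknown" for unlabeled queries).  A demonstration is a labeled in-context
example retrieved for a query, and an explanation is a free-text rationale
attached to one demonstration.  All files are UTF-8 JSONL, one record per
line, so corpora stream and diff cleanly.
"""

from __future__ import annotations

import json
from typing import Iterable, Literal, Sequence

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

Label = Literal["normal", "depression"]
UtteranceLabel = Literal["normal", "depression", "unknown"]

SESSION_LENGTH_CLASSES = {5: "Len-5", 10: "Len-10", 15: "Len-15"}


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus records."""


class Utterance(BaseModel):
    model_config = ConfigDict(frozen=True)

    utterance_id: str
    speaker_id: str
    text: str
    position: int = Field(ge=0)
    gold_label: UtteranceLabel = "unknown"

    @model_validator(mode="after")
    def _non_blank_text(self) -> "Utterance":
        if not self.text.strip():
            raise ValueError("text must be non-empty after whitespace stripping")
        return self


class Conversation(BaseModel):
    model_config = ConfigDict(frozen=True)

    conversation_id: str
    utterances: tuple[Utterance, ...]
    session_length_class: Literal["Len-5", "Len-10", "Len-15", "other"] = "other"

    @model_validator(mode="before")
    @classmethod
    def _default_length_class(cls, data):
        if isinstance(data, dict) and "session_length_class" not in data:
            utts = data.get("utterances") or ()
            data = dict(data)
            data["session_length_class"] = SESSION_LENGTH_CLASSES.get(len(utts), "other")
        return data

    @model_validator(mode="after")
    def _invariants(self) -> "Conversation":
        n = len(self.utterances)
        if n < 2:
            raise ValueError("utterances: a conversation needs at least 2 utterances")
        positions = [u.position for u in self.utterances]
        if positions != list(range(n)):
            raise ValueError("utterances: positions must be 0-based, unique and contiguous")
        expected = SESSION_LENGTH_CLASSES.get(n, "other")
        if self.session_length_class != expected:
            raise ValueError(
                f"session_length_class: {self.session_length_class!r} inconsistent "
                f"with {n} utterances (expected {expected!r})"
            )
        return self

    @property
    def speaker_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for u in self.utterances:
            seen.setdefault(u.speaker_id, None)
        return tuple(seen)

    def joined_text(self, sep: str = " | ") -> str:
        return sep.join(u.text for u in self.utterances)


class Demonstration(BaseModel):
    model_config = ConfigDict(frozen=True)

    demo_id: str
    text: str
    label: Label
    source: str = ""


class Explanation(BaseModel):
    model_config = ConfigDict(frozen=True)

    expl_id: str
    text: str
    demo_id: str
    generator: str = "mock"

    @model_validator(mode="after")
    def _non_blank(self) -> "Explanation":
        if not self.text.strip():
            raise ValueError("text must be non-empty")
        return self


class GoldExplanation(BaseModel):
    model_config = ConfigDict(frozen=True)

    gold_id: str
    text: str
    demo_id: str

    @model_validator(mode="after")
    def _non_blank(self) -> "GoldExplanation":
        if not self.text.strip():
            raise ValueError("text must be non-empty")
        return self


class RankedItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    expl_id: str
    s_comb: float
    err_term: float
    mmr_term: float


class RankedSelection(BaseModel):
    """Ordered top-k explanations with their combined greedy scores."""

    model_config = ConfigDict(frozen=True)

    selected: tuple[RankedItem, ...]
    pool_size: int = Field(ge=0)

    @model_validator(mode="after")
    def _distinct(self) -> "RankedSelection":
        ids = [it.expl_id for it in self.selected]
        if len(ids) != len(set(ids)):
            raise ValueError("selected: explanation ids must be distinct")
        if len(ids) > self.pool_size:
            raise ValueError("selected: cannot exceed pool_size")
        return self


# ---------------------------------------------------------------------------
# JSONL I/O


def _read_jsonl(path, model):
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            try:
                records.append(model.model_validate(payload))
            except ValidationError as exc:
                fields = ", ".join(
                    ".".join(str(p) for p in err["loc"]) or "<record>"
                    for err in exc.errors()
                )
                raise CorpusError(
                    f"{path}:{lineno}: invalid {model.__name__} (field(s): {fields}): {exc}"
                ) from exc
    return records


def _write_jsonl(path, records: Iterable[BaseModel]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.model_dump(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")


def read_conversations(path) -> list[Conversation]:
    """Read one :class:`Conversation` per JSONL line; fail loudly with line numbers."""
    return _read_jsonl(path, Conversation)


def read_demonstrations(path) -> list[Demonstration]:
    return _read_jsonl(path, Demonstration)


def read_explanations(path) -> list[Explanation]:
    return _read_jsonl(path, Explanation)


def read_gold_explanations(path) -> list[GoldExplanation]:
    return _read_jsonl(path, GoldExplanation)


write_conversations = _write_jsonl
write_demonstrations = _write_jsonl
write_explanations = _write_jsonl
write_gold_explanations = _write_jsonl


def write_ranked_selection(selection: RankedSelection, path) -> None:
    """One JSON object per selected explanation: rank, expl_id, score terms.

    Floats serialize via ``repr`` (17 significant digits) so a round-trip
    through the reader reproduces scores exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rank, item in enumerate(selection.selected, start=1):
            fh.write(
                json.dumps(
                    {
                        "rank": rank,
                        "expl_id": item.expl_id,
                        "s_comb": item.s_comb,
                        "err_term": item.err_term,
                        "mmr_term": item.mmr_term,
                        "pool_size": selection.pool_size,
                    },
                    sort_keys=True,
                )
            )
            fh.write("\n")


def read_ranked_selection(path) -> RankedSelection:
    rows = []
    pool_size = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            pool_size = int(payload.get("pool_size", pool_size))
            rows.append(
                RankedItem(
                    expl_id=payload["expl_id"],
                    s_comb=payload["s_comb"],
                    err_term=payload["err_term"],
                    mmr_term=payload["mmr_term"],
                )
            )
    return RankedSelection(selected=tuple(rows), pool_size=max(pool_size, len(rows)))


def check_references(
    explanations: Sequence[Explanation],
    demonstrations: Sequence[Demonstration],
    golds: Sequence[GoldExplanation] = (),
) -> None:
    """Every demo_id mentioned by an explanation or gold must resolve."""
    known = {d.demo_id for d in demonstrations}
    for e in explanations:
        if e.demo_id not in known:
            raise CorpusError(f"explanation {e.expl_id!r}: demo_id {e.demo_id!r} does not resolve")
    for g in golds:
        if g.demo_id not in known:
            raise CorpusError(f"gold {g.gold_id!r}: demo_id {g.demo_id!r} does not resolve")
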