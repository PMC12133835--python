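"""Token normalization shared by metrics, embeddings, and the verbalizer.

All lexical operations in the package (overlap factuality, the hash-embedding
backend, label-word counting) agree on one tokenization: split on Unicode
whitespace, strip leading/trailing punctuation, lowercase, drop empties.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def _strip_punct(token: str) -> str:
    start, end = 0, len(token)
    while start < end and _is_punct(token[start]):
        start += 1
    while end > start and _is_punct(token[end - 1]):
        end -= 1
    return token[start:end]


def token_list(text: str) -> list[str]:
    """Normalized tokens in document order, duplicates kept."""
    out = []
    for raw in text.split():
        tok = _strip_punct(raw).lower()
        if tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class TokenSet:
    """A deduplicated bag of normalized tokens.

    ``source_length`` is the token count before deduplication, so overlap
    metrics can distinguish set size from utterance length.
    """

    tokens: frozenset[str] = field(default_factory=frozenset)
    source_length: int = 0

    def __len__(self) -> int:
        return len(self.tokens)


def tokenize(text: str) -> TokenSet:
    """Normalize ``text`` into a :class:`TokenSet` (set semantics)."""
    toks = token_list(text)
    return TokenSet(tokens=frozenset(toks), source_length=len(toks))
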