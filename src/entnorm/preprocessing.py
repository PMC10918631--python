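"""Canonicalization of raw entity names.

Every matcher in the cascade operates on canonical names: lowercase,
ASCII-alphanumeric tokens separated by single spaces. Any non-alphanumeric
character acts as a token boundary ("beta-blocker" -> "beta blocker"),
runs of boundaries collapse, and accented characters are transliterated
where a Unicode decomposition exists ("é" -> "e").
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

__all__ = ["CanonicalName", "preprocess"]


@dataclass(frozen=True)
class CanonicalName:
    """A preprocessed name: ``text`` is ``tokens`` joined by single spaces."""

    text: str
    tokens: tuple[str, ...] = field(default=())

    def __bool__(self) -> bool:
        return bool(self.text)


def _is_ascii_alnum(c: str) -> bool:
    return ("a" <= c <= "z") or ("0" <= c <= "9")


def preprocess(name: str) -> CanonicalName:
    """Canonicalize ``name`` to lowercase alphanumeric tokens.

    Non-alphanumeric characters (after NFKD transliteration and case
    folding) are treated as token boundaries; consecutive boundaries
    collapse. An input without any alphanumeric character yields an
    empty canonical name, which downstream matchers treat as unmatched.

    Idempotent: ``preprocess(preprocess(s).text).text == preprocess(s).text``.
    """
    # NFKD -> casefold -> NFKD: casefolding can reintroduce precomposed or
    # compatibility characters (e.g. "ß" -> "ss" is fine, but "ᾛ" expands
    # to characters that decompose again), so normalize a second time.
    folded = unicodedata.normalize(
        "NFKD", unicodedata.normalize("NFKD", name).casefold()
    )
    tokens: list[str] = []
    current: list[str] = []
    for c in folded:
        if _is_ascii_alnum(c):
            current.append(c)
        elif unicodedata.combining(c):
            continue  # stripped accent, not a token boundary
        elif current:
            tokens.append("".join(current))
            current = []
    if current:
        tokens.append("".join(current))
    return CanonicalName(text=" ".join(tokens), tokens=tuple(tokens))
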