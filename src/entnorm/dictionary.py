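"""Reference dictionary with exact, sorted-token, and word-n-gram indexes.

A :class:`ReferenceDictionary` is built once from ``(raw name, identifier)``
pairs and then queried by the matchers. Three lookup structures are kept:

* ``exact_index``  — canonical text -> :class:`ReferenceEntry`
* ``token_index``  — lexicographically sorted token key -> canonical texts
* ``gram_index``   — word n-gram -> canonical texts containing that gram

Names whose canonical forms collide are merged into a single entry whose
identifier set is the union; ontologies legitimately share surface forms
across identifiers, so multi-identifier entries are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .preprocessing import CanonicalName, preprocess

__all__ = [
    "ReferenceEntry",
    "ReferenceDictionary",
    "EmptyDictionaryError",
    "build_dictionary",
    "word_ngrams",
    "token_key",
]

DEFAULT_NGRAM_SIZE = 2


class EmptyDictionaryError(ValueError):
    """Raised when no usable reference entries can be built."""


@dataclass
class ReferenceEntry:
    canonical: CanonicalName
    identifiers: set[str]
    raw_names: set[str] = field(default_factory=set)


def token_key(tokens) -> str:
    """Order-invariant key: tokens sorted lexicographically, space-joined."""
    return " ".join(sorted(tokens))


def word_ngrams(tokens, n: int) -> list[str]:
    """Contiguous word windows of length ``n``, space-joined, in order.

    Token lists shorter than ``n`` fall back to the single gram of the
    full sequence; an empty token list yields no grams.
    """
    if n < 1:
        raise ValueError(f"ngram size must be >= 1, got {n}")
    tokens = list(tokens)
    if not tokens:
        return []
    if len(tokens) < n:
        return [" ".join(tokens)]
    return [" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


class ReferenceDictionary:
    """Preprocessed reference names plus their lookup indexes."""

    def __init__(self, ngram_size: int = DEFAULT_NGRAM_SIZE):
        if ngram_size < 1:
            raise ValueError(f"ngram size must be >= 1, got {ngram_size}")
        self.ngram_size = ngram_size
        self.exact_index: dict[str, ReferenceEntry] = {}
        self.token_index: dict[str, set[str]] = {}
        self.gram_index: dict[str, set[str]] = {}
        self.dropped_count = 0  # raw names with empty canonical form

    @property
    def entries(self) -> list[ReferenceEntry]:
        return list(self.exact_index.values())

    def __len__(self) -> int:
        return len(self.exact_index)

    def add(self, raw_name: str, identifier: str) -> bool:
        """Insert one surface form; returns False if it canonicalizes to nothing."""
        canonical = preprocess(raw_name)
        if not canonical.text:
            self.dropped_count += 1
            return False
        entry = self.exact_index.get(canonical.text)
        if entry is None:
            entry = ReferenceEntry(canonical=canonical, identifiers=set())
            self.exact_index[canonical.text] = entry
            self.token_index.setdefault(token_key(canonical.tokens), set()).add(
                canonical.text
            )
            for gram in word_ngrams(canonical.tokens, self.ngram_size):
                self.gram_index.setdefault(gram, set()).add(canonical.text)
        entry.identifiers.add(identifier)
        entry.raw_names.add(raw_name)
        return True


def build_dictionary(pairs, ngram_size: int = DEFAULT_NGRAM_SIZE) -> ReferenceDictionary:
    """Build a :class:`ReferenceDictionary` from ``(raw name, identifier)`` pairs.

    Pairs whose name canonicalizes to the empty string are dropped and
    counted in ``dictionary.dropped_count``. Raises
    :class:`EmptyDictionaryError` if no pair survives.
    """
    pairs = list(pairs)
    if not pairs:
        raise EmptyDictionaryError("no reference pairs given")
    d = ReferenceDictionary(ngram_size=ngram_size)
    for raw_name, identifier in pairs:
        d.add(raw_name, identifier)
    if not d.exact_index:
        raise EmptyDictionaryError(
            f"all {len(pairs)} reference names canonicalized to empty strings"
        )
    return d
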