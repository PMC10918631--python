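"""The three matchers of the normalization cascade.

Step 1 is an exact hash lookup of the canonical text. Step 2 allows
different token orders (sorted-token equality) and slight length
variations (word-n-gram containment in either direction). Step 3 scans
all reference entries and accepts the nearest ones whose normalized
Levenshtein distance is at or below a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .dictionary import ReferenceDictionary, word_ngrams, token_key
from .preprocessing import CanonicalName

__all__ = [
    "STEP_EXACT",
    "STEP_TOKEN",
    "STEP_NGRAM",
    "STEP_PARTIAL",
    "STEP_NONE",
    "MatchResult",
    "MatchConfig",
    "exact_match",
    "token_match",
    "ngram_match",
    "partial_match",
    "levenshtein",
    "normalized_edit_distance",
]

STEP_EXACT = "exact"
STEP_TOKEN = "token"
STEP_NGRAM = "ngram"
STEP_PARTIAL = "partial"
STEP_NONE = "none"

DEFAULT_PARTIAL_THRESHOLD = 0.2


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one matcher (or of the whole cascade)."""

    query: CanonicalName
    matched_names: frozenset[str]
    identifiers: frozenset[str]
    step: str
    distance: float | None = None

    @property
    def matched(self) -> bool:
        return self.step != STEP_NONE


@dataclass(frozen=True)
class MatchConfig:
    """Cascade configuration; defaults follow the 20% / bigram operating point."""

    partial_threshold: float = DEFAULT_PARTIAL_THRESHOLD
    ngram_size: int = 2
    enable_token: bool = True
    enable_ngram: bool = True
    enable_partial: bool = True

    def __post_init__(self):
        if not 0.0 <= self.partial_threshold <= 1.0:
            raise ValueError(
                f"partial_threshold must be in [0, 1], got {self.partial_threshold}"
            )
        if self.ngram_size < 1:
            raise ValueError(f"ngram_size must be >= 1, got {self.ngram_size}")


def _no_match(query: CanonicalName) -> MatchResult:
    return MatchResult(
        query=query,
        matched_names=frozenset(),
        identifiers=frozenset(),
        step=STEP_NONE,
    )


def _hit(query, names, d: ReferenceDictionary, step, distance=None) -> MatchResult:
    identifiers: set[str] = set()
    for name in names:
        identifiers |= d.exact_index[name].identifiers
    return MatchResult(
        query=query,
        matched_names=frozenset(names),
        identifiers=frozenset(identifiers),
        step=step,
        distance=distance,
    )


def exact_match(query: CanonicalName, d: ReferenceDictionary) -> MatchResult:
    if query.text and query.text in d.exact_index:
        return _hit(query, [query.text], d, STEP_EXACT)
    return _no_match(query)


def token_match(query: CanonicalName, d: ReferenceDictionary) -> MatchResult:
    """Match entries whose sorted-token key equals the query's."""
    if not query.text:
        return _no_match(query)
    names = d.token_index.get(token_key(query.tokens))
    if names:
        return _hit(query, sorted(names), d, STEP_TOKEN)
    return _no_match(query)


def ngram_match(
    query: CanonicalName, d: ReferenceDictionary, n: int | None = None
) -> MatchResult:
    """Match by word-n-gram containment in either direction.

    Hits are (a) entries whose full canonical text or token key equals a
    word-n-gram of the query, and (b) entries one of whose own word-n-grams
    equals the query's full canonical text.
    """
    if n is None:
        n = d.ngram_size
    if not query.text:
        return _no_match(query)
    names: set[str] = set()
    for gram in word_ngrams(query.tokens, n):
        if gram in d.exact_index:
            names.add(gram)
        names.update(d.token_index.get(gram, ()))
    if n == d.ngram_size:
        names.update(d.gram_index.get(query.text, ()))
    else:  # non-default n: derive reference grams on the fly
        for text, entry in d.exact_index.items():
            if query.text in word_ngrams(entry.canonical.tokens, n):
                names.add(text)
    if names:
        return _hit(query, sorted(names), d, STEP_NGRAM)
    return _no_match(query)


def levenshtein(a: str, b: str) -> int:
    """Classic edit distance: minimal single-character ins/del/sub count."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _levenshtein_within(a: str, b: str, limit: int) -> int | None:
    """Edit distance if it is <= ``limit``, else None (early-abandoning)."""
    if abs(len(a) - len(b)) > limit:
        return None
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a) if len(a) <= limit else None
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        append = cur.append
        for j, cb in enumerate(b, 1):
            append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > limit:
            return None
        prev = cur
    dist = prev[-1]
    return dist if dist <= limit else None


def normalized_edit_distance(a: str, b: str) -> float:
    """``levenshtein(a, b) / max(len(a), len(b))``; 0 iff equal, bounded by 1."""
    m = max(len(a), len(b))
    if m == 0:
        raise ValueError("normalized edit distance is undefined for two empty strings")
    return levenshtein(a, b) / m


def partial_match(
    query: CanonicalName,
    d: ReferenceDictionary,
    threshold: float = DEFAULT_PARTIAL_THRESHOLD,
) -> MatchResult:
    """Nearest entries by normalized edit distance, within ``threshold``.

    Scans every entry (no pruning index) and returns all entries attaining
    the minimum normalized distance among those at or below the threshold;
    ties return every co-minimal entry. Distances are computed on the
    space-joined canonical text.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    q = query.text
    if not q:
        return _no_match(query)
    lq = len(q)
    best: float | None = None
    best_names: list[str] = []
    for text in d.exact_index:
        m = lq if lq >= len(text) else len(text)
        # floor with a tiny slack so that e.g. threshold 0.2, m 5 admits 1 edit
        limit = math.floor(threshold * m + 1e-9)
        dist = _levenshtein_within(q, text, limit)
        if dist is None:
            continue
        nd = dist / m
        if best is None or nd < best - 1e-12:
            best = nd
            best_names = [text]
        elif abs(nd - best) <= 1e-12:
            best_names.append(text)
    if best is None:
        return _no_match(query)
    return _hit(query, sorted(best_names), d, STEP_PARTIAL, distance=best)
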