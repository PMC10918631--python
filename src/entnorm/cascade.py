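"""Short-circuiting orchestration of the matching cascade.

Steps run in order of increasing cost — exact, token, n-gram, partial —
and the first successful step stops the cascade, so the expensive fuzzy
matchers only run for queries the cheap ones cannot resolve.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from . import matching
from .dictionary import ReferenceDictionary
from .matching import (
    MatchConfig,
    MatchResult,
    STEP_EXACT,
    STEP_NGRAM,
    STEP_PARTIAL,
    STEP_TOKEN,
)
from .preprocessing import preprocess

__all__ = ["CascadeTrace", "normalize", "normalize_batch"]

STEP_ORDER = (STEP_EXACT, STEP_TOKEN, STEP_NGRAM, STEP_PARTIAL)


@dataclass
class CascadeTrace:
    """One query's result plus which steps ran and how long they took."""

    raw: str
    result: MatchResult
    steps_attempted: list[str] = field(default_factory=list)
    elapsed: float = 0.0


def normalize(
    raw: str, d: ReferenceDictionary, config: MatchConfig | None = None
) -> CascadeTrace:
    """Run the full cascade on one raw name.

    Unmatched queries return a trace whose result step is ``"none"``;
    no error is raised.
    """
    if config is None:
        config = MatchConfig()
    start = time.perf_counter()
    query = preprocess(raw)
    attempted: list[str] = [STEP_EXACT]
    # matchers are resolved through the module so tests can instrument them
    result = matching.exact_match(query, d)
    if not result.matched and config.enable_token:
        attempted.append(STEP_TOKEN)
        result = matching.token_match(query, d)
    if not result.matched and config.enable_ngram:
        attempted.append(STEP_NGRAM)
        result = matching.ngram_match(query, d, config.ngram_size)
    if not result.matched and config.enable_partial:
        attempted.append(STEP_PARTIAL)
        result = matching.partial_match(query, d, config.partial_threshold)
    elapsed = time.perf_counter() - start
    return CascadeTrace(raw=raw, result=result, steps_attempted=attempted, elapsed=elapsed)


def normalize_batch(
    raws, d: ReferenceDictionary, config: MatchConfig | None = None
) -> list[CascadeTrace]:
    """Element-wise :func:`normalize`, input order preserved."""
    if config is None:
        config = MatchConfig()
    return [normalize(raw, d, config) for raw in raws]
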