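"""Seeded synthetic dictionaries and gold standards with known ground truth.

The generator builds a reference dictionary whose canonical names are
pairwise separated by more than twice the partial-matching threshold, so
every perturbed query has a unique, unambiguous source entry. Each gold
record is produced by one named perturbation, which fixes the earliest
cascade step able to recover it:

====================  =================
perturbation          expected step
====================  =================
identity              exact
case_punct            exact
token_shuffle         token
embed_in_phrase       ngram
char_edit             partial
unmatchable           none
====================  =================
"""

from __future__ import annotations

import json
import math
import random
import string
from dataclasses import dataclass, field
from pathlib import Path

from .dictionary import build_dictionary, token_key, word_ngrams
from .evaluation import GoldStandardRecord, NEGATIVE_MARKER
from .matching import (
    DEFAULT_PARTIAL_THRESHOLD,
    STEP_EXACT,
    STEP_NGRAM,
    STEP_NONE,
    STEP_PARTIAL,
    STEP_TOKEN,
    _levenshtein_within,
    normalized_edit_distance,
)
from .preprocessing import preprocess

__all__ = [
    "KINDS",
    "EXPECTED_STEP",
    "PerturbationSpec",
    "PerturbResult",
    "SyntheticGold",
    "SeparationError",
    "make_dictionary",
    "perturb",
    "make_gold",
    "write_fixtures",
    "DEFAULT_MIX",
]

KIND_IDENTITY = "identity"
KIND_CASE_PUNCT = "case_punct"
KIND_TOKEN_SHUFFLE = "token_shuffle"
KIND_EMBED = "embed_in_phrase"
KIND_CHAR_EDIT = "char_edit"
KIND_UNMATCHABLE = "unmatchable"

KINDS = (
    KIND_IDENTITY,
    KIND_CASE_PUNCT,
    KIND_TOKEN_SHUFFLE,
    KIND_EMBED,
    KIND_CHAR_EDIT,
    KIND_UNMATCHABLE,
)

EXPECTED_STEP = {
    KIND_IDENTITY: STEP_EXACT,
    KIND_CASE_PUNCT: STEP_EXACT,
    KIND_TOKEN_SHUFFLE: STEP_TOKEN,
    KIND_EMBED: STEP_NGRAM,
    KIND_CHAR_EDIT: STEP_PARTIAL,
    KIND_UNMATCHABLE: STEP_NONE,
}

DEFAULT_MIX = {
    KIND_IDENTITY: 0.2,
    KIND_CASE_PUNCT: 0.2,
    KIND_TOKEN_SHUFFLE: 0.2,
    KIND_EMBED: 0.1,
    KIND_CHAR_EDIT: 0.2,
    KIND_UNMATCHABLE: 0.1,
}

_EDIT_ALPHABET = string.ascii_lowercase + string.digits
_SEPARATORS = (" ", "-", ", ", " / ", "_", " - ")


class SeparationError(RuntimeError):
    """Could not build a sufficiently separated dictionary."""


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    edit_count: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.edit_count < 0:
            raise ValueError("edit_count must be >= 0")


@dataclass(frozen=True)
class PerturbResult:
    text: str
    effective_kind: str
    fell_back: bool = False


@dataclass
class SyntheticGold:
    dictionary_pairs: list[tuple[str, str]]
    records: list[GoldStandardRecord]
    expected_steps: list[str]
    specs: list[PerturbationSpec]
    parameters: dict = field(default_factory=dict)


def _random_word(rng: random.Random, lo: int = 4, hi: int = 9) -> str:
    return "".join(
        rng.choice(string.ascii_lowercase) for _ in range(rng.randint(lo, hi))
    )


def _filler_word(rng: random.Random) -> str:
    # fillers carry a digit so they can never collide with vocabulary words
    word = _random_word(rng, 5, 9)
    pos = rng.randint(1, len(word) - 1)
    return word[:pos] + rng.choice(string.digits) + word[pos:]


def _separated(candidate: str, accepted: list[str], min_separation: float) -> bool:
    lc = len(candidate)
    for other in accepted:
        m = max(lc, len(other))
        limit = math.floor(min_separation * m + 1e-9)
        if _levenshtein_within(candidate, other, limit) is not None:
            return False
    return True


def make_dictionary(
    n_entries: int,
    vocab_size: int | None = None,
    seed: int = 0,
    min_separation: float = 2 * DEFAULT_PARTIAL_THRESHOLD,
    max_attempts_per_entry: int = 200,
) -> list[tuple[str, str]]:
    """Generate ``(name, identifier)`` pairs with well-separated names.

    Names are 1-4 distinct tokens from a seeded synthetic vocabulary;
    canonical texts are pairwise distinct with normalized edit distance
    strictly greater than ``min_separation`` (rejection sampling), so
    perturbation ground truth is unambiguous.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    rng = random.Random(seed)
    if vocab_size is None:
        vocab_size = max(4 * n_entries, 24)
    vocab: list[str] = []
    seen = set()
    while len(vocab) < vocab_size:
        w = _random_word(rng)
        if w not in seen:
            seen.add(w)
            vocab.append(w)
    accepted: list[str] = []
    attempts = 0
    budget = n_entries * max_attempts_per_entry
    while len(accepted) < n_entries:
        if attempts >= budget:
            raise SeparationError(
                f"could not place {n_entries} names with separation "
                f"{min_separation} after {attempts} attempts; "
                "reduce n_entries or increase vocab_size"
            )
        attempts += 1
        k = rng.choices((1, 2, 3, 4), weights=(3, 4, 2, 1))[0]
        name = " ".join(rng.sample(vocab, k))
        if _separated(name, accepted, min_separation):
            accepted.append(name)
    width = max(4, len(str(n_entries)))
    return [(name, f"SYN:{i:0{width}d}") for i, name in enumerate(accepted)]


def _perturb_case_punct(tokens, rng: random.Random) -> str:
    out = []
    for i, tok in enumerate(tokens):
        styled = "".join(c.upper() if rng.random() < 0.5 else c for c in tok)
        out.append(styled)
    sep = rng.choice(_SEPARATORS)
    text = sep.join(out)
    if rng.random() < 0.3:
        text = f"({text})"
    if rng.random() < 0.3:
        text = text + "."
    return text


def _perturb_char_edit(text: str, edit_count: int, rng: random.Random) -> str:
    chars = list(text)
    for _ in range(edit_count):
        op = rng.choice(("sub", "ins", "del")) if len(chars) > 1 else "ins"
        if op == "sub":
            pos = rng.randrange(len(chars))
            chars[pos] = rng.choice([c for c in _EDIT_ALPHABET if c != chars[pos]])
        elif op == "ins":
            chars.insert(rng.randint(0, len(chars)), rng.choice(_EDIT_ALPHABET))
        else:
            del chars[rng.randrange(len(chars))]
    return "".join(chars)


def perturb(name: str, spec: PerturbationSpec) -> PerturbResult:
    """Apply one named perturbation to ``name``, deterministically per seed.

    ``token_shuffle`` on names without two distinct tokens falls back to
    identity with ``fell_back=True``.
    """
    if not name:
        raise ValueError("cannot perturb an empty name")
    rng = random.Random(spec.seed)
    canonical = preprocess(name)
    tokens = list(canonical.tokens)

    if spec.kind == KIND_IDENTITY:
        return PerturbResult(name, KIND_IDENTITY)

    if spec.kind == KIND_CASE_PUNCT:
        return PerturbResult(_perturb_case_punct(tokens, rng), KIND_CASE_PUNCT)

    if spec.kind == KIND_TOKEN_SHUFFLE:
        if len(tokens) < 2 or len(set(tokens)) < 2:
            return PerturbResult(name, KIND_IDENTITY, fell_back=True)
        shuffled = tokens[:]
        while " ".join(shuffled) == canonical.text:
            rng.shuffle(shuffled)
        return PerturbResult(" ".join(shuffled), KIND_TOKEN_SHUFFLE)

    if spec.kind == KIND_EMBED:
        before = [_filler_word(rng) for _ in range(rng.randint(0, 2))]
        after = [_filler_word(rng) for _ in range(rng.randint(0, 2))]
        if not before and not after:
            before = [_filler_word(rng)]
        return PerturbResult(" ".join(before + tokens + after), KIND_EMBED)

    if spec.kind == KIND_CHAR_EDIT:
        count = max(1, spec.edit_count)
        for _ in range(100):
            edited = _perturb_char_edit(canonical.text, count, rng)
            if edited and edited != canonical.text and preprocess(edited).text == edited:
                return PerturbResult(edited, KIND_CHAR_EDIT)
        raise RuntimeError(f"could not apply {count} edits to {name!r}")

    # unmatchable: gibberish tokens carrying digits; callers reject
    # candidates that land too close to a dictionary entry
    n_tokens = rng.randint(1, 3)
    return PerturbResult(
        " ".join(_filler_word(rng) for _ in range(n_tokens)), KIND_UNMATCHABLE
    )


def _allocate_counts(mix: dict, n_records: int) -> dict:
    """Largest-remainder allocation of ``n_records`` across the mix."""
    total = sum(mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError(f"mix proportions must sum to 1, got {total}")
    raw = {k: v * n_records for k, v in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = n_records - sum(counts.values())
    by_frac = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def _structurally_unmatched(canonical, ref) -> bool:
    """True if the query hits none of the exact/token/gram indexes."""
    if canonical.text in ref.exact_index:
        return False
    if token_key(canonical.tokens) in ref.token_index:
        return False
    for gram in word_ngrams(canonical.tokens, ref.ngram_size):
        if gram in ref.exact_index or gram in ref.token_index:
            return False
    if canonical.text in ref.gram_index:
        return False
    return True


def _nearest_within(canonical, ref, threshold: float):
    """Entries of ``ref`` within ``threshold`` normalized distance, as
    ``(min distance, canonical texts attaining it)``."""
    best, names = None, []
    for text in ref.exact_index:
        m = max(len(canonical.text), len(text))
        limit = math.floor(threshold * m + 1e-9)
        dist = _levenshtein_within(canonical.text, text, limit)
        if dist is None:
            continue
        nd = dist / m
        if best is None or nd < best - 1e-12:
            best, names = nd, [text]
        elif abs(nd - best) <= 1e-12:
            names.append(text)
    return best, names


def make_gold(
    dictionary_pairs,
    mix: dict | None = None,
    n_records: int = 100,
    seed: int = 0,
    threshold: float = DEFAULT_PARTIAL_THRESHOLD,
    ngram_size: int = 2,
) -> SyntheticGold:
    """Generate a gold standard of perturbed queries over ``dictionary_pairs``.

    Every record carries the perturbation spec that produced it and the
    earliest cascade step able to recover it. Unmatchable records are
    rejection-sampled until their normalized distance to every dictionary
    name exceeds ``2 * threshold`` and no token/n-gram structure is shared.
    """
    if mix is None:
        mix = DEFAULT_MIX
    dictionary_pairs = list(dictionary_pairs)
    ref = build_dictionary(dictionary_pairs, ngram_size=ngram_size)
    entry_ids = {
        text: sorted(entry.identifiers)[0] for text, entry in ref.exact_index.items()
    }
    texts = list(ref.exact_index)
    rng = random.Random(seed)
    counts = _allocate_counts(mix, n_records)

    pools = {
        KIND_IDENTITY: texts,
        KIND_CASE_PUNCT: texts,
        KIND_TOKEN_SHUFFLE: [
            t for t in texts if len(set(ref.exact_index[t].canonical.tokens)) >= 2
        ],
        KIND_EMBED: [
            t for t in texts if len(ref.exact_index[t].canonical.tokens) == ngram_size
        ],
        KIND_CHAR_EDIT: [
            t for t in texts if threshold > 0 and len(t) >= math.ceil(1.0 / threshold)
        ],
        KIND_UNMATCHABLE: [None],
    }
    for kind, need in counts.items():
        if need > 0 and not pools[kind]:
            raise ValueError(
                f"dictionary has no entry suitable for {kind!r} perturbations"
            )

    items = []  # (record, step, spec)
    for kind in KINDS:
        for _ in range(counts.get(kind, 0)):
            items.append(_make_record(kind, pools, ref, entry_ids, rng, threshold))
    rng.shuffle(items)
    records = [it[0] for it in items]
    steps = [it[1] for it in items]
    specs = [it[2] for it in items]
    return SyntheticGold(
        dictionary_pairs=dictionary_pairs,
        records=records,
        expected_steps=steps,
        specs=specs,
        parameters={
            "mix": dict(mix),
            "n_records": n_records,
            "seed": seed,
            "threshold": threshold,
            "ngram_size": ngram_size,
        },
    )


def _make_record(kind, pools, ref, entry_ids, rng, threshold):
    for _ in range(200):
        source = rng.choice(pools[kind])
        edit_count = 0
        if kind == KIND_CHAR_EDIT:
            edit_count = rng.randint(1, max(1, math.floor(threshold * len(source))))
        spec = PerturbationSpec(kind=kind, edit_count=edit_count, seed=rng.randrange(2**32))
        base = source if source is not None else "x"
        result = perturb(base, spec)
        query = result.text
        canonical = preprocess(query)
        if kind in (KIND_IDENTITY, KIND_CASE_PUNCT):
            if canonical.text == source:
                return (
                    GoldStandardRecord(query, entry_ids[source]),
                    EXPECTED_STEP[kind],
                    spec,
                )
        elif kind == KIND_TOKEN_SHUFFLE:
            if (
                not result.fell_back
                and canonical.text != source
                and canonical.text not in ref.exact_index
            ):
                return (GoldStandardRecord(query, entry_ids[source]), STEP_TOKEN, spec)
        elif kind == KIND_EMBED:
            if (
                canonical.text not in ref.exact_index
                and token_key(canonical.tokens) not in ref.token_index
                and source in word_ngrams(canonical.tokens, ref.ngram_size)
            ):
                return (GoldStandardRecord(query, entry_ids[source]), STEP_NGRAM, spec)
        elif kind == KIND_CHAR_EDIT:
            nd = normalized_edit_distance(canonical.text, source)
            if 0 < nd <= threshold and _structurally_unmatched(canonical, ref):
                best, names = _nearest_within(canonical, ref, threshold)
                if names == [source]:
                    return (
                        GoldStandardRecord(query, entry_ids[source]),
                        STEP_PARTIAL,
                        spec,
                    )
        else:  # unmatchable
            best, _ = _nearest_within(canonical, ref, min(1.0, 2 * threshold))
            if best is None and _structurally_unmatched(canonical, ref):
                return (GoldStandardRecord(query, None), STEP_NONE, spec)
    raise RuntimeError(f"could not generate a valid {kind!r} record after 200 tries")


def write_fixtures(gold: SyntheticGold, outdir) -> dict:
    """Write dictionary TSV, gold TSV and a JSON manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dict_path = outdir / "dictionary.tsv"
    gold_path = outdir / "gold.tsv"
    manifest_path = outdir / "manifest.json"
    with open(dict_path, "w", encoding="utf-8") as fh:
        for name, identifier in gold.dictionary_pairs:
            fh.write(f"{identifier}\t{name}\n")
    with open(gold_path, "w", encoding="utf-8") as fh:
        for record in gold.records:
            expected = record.expected if record.expected is not None else NEGATIVE_MARKER
            fh.write(f"{record.query}\t{expected}\n")
    manifest = {
        **gold.parameters,
        "n_dictionary_entries": len(gold.dictionary_pairs),
        "expected_steps": gold.expected_steps,
        "files": {"dictionary": dict_path.name, "gold": gold_path.name},
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"dictionary": dict_path, "gold": gold_path, "manifest": manifest_path}
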