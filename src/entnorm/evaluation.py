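"""Scoring of normalization output against a gold standard.

Counting rule (strict, NER-style): for a positive record, a prediction
containing the expected identifier is a true positive; a non-empty
prediction missing it counts as both a false positive and a false
negative; an empty prediction is a false negative. For a negative record
(no identifier expected), an empty prediction is a true negative and any
non-empty one a false positive.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np

from .cascade import normalize_batch, STEP_ORDER
from .dictionary import ReferenceDictionary
from .matching import MatchConfig

__all__ = [
    "NEGATIVE_MARKER",
    "GoldStandardRecord",
    "EvalMetrics",
    "BootstrapSummary",
    "TimingSummary",
    "score",
    "bootstrap",
    "time_batch",
]

#: Literal token marking an expected no-match in two-column gold files.
NEGATIVE_MARKER = "NONE"


@dataclass(frozen=True)
class GoldStandardRecord:
    """A query name with its expected identifier (None for negatives)."""

    query: str
    expected: str | None

    def __post_init__(self):
        if not self.query:
            raise ValueError("gold-standard query must be non-empty")

    @property
    def is_negative(self) -> bool:
        return self.expected is None


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    mean_prediction_size: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mean_prediction_size": self.mean_prediction_size,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def score(records, predictions) -> EvalMetrics:
    """Score aligned ``records`` / ``predictions`` (one identifier set each)."""
    records = list(records)
    predictions = [set(p) for p in predictions]
    if len(records) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(records)} records vs {len(predictions)} predictions"
        )
    tp = fp = fn = tn = 0
    for record, predicted in zip(records, predictions):
        if record.is_negative:
            if predicted:
                fp += 1
            else:
                tn += 1
        elif not predicted:
            fn += 1
        elif record.expected in predicted:
            tp += 1
        else:  # wrong identifier: penalized on both axes
            fp += 1
            fn += 1
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mean_size = _safe_div(sum(len(p) for p in predictions), len(predictions))
    return EvalMetrics(tp, fp, fn, tn, precision, recall, f1, mean_size)


@dataclass(frozen=True)
class BootstrapSummary:
    replicates: int
    seed: int
    precision_mean: float
    precision_std: float
    recall_mean: float
    recall_std: float
    f1_mean: float
    f1_std: float

    def as_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "seed": self.seed,
            "precision": {"mean": self.precision_mean, "std": self.precision_std},
            "recall": {"mean": self.recall_mean, "std": self.recall_std},
            "f1": {"mean": self.f1_mean, "std": self.f1_std},
        }


def bootstrap(records, predictions, replicates: int = 100, seed: int = 0) -> BootstrapSummary:
    """Resample record/prediction pairs with replacement and score each replicate.

    Returns per-metric mean and population standard deviation; fully
    determined by ``seed``.
    """
    records = list(records)
    predictions = list(predictions)
    if len(records) != len(predictions):
        raise ValueError("records and predictions must be aligned")
    if not records:
        raise ValueError("cannot bootstrap an empty record list")
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    n = len(records)
    ps, rs, fs = [], [], []
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        m = score([records[i] for i in idx], [predictions[i] for i in idx])
        ps.append(m.precision)
        rs.append(m.recall)
        fs.append(m.f1)
    return BootstrapSummary(
        replicates=replicates,
        seed=seed,
        precision_mean=float(np.mean(ps)),
        precision_std=float(np.std(ps)),
        recall_mean=float(np.mean(rs)),
        recall_std=float(np.std(rs)),
        f1_mean=float(np.mean(fs)),
        f1_std=float(np.std(fs)),
    )


@dataclass(frozen=True)
class TimingSummary:
    n_queries: int
    mean_seconds: float
    median_seconds: float
    step_attempts: dict

    def as_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "mean_seconds": self.mean_seconds,
            "median_seconds": self.median_seconds,
            "step_attempts": dict(self.step_attempts),
        }


def time_batch(raws, d: ReferenceDictionary, config: MatchConfig | None = None) -> TimingSummary:
    """Normalize a batch and report per-query timing and step-attempt counts."""
    traces = normalize_batch(raws, d, config)
    attempts = {step: 0 for step in STEP_ORDER}
    for trace in traces:
        for step in trace.steps_attempted:
            attempts[step] += 1
    durations = [t.elapsed for t in traces]
    return TimingSummary(
        n_queries=len(traces),
        mean_seconds=statistics.fmean(durations) if durations else 0.0,
        median_seconds=statistics.median(durations) if durations else 0.0,
        step_attempts=attempts,
    )
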