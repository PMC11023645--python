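"""Majority-vote ensembling, confusion-matrix metrics and error-profile
(three-set Venn) analysis.

The ensemble label is the mode of three binary votes (prompted LLM,
attention network, boosted trees). Because the vote is 2-of-3, a section is
an ensemble error exactly when at least two individual models err on it —
an identity asserted in :func:`ensemble_run`. Error overlap between models
is summarized as the seven Venn regions of the three per-model error sets,
with the union tied to inclusion-exclusion:

    |A u B u C| = |A|+|B|+|C| - |A^B| - |A^C| - |B^C| + |A^B^C|
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    """Precision/recall/F1/accuracy on [0,1]; zero denominators yield 0.0
    and are flagged in ``warnings``."""

    precision: float
    recall: float
    f1: float
    accuracy: float
    warnings: list[str] = field(default_factory=list)

    def as_percent(self, digits: int = 1) -> dict[str, float]:
        return {
            "precision": round(100 * self.precision, digits),
            "recall": round(100 * self.recall, digits),
            "f1": round(100 * self.f1, digits),
            "accuracy": round(100 * self.accuracy, digits),
        }

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "percent": self.as_percent(),
            "warnings": list(self.warnings),
        }


@dataclass
class ErrorProfile:
    """Venn decomposition of three per-model error id-sets.

    ``pairwise`` regions are reported under both conventions: full
    intersections (including the triple) and exactly-two regions.
    """

    errors_a: frozenset
    errors_b: frozenset
    errors_c: frozenset

    @property
    def abc(self) -> int:
        return len(self.errors_a & self.errors_b & self.errors_c)

    @property
    def ab_full(self) -> int:
        return len(self.errors_a & self.errors_b)

    @property
    def ac_full(self) -> int:
        return len(self.errors_a & self.errors_c)

    @property
    def bc_full(self) -> int:
        return len(self.errors_b & self.errors_c)

    @property
    def ab_only(self) -> int:
        return self.ab_full - self.abc

    @property
    def ac_only(self) -> int:
        return self.ac_full - self.abc

    @property
    def bc_only(self) -> int:
        return self.bc_full - self.abc

    @property
    def only_a(self) -> int:
        return len(self.errors_a - self.errors_b - self.errors_c)

    @property
    def only_b(self) -> int:
        return len(self.errors_b - self.errors_a - self.errors_c)

    @property
    def only_c(self) -> int:
        return len(self.errors_c - self.errors_a - self.errors_b)

    @property
    def union_size(self) -> int:
        return len(self.errors_a | self.errors_b | self.errors_c)

    @property
    def inclusion_exclusion_union(self) -> int:
        return (
            len(self.errors_a)
            + len(self.errors_b)
            + len(self.errors_c)
            - self.ab_full
            - self.ac_full
            - self.bc_full
            + self.abc
        )

    @property
    def mutual_error_share(self) -> float:
        """Triple-overlap errors as a fraction of the error union."""
        return self.abc / self.union_size if self.union_size else 0.0

    def region_counts(self) -> dict[str, int]:
        return {
            "only_a": self.only_a,
            "only_b": self.only_b,
            "only_c": self.only_c,
            "ab_only": self.ab_only,
            "ac_only": self.ac_only,
            "bc_only": self.bc_only,
            "abc": self.abc,
        }

    def to_dict(self) -> dict:
        return {
            "totals": {
                "a": len(self.errors_a),
                "b": len(self.errors_b),
                "c": len(self.errors_c),
            },
            "pairwise_full": {"ab": self.ab_full, "ac": self.ac_full, "bc": self.bc_full},
            "regions": self.region_counts(),
            "union_size": self.union_size,
            "mutual_error_share": self.mutual_error_share,
        }


@dataclass
class EnsemblePrediction:
    section_id: str
    votes: tuple[int, int, int]
    label: int

    def __post_init__(self) -> None:
        if self.label != majority_vote(self.votes):
            raise ValueError("label must equal the majority of the votes")


def majority_vote(votes: Sequence[int]) -> int:
    """Label held by at least two of exactly three binary votes."""
    if len(votes) != 3:
        raise ValueError(f"expected exactly 3 votes, got {len(votes)}")
    if any(v not in (0, 1) for v in votes):
        raise ValueError(f"votes must be binary, got {votes!r}")
    return int(sum(votes) >= 2)


def confusion(preds: Sequence[int], gold: Sequence[int]) -> ConfusionCounts:
    """Four-cell confusion counts for aligned binary label lists."""
    if len(preds) != len(gold):
        raise ValueError(f"length mismatch: {len(preds)} predictions vs {len(gold)} gold")
    tp = fp = fn = tn = 0
    for p, g in zip(preds, gold):
        if g == 1:
            if p == 1:
                tp += 1
            else:
                fn += 1
        else:
            if p == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(counts: ConfusionCounts) -> Metrics:
    """Precision, recall, F1 and accuracy from confusion counts."""
    warnings = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.append(f"{name}: zero denominator, reported as 0.0")
            return 0.0
        return num / den

    precision = safe(counts.tp, counts.tp + counts.fp, "precision")
    recall = safe(counts.tp, counts.tp + counts.fn, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "f1")
    accuracy = safe(counts.tp + counts.tn, counts.total, "accuracy")
    return Metrics(precision, recall, f1, accuracy, warnings)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (any consistent scale)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def improvement(after: Mapping[str, float], before: Mapping[str, float]) -> dict[str, float]:
    """Metric-wise deltas ``after - before`` over the shared keys."""
    return {k: after[k] - before[k] for k in after.keys() & before.keys()}


def error_ids(preds: Mapping[str, int], gold: Mapping[str, int]) -> frozenset:
    """Ids of sections where the prediction disagrees with gold."""
    missing = set(gold) - set(preds)
    if missing:
        raise ValueError(f"predictions missing for ids: {sorted(missing)[:5]}")
    return frozenset(i for i in gold if preds[i] != gold[i])


def error_profile(
    errors_a: Iterable, errors_b: Iterable, errors_c: Iterable
) -> ErrorProfile:
    """Venn decomposition of three per-model error id-sets."""
    return ErrorProfile(frozenset(errors_a), frozenset(errors_b), frozenset(errors_c))


@dataclass
class EnsembleResult:
    predictions: list[EnsemblePrediction]
    counts: ConfusionCounts
    metrics: Metrics
    profile: ErrorProfile
    per_model_metrics: list[Metrics]

    def to_dict(self) -> dict:
        return {
            "ensemble": self.metrics.to_dict(),
            "per_model": [m.to_dict() for m in self.per_model_metrics],
            "confusion": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
            "error_profile": self.profile.to_dict(),
        }


def ensemble_run(
    pred_tables: Sequence[Mapping[str, int]], gold: Mapping[str, int]
) -> EnsembleResult:
    """Full majority-vote evaluation bundle from three aligned label tables.

    Validates id alignment, forms per-section vote triples, scores the
    ensemble and each model, and checks the ensemble-error identity (the
    ensemble errs iff >= 2 individual models err).
    """
    if len(pred_tables) != 3:
        raise ValueError("exactly three prediction tables are required")
    gold_ids = set(gold)
    for k, table in enumerate(pred_tables):
        extra = set(table) - gold_ids
        missing = gold_ids - set(table)
        if extra or missing:
            raise ValueError(
                f"prediction table {k} misaligned: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
    ids = sorted(gold)
    predictions = []
    for sid in ids:
        votes = tuple(int(t[sid]) for t in pred_tables)
        predictions.append(EnsemblePrediction(sid, votes, majority_vote(votes)))
    ens_labels = [p.label for p in predictions]
    gold_labels = [gold[i] for i in ids]
    counts = confusion(ens_labels, gold_labels)
    model_errors = [error_ids(t, gold) for t in pred_tables]
    per_model = [
        metrics(confusion([t[i] for i in ids], gold_labels)) for t in pred_tables
    ]
    profile = error_profile(*model_errors)
    ens_errors = error_ids({p.section_id: p.label for p in predictions}, gold)
    expected = (
        (model_errors[0] & model_errors[1])
        | (model_errors[0] & model_errors[2])
        | (model_errors[1] & model_errors[2])
    )
    assert ens_errors == expected, "ensemble-error identity violated"
    return EnsembleResult(predictions, counts, metrics(counts), profile, per_model)
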