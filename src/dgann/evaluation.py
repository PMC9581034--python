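"""Ranking metrics: enrichment factors, success rates, fold aggregation.

EF_x% compares the positive rate in the top x% of the score-ranked decoy
list against the base rate; its attainable ceiling EF_max is the ratio of
all decoys to positives. The top window holds ``max(1, round(x% * N))``
decoys, so EF_0.01% on 3,600 decoys is a top-1 metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoredDecoySet",
    "EvalReport",
    "enrichment_factor",
    "ef_max",
    "success_rate",
    "evaluate_target",
    "aggregate_folds",
    "DEFAULT_CHECKPOINTS",
]

logger = logging.getLogger(__name__)

DEFAULT_CHECKPOINTS = (0.01, 0.1, 0.5, 1.0, 5.0, 10.0)


@dataclass(frozen=True)
class ScoredDecoySet:
    target_id: str
    model_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray  # bool, True = positive

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, float)
        labels = np.asarray(self.labels, bool)
        if len(scores) == 0 or len(scores) != len(labels):
            raise ValueError("need >= 1 decoy with matching labels")
        if len(self.model_ids) != len(scores):
            raise ValueError("model_ids must match scores")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def ranking(self) -> np.ndarray:
        """Indices by descending score; ties broken by model_id."""
        order = sorted(
            range(self.n), key=lambda i: (-self.scores[i], self.model_ids[i])
        )
        return np.asarray(order, dtype=int)


@dataclass(frozen=True)
class EvalReport:
    target_id: str
    ef: dict[float, float]  # checkpoint (%) -> EF
    ef_max: float
    success_curve: np.ndarray  # fraction with >= 1 positive in top N, N=1..
    confusion: dict[str, int]  # tp/fp/tn/fn at the 0.5 threshold


def ef_max(s: ScoredDecoySet) -> float:
    """N / n_positives — the ceiling any EF can reach."""
    if s.n_positive == 0:
        raise ValueError("EF undefined: no positive decoys")
    return s.n / s.n_positive


def enrichment_factor(s: ScoredDecoySet, x_percent: float) -> float:
    """(positives in top window / window size) * (N / total positives)."""
    if not 0 < x_percent <= 100:
        raise ValueError("x_percent must be in (0, 100]")
    if s.n_positive == 0:
        raise ValueError("EF undefined: no positive decoys")
    n_top = max(1, round(x_percent / 100.0 * s.n))
    top = s.ranking()[:n_top]
    hits = int(s.labels[top].sum())
    # single integer ratio so the x=100% case collapses to exactly 1.0
    return (hits * s.n) / (n_top * s.n_positive)


def success_rate(targets: list[ScoredDecoySet], n_max: int) -> np.ndarray:
    """Per N in 1..n_max, the fraction of targets whose top N contain a
    positive."""
    if not targets:
        raise ValueError("need at least one target")
    first_hit = []
    for s in targets:
        ranked_labels = s.labels[s.ranking()]
        hits = np.flatnonzero(ranked_labels)
        first_hit.append(hits[0] + 1 if hits.size else np.inf)
    first_hit = np.asarray(first_hit, float)
    ns = np.arange(1, n_max + 1)
    return (first_hit[None, :] <= ns[:, None]).mean(axis=1)


def evaluate_target(
    s: ScoredDecoySet,
    checkpoints=DEFAULT_CHECKPOINTS,
    threshold: float = 0.5,
) -> EvalReport:
    ranked = s.ranking()
    curve_hits = np.cumsum(s.labels[ranked]) > 0
    pred = s.scores >= threshold
    confusion = {
        "tp": int(np.sum(pred & s.labels)),
        "fp": int(np.sum(pred & ~s.labels)),
        "tn": int(np.sum(~pred & ~s.labels)),
        "fn": int(np.sum(~pred & s.labels)),
    }
    return EvalReport(
        target_id=s.target_id,
        ef={x: enrichment_factor(s, x) for x in checkpoints},
        ef_max=ef_max(s),
        success_curve=curve_hits.astype(float),
        confusion=confusion,
    )


def aggregate_folds(fold_reports: list[list[EvalReport]]) -> dict:
    """Unweighted mean over targets within a fold, then over folds.

    Targets without positives must already have been excluded upstream
    (they raise in :func:`enrichment_factor`).
    """
    checkpoints = None
    fold_means = []
    for reports in fold_reports:
        if not reports:
            continue
        keys = tuple(sorted(reports[0].ef))
        if checkpoints is None:
            checkpoints = keys
        elif keys != checkpoints:
            raise ValueError("checkpoint mismatch across folds")
        fold_means.append(
            {x: float(np.mean([r.ef[x] for r in reports])) for x in keys}
            | {"ef_max": float(np.mean([r.ef_max for r in reports]))}
        )
    if not fold_means:
        raise ValueError("no reports to aggregate")
    summary = {
        x: float(np.mean([fm[x] for fm in fold_means])) for x in checkpoints
    }
    summary["ef_max"] = float(np.mean([fm["ef_max"] for fm in fold_means]))
    return summary
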