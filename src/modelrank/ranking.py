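"""Per-model charged-interaction scores, replicate aggregation, ranking, extremes.

A model's score for one docking run is the fraction of its poses forming the
anchor charged contact; replicate runs are averaged as run-level fractions
(not pooled), mirroring a two-run docking protocol with replicate control.
Scores are kept as exact rationals alongside their float value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .interactions import InteractionRecord


def score_pose_set(records: Sequence[InteractionRecord]) -> Fraction:
    """Fraction of poses with the anchor charged contact, as an exact rational."""
    if not records:
        raise ValueError("empty record list")
    k = sum(1 for r in records if r.ionic_to_anchor)
    return Fraction(k, len(records))


def aggregate_runs(per_run_scores: Mapping[str, Fraction | float]) -> tuple[float, float]:
    """Arithmetic mean over runs and the absolute run discrepancy (max - min)."""
    if not per_run_scores:
        raise ValueError("no runs")
    vals = [float(v) for v in per_run_scores.values()]
    return float(np.mean(vals)), float(max(vals) - min(vals))


@dataclass
class ModelScore:
    model_id: str
    per_run: dict[str, Fraction]
    n_poses: dict[str, int]
    aggregate: float = 0.0
    discrepancy: float = 0.0
    pooled: Fraction | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        for run, s in self.per_run.items():
            if not 0 <= s <= 1:
                raise ValueError(f"score {s} for run {run!r} outside [0, 1]")
        self.aggregate, self.discrepancy = aggregate_runs(self.per_run)
        den = sum(self.n_poses.values())
        interacting = sum(Fraction(s) * self.n_poses[r] for r, s in self.per_run.items())
        self.pooled = interacting / den if den else None

    @classmethod
    def from_records(
        cls, model_id: str, per_run_records: Mapping[str, Sequence[InteractionRecord]]
    ) -> "ModelScore":
        per_run = {run: score_pose_set(recs) for run, recs in per_run_records.items()}
        n_poses = {run: len(recs) for run, recs in per_run_records.items()}
        return cls(model_id, per_run, n_poses)


def rank_models(scores: Iterable[ModelScore]) -> list[ModelScore]:
    """Sort models by descending aggregate score and assign dense ranks 1..n.

    Ties break by smaller run discrepancy, then lexical model_id — a
    reproducibility convention, not a scientific claim.
    """
    scores = list(scores)
    ids = [s.model_id for s in scores]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate model_id {dup!r}")
    ordered = sorted(scores, key=lambda s: (-s.aggregate, s.discrepancy, s.model_id))
    for i, s in enumerate(ordered, start=1):
        s.rank = i
    return ordered


@dataclass
class ExtremeSelection:
    k: int
    best: list[str]
    worst: list[str]


def select_extremes(ranked: Sequence[ModelScore], k: int = 10) -> ExtremeSelection:
    """The k best (ranks 1..k) and k worst (ranks n-k+1..n) model ids."""
    n = len(ranked)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} models for disjoint extremes, got {n}")
    ordered = sorted(ranked, key=lambda s: s.rank)
    return ExtremeSelection(
        k=k,
        best=[s.model_id for s in ordered[:k]],
        worst=[s.model_id for s in ordered[-k:]],
    )


def score_distribution_summary(
    scores: Sequence[float | Fraction], thresholds: Sequence[float] = (0.0, 0.1)
) -> dict:
    """Quartiles plus the fraction of models scoring at or below each threshold."""
    if len(scores) == 0:
        raise ValueError("no scores")
    vals = np.array([float(s) for s in scores])
    q = np.quantile(vals, [0.25, 0.5, 0.75])
    return {
        "n": len(vals),
        "quartiles": {"q25": float(q[0]), "q50": float(q[1]), "q75": float(q[2])},
        "fraction_at_or_below": {
            float(t): float(np.mean(vals <= t)) for t in thresholds
        },
    }


def score_table(ranked: Sequence[ModelScore]) -> pd.DataFrame:
    """Tabulate ranked scores (one row per model, one column per run)."""
    runs = sorted({r for s in ranked for r in s.per_run})
    rows = []
    for s in sorted(ranked, key=lambda s: s.rank):
        row = {"model_id": s.model_id, "rank": s.rank}
        for r in runs:
            row[f"score_{r}"] = float(s.per_run[r]) if r in s.per_run else np.nan
        row["aggregate"] = s.aggregate
        row["discrepancy"] = s.discrepancy
        row["pooled"] = float(s.pooled) if s.pooled is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
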