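"""Ranking evaluation: hit-rate, mean percentile rank, and grouped recall.

For each test walk a model returns a sorted list R of at most K candidates.
HR is the fraction of test walks whose true next node appears in R. MPR
averages rank/K over the *hit* walks only, with 1-based ranks — so with K=1
every hit contributes 1/1 and MPR is exactly 1.0. The grouped-recall table
min-max normalizes a walk attribute (length or time range) over the test
set, cuts it at percentile boundaries into quintile-style groups, and
reports the within-group hit fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Prediction:
    walk_id: str
    ranked: tuple[str, ...]
    f: str

    def __post_init__(self) -> None:
        if len(set(self.ranked)) != len(self.ranked):
            raise ValueError(f"duplicate candidates in ranked list for {self.walk_id!r}")

    @property
    def hit(self) -> bool:
        return self.f in self.ranked

    @property
    def rank(self) -> int | None:
        """1-based position of the ground truth in the list, None on a miss."""
        try:
            return self.ranked.index(self.f) + 1
        except ValueError:
            return None


class PredictionBatch:
    """Per-test-walk ranked lists (length <= K) with ground truths."""

    def __init__(self, predictions: list[Prediction], k: int) -> None:
        if k < 1:
            raise ValueError("K must be >= 1")
        for p in predictions:
            if len(p.ranked) > k:
                raise ValueError(f"ranked list longer than K for {p.walk_id!r}")
        self.predictions = list(predictions)
        self.k = k

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)


def hit_rate(batch: PredictionBatch) -> float:
    """Fraction of test walks whose ground truth appears in the ranked list."""
    if len(batch) == 0:
        raise ValueError("empty prediction batch")
    return sum(p.hit for p in batch) / len(batch)


def mpr(batch: PredictionBatch) -> float:
    """Mean percentile rank over hit walks: mean of rank(f)/K, rank 1-based.

    Undefined (raises) when no walk hits; equals 1.0 when K = 1 and every
    single-candidate list hits.
    """
    ranks = [p.rank for p in batch if p.hit]
    if not ranks:
        raise ValueError("MPR undefined: no hits in batch")
    return float(np.mean([r / batch.k for r in ranks]))


def grouped_recall(
    batch: PredictionBatch,
    attributes: dict[str, float],
    n_groups: int = 5,
) -> pd.DataFrame:
    """Within-group hit fraction after min-max normalizing a walk attribute
    and cutting the test set at percentile boundaries (0-20%, ..., 80-100%
    for the default five groups). Boundary ties go to the lower group.

    Returns a frame with columns group, lo_pct, hi_pct, n, recall. A constant
    attribute collapses to a single group with a warning.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(batch) == 0:
        raise ValueError("empty prediction batch")
    vals = np.array([attributes[p.walk_id] for p in batch], dtype=float)
    span = vals.max() - vals.min()
    if span == 0:
        warnings.warn("constant attribute: single recall group", stacklevel=2)
        rec = sum(p.hit for p in batch) / len(batch)
        return pd.DataFrame(
            [(0, 0.0, 100.0, len(batch), rec)],
            columns=["group", "lo_pct", "hi_pct", "n", "recall"],
        )
    norm = (vals - vals.min()) / span
    pct = np.linspace(0, 100, n_groups + 1)
    bounds = np.percentile(norm, pct[1:-1])
    groups = np.searchsorted(bounds, norm, side="left")
    rows = []
    hits = np.array([p.hit for p in batch])
    for g in range(n_groups):
        mask = groups == g
        n = int(mask.sum())
        rec = float(hits[mask].mean()) if n else float("nan")
        rows.append((g, pct[g], pct[g + 1], n, rec))
    return pd.DataFrame(rows, columns=["group", "lo_pct", "hi_pct", "n", "recall"])
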