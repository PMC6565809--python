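"""Temporal train/test/candidate split at an observation day T.

Walks ending strictly before T form the training set: all visits but the
last are the observed part and the last actor is the ground truth ``f``.
Walks straddling T (at least one visit before and one at or after T, under
the half-open convention that a visit exactly at T is future) form the test
set: the observed part is the prefix before T and ``f`` is the first actor
visited at or after T. The candidate set J collects the ground truths of all
test walks. Walks shorter than ``min_visits`` (default 6) are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .netcore import InformationWalk, WalkCorpus

DEFAULT_MIN_VISITS = 6


@dataclass(frozen=True)
class SplitExample:
    """An observed walk prefix paired with its ground-truth next actor."""

    observed: InformationWalk
    f: str

    @property
    def walk_id(self) -> str:
        return self.observed.walk_id

    @property
    def last_actor(self) -> str:
        """The last observed actor c."""
        return self.observed.visits[-1].actor_id


@dataclass
class SplitResult:
    T: int
    train: list[SplitExample] = field(default_factory=list)
    test: list[SplitExample] = field(default_factory=list)
    candidates: frozenset[str] = frozenset()

    def manifest(self) -> pd.DataFrame:
        rows = [(ex.walk_id, role, ex.f) for role, part in
                (("train", self.train), ("test", self.test)) for ex in part]
        return pd.DataFrame(rows, columns=["walk_id", "role", "f"])


def split_at(
    corpus: WalkCorpus, T: int, min_visits: int = DEFAULT_MIN_VISITS
) -> SplitResult:
    """Split a corpus at observation day ``T``.

    Raises on ``min_visits < 2``; warns (and may return empty sets) when T
    falls outside the corpus time span.
    """
    if min_visits < 2:
        raise ValueError(f"min_visits must be >= 2, got {min_visits}")
    if len(corpus):
        lo = min(w.start_day for w in corpus)
        hi = max(w.end_day for w in corpus)
        if not (lo < T <= hi + 1):
            warnings.warn(
                f"observation day {T} outside corpus span [{lo}, {hi}]",
                stacklevel=2,
            )
    train: list[SplitExample] = []
    test: list[SplitExample] = []
    for walk in sorted(corpus, key=lambda w: w.walk_id):
        if len(walk) < min_visits:
            continue
        if walk.end_day < T:
            train.append(
                SplitExample(
                    observed=InformationWalk(walk.walk_id, walk.visits[:-1]),
                    f=walk.visits[-1].actor_id,
                )
            )
        elif walk.start_day < T:  # ongoing at T; prefix non-empty by construction
            observed = walk.observed_before(T)
            future = [v for v in walk.visits if v.day >= T]
            if not observed or not future:  # defensive; cannot happen here
                continue
            test.append(
                SplitExample(
                    observed=InformationWalk(walk.walk_id, observed),
                    f=future[0].actor_id,
                )
            )
        # walks starting at/after T are entirely future: dropped
    return SplitResult(
        T=T,
        train=train,
        test=test,
        candidates=frozenset(ex.f for ex in test),
    )
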