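"""Comparison scorers for next-node prediction.

All scorers share the contract ``score(context, candidate) -> float`` so they
plug into the same ranking and evaluation code as the trained model: MP
(historical edge weight), the classical link-prediction indices CN / PA /
Adamic-Adar / Jaccard on undirected neighborhoods, a 2-gram Markov chain over
consecutive training-walk triples, and the profile-similarity-only ranking
model (w trained with the interaction matrices pinned at zero).
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable

import numpy as np

from .netcore import InformationWalk, ReferralNetwork

MODEL_NAMES = ("mp", "cn", "pa", "aa", "jaccard", "mc2", "bpr_no_iw", "bpr_iw")


class NeighborIndex:
    """Out-, in-, and undirected-neighbor sets per actor of a network."""

    def __init__(self, network: ReferralNetwork, directed: bool = False) -> None:
        self.directed = directed
        self.out: dict[str, set[str]] = {a: set() for a in network.actors}
        self.inn: dict[str, set[str]] = {a: set() for a in network.actors}
        for s, d in network.edges:
            self.out[s].add(d)
            self.inn[d].add(s)
        self.und: dict[str, set[str]] = {
            a: self.out[a] | self.inn[a] for a in network.actors
        }

    def gamma(self, actor: str) -> set[str]:
        """The neighborhood the similarity indices operate on (out-neighbors
        in directed mode, undirected neighbors otherwise)."""
        return self.out[actor] if self.directed else self.und[actor]

    def degree(self, actor: str) -> int:
        return len(self.gamma(actor))


def score_mp(c: str, j: str, network: ReferralNetwork) -> float:
    """Most-popular: the historical referral count on the directed edge c->j."""
    return float(network.edge_count(c, j))


def score_cn(c: str, j: str, index: NeighborIndex) -> float:
    return float(len(index.gamma(c) & index.gamma(j)))


def score_pa(c: str, j: str, index: NeighborIndex) -> float:
    return float(len(index.gamma(c)) * len(index.gamma(j)))


def score_aa(c: str, j: str, index: NeighborIndex) -> float:
    """Adamic-Adar: sum of 1/log degree over common neighbors; neighbors of
    degree <= 1 are skipped (log 1 = 0)."""
    total = 0.0
    for z in index.gamma(c) & index.gamma(j):
        dz = index.degree(z)
        if dz > 1:
            total += 1.0 / math.log(dz)
    return total


def score_jaccard(c: str, j: str, index: NeighborIndex) -> float:
    union = index.gamma(c) | index.gamma(j)
    if not union:
        return 0.0
    return len(index.gamma(c) & index.gamma(j)) / len(union)


class TransitionCounts:
    """2-gram transition counts (prev, current) -> next tallied from training
    walks' consecutive visit triples."""

    def __init__(self) -> None:
        self._counts: dict[tuple[str, str], dict[str, int]] = defaultdict(
            lambda: defaultdict(int)
        )

    @classmethod
    def from_walks(cls, walks: Iterable[InformationWalk]) -> "TransitionCounts":
        tc = cls()
        for walk in walks:
            seq = walk.actor_sequence
            for i in range(len(seq) - 2):
                tc._counts[(seq[i], seq[i + 1])][seq[i + 2]] += 1
        return tc

    def context_total(self, prev: str, c: str) -> int:
        return sum(self._counts.get((prev, c), {}).values())

    def count(self, prev: str, c: str, j: str) -> int:
        return self._counts.get((prev, c), {}).get(j, 0)


def score_mc2(prev: str | None, c: str, j: str, counts: TransitionCounts) -> float:
    """2-gram Markov chain: Prob(next = j | prev, c); 0 for unseen contexts
    (no 1-gram backoff) and when the walk has no second-to-last node."""
    if prev is None:
        return 0.0
    total = counts.context_total(prev, c)
    if total == 0:
        return 0.0
    return counts.count(prev, c, j) / total


def score_bpr_no_iw(d: np.ndarray, w: np.ndarray) -> float:
    """Profile-similarity-only score w . d(c, j); w comes from the pairwise
    ranking trainer with S and U frozen at zero."""
    d = np.asarray(d, float)
    w = np.asarray(w, float).ravel()
    if d.shape != w.shape:
        raise ValueError(f"dimension mismatch: d {d.shape} vs w {w.shape}")
    return float(w @ d)
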