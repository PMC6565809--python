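"""The derived network of information walks and its structural patterns.

Each node of the walk network is a walk; two walks are linked when they
share at least one actor of the original referral network. Edges carry four
weights: the number of distinct shared actors, the Jaccard index of the two
distinct-actor sets, and the combined visit count / RVU that the two walks
spend at the shared actors.

Pattern detectors: *homotopic* pairs (same start and end actor), *lifting*
pairs (one walk equals the other with a single actor inserted between two
consecutive actors), and *composition* triples (walk 1 ends with A->B, walk
2 starts with B->C, walk 3 carries A->B->C strictly in its interior).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .netcore import InformationWalk, WalkCorpus

PAGERANK_DAMPING = 0.85


@dataclass(frozen=True)
class WalkEdge:
    n_common: int
    jaccard: float
    shared_visits: int
    shared_rvu: float


class WalkNetwork:
    """Undirected graph over walk ids with overlap-weighted edges."""

    def __init__(self, nodes: list[str], edges: dict[tuple[str, str], WalkEdge]) -> None:
        self.nodes = sorted(nodes)
        self.edges: dict[tuple[str, str], WalkEdge] = {}
        for (a, b), e in edges.items():
            key = (a, b) if a < b else (b, a)
            if e.n_common < 1 or not (0 < e.jaccard <= 1):
                raise ValueError(f"invalid edge weights for {key}: {e}")
            self.edges[key] = e

    def edge(self, a: str, b: str) -> WalkEdge | None:
        return self.edges.get((a, b) if a < b else (b, a))

    def degree(self, a: str) -> int:
        return sum(1 for k in self.edges if a in k)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, e.n_common, e.jaccard, e.shared_visits, e.shared_rvu)
            for (a, b), e in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["walk_a", "walk_b", "n_common", "jaccard",
                     "shared_visits", "shared_rvu"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_networkx(self, weight: str = "n_common") -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        for (a, b), e in self.edges.items():
            G.add_edge(a, b, weight=1.0 if weight == "unweighted" else getattr(e, weight))
        return G


def build_walk_network(corpus: WalkCorpus | list[InformationWalk]) -> WalkNetwork:
    """Build the walk network via an inverted actor -> walks index.

    Cost scales with the sum over actors of (walks through that actor)^2
    rather than with all walk pairs, which matters on sparse corpora.
    """
    walks = list(corpus)
    if not walks:
        raise ValueError("need at least one walk")
    actor_sets = {w.walk_id: w.actor_set for w in walks}
    visit_counts = {w.walk_id: Counter(w.actor_sequence) for w in walks}
    rvu_by_actor: dict[str, dict[str, float]] = {}
    for w in walks:
        acc: dict[str, float] = defaultdict(float)
        for v in w.visits:
            acc[v.actor_id] += v.rvu
        rvu_by_actor[w.walk_id] = acc
    index: dict[str, list[str]] = defaultdict(list)
    for w in walks:
        for a in actor_sets[w.walk_id]:
            index[a].append(w.walk_id)
    common: dict[tuple[str, str], int] = defaultdict(int)
    for a, wids in index.items():
        wids = sorted(wids)
        for i in range(len(wids)):
            for j in range(i + 1, len(wids)):
                common[(wids[i], wids[j])] += 1
    edges: dict[tuple[str, str], WalkEdge] = {}
    for (wa, wb), n_common in common.items():
        sa, sb = actor_sets[wa], actor_sets[wb]
        shared = sa & sb
        union = len(sa | sb)
        edges[(wa, wb)] = WalkEdge(
            n_common=n_common,
            jaccard=n_common / union,
            shared_visits=sum(
                visit_counts[wa][x] + visit_counts[wb][x] for x in shared
            ),
            shared_rvu=float(
                sum(rvu_by_actor[wa][x] + rvu_by_actor[wb][x] for x in shared)
            ),
        )
    return WalkNetwork([w.walk_id for w in walks], edges)


def find_homotopic_pairs(corpus) -> set[tuple[str, str]]:
    """Unordered pairs of walks (length >= 2) sharing both their first and
    their last actor; start may equal end (loop walks)."""
    walks = [w for w in corpus if len(w) >= 2]
    by_ends: dict[tuple[str, str], list[str]] = defaultdict(list)
    for w in walks:
        seq = w.actor_sequence
        by_ends[(seq[0], seq[-1])].append(w.walk_id)
    pairs: set[tuple[str, str]] = set()
    for wids in by_ends.values():
        wids = sorted(wids)
        for i in range(len(wids)):
            for j in range(i + 1, len(wids)):
                pairs.add((wids[i], wids[j]))
    return pairs


def _is_single_insertion(short: tuple[str, ...], long: tuple[str, ...]):
    """If ``long`` equals ``short`` with one actor inserted, return (position,
    inserted actor); else None. Position is the index of X in ``long``."""
    if len(long) != len(short) + 1:
        return None
    for pos in range(1, len(long) - 1):  # insertion strictly between A and B
        if long[:pos] + long[pos + 1:] == short:
            return pos, long[pos]
    return None


def find_lifting_pairs(corpus) -> set[tuple[str, str, str]]:
    """(shorter walk, longer walk, inserted actor X) triples where the longer
    walk's actor sequence is the shorter's with exactly one actor X inserted
    between consecutive actors A and B."""
    walks = list(corpus)
    by_len: dict[int, list[InformationWalk]] = defaultdict(list)
    for w in walks:
        by_len[len(w.actor_sequence)].append(w)
    out: set[tuple[str, str, str]] = set()
    for n, shorts in by_len.items():
        for short in shorts:
            for long in by_len.get(n + 1, []):
                hit = _is_single_insertion(short.actor_sequence, long.actor_sequence)
                if hit is not None:
                    out.add((short.walk_id, long.walk_id, hit[1]))
    return out


def _interior_triple_positions(seq: tuple[str, ...], a: str, b: str, c: str) -> bool:
    # A->B->C strictly interior: not touching the first or last position
    for i in range(1, len(seq) - 3):
        if seq[i] == a and seq[i + 1] == b and seq[i + 2] == c:
            return True
    return False


def find_composition_triples(corpus) -> set[tuple[str, str, str]]:
    """(w1, w2, w3) with w1 ending in consecutive A->B, w2 starting with
    consecutive B->C, and w3 containing A->B->C strictly in its interior."""
    walks = [w for w in corpus if len(w.actor_sequence) >= 2]
    enders: dict[tuple[str, str], list[str]] = defaultdict(list)
    starters: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for w in walks:
        seq = w.actor_sequence
        enders[(seq[-2], seq[-1])].append(w.walk_id)
        starters[seq[0]].append((w.walk_id, seq[1]))
    out: set[tuple[str, str, str]] = set()
    for (a, b), w1s in enders.items():
        for w2_id, c in starters.get(b, []):
            for w3 in walks:
                if len(w3.actor_sequence) >= 5 and _interior_triple_positions(
                    w3.actor_sequence, a, b, c
                ):
                    for w1_id in w1s:
                        out.add((w1_id, w2_id, w3.walk_id))
    return out


def compare_groups(values_a, values_b) -> tuple[float, float, tuple[float, float]]:
    """Welch two-sample t-test between two groups of edge-weight or centrality
    values; returns (t, p, (mean_a, mean_b)).

    Degenerate zero-variance groups are guarded: equal means give (0, 1),
    fully separated constant groups give (+/-inf, 0).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    ma, mb = float(a.mean()), float(b.mean())
    if a.std() == 0 and b.std() == 0:
        if ma == mb:
            return 0.0, 1.0, (ma, mb)
        return float(np.sign(ma - mb)) * float("inf"), 0.0, (ma, mb)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), (ma, mb)


def walknet_pagerank(wn: WalkNetwork, weight: str = "n_common") -> dict[str, float]:
    """PageRank (damping 0.85) on the undirected walk network; ``weight`` is
    one of n_common, jaccard, or unweighted."""
    if weight not in ("n_common", "jaccard", "unweighted"):
        raise ValueError(f"unknown weight choice {weight!r}")
    if not wn.nodes:
        raise ValueError("empty walk network")
    G = wn.to_networkx(weight)
    return {k: float(v) for k, v in nx.pagerank(G, alpha=PAGERANK_DAMPING,
                                                weight="weight").items()}
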