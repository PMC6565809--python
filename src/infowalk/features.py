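"""Feature extraction for walks, candidate nodes, last nodes, and actor pairs.

Four feature families feed the preference score:

* ``p`` — walk-level vector (dimension M=6) summarizing the observed prefix;
* ``gamma`` — candidate-node centrality vector (dimension H=4);
* ``beta`` — last-node vector (dimension N=8): the candidate features plus
  walk-contextual features of the most recent visit;
* ``d`` — profile-similarity vector (dimension L=4) between the last node
  and a candidate.

Centralities are computed on the *previous* period's network so that feature
extraction at an observation time never looks ahead of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .netcore import InformationWalk, ReferralNetwork, UNKNOWN

M_WALK = 6
H_CANDIDATE = 4
N_LASTNODE = 8
L_PROFILE = 4

PAGERANK_DAMPING = 0.85


@dataclass(frozen=True)
class ActorCentrality:
    pagerank: float
    clustering: float
    h_index: int
    cross_region_out: int


class CentralityTable:
    """Per-actor centralities: PageRank, clustering coefficient, h-index, and
    the number of initiated cross-region referrals (distinct out-edges whose
    target lies in a different region)."""

    def __init__(self, values: dict[str, ActorCentrality]) -> None:
        self.values = values

    def __getitem__(self, actor_id: str) -> ActorCentrality:
        try:
            return self.values[actor_id]
        except KeyError:
            raise KeyError(f"actor {actor_id!r} not in centrality table") from None

    def __contains__(self, actor_id: str) -> bool:
        return actor_id in self.values

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, c.pagerank, c.clustering, c.h_index, c.cross_region_out)
            for a, c in sorted(self.values.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["actor_id", "pagerank", "clustering", "h_index", "cross_region_out"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def h_index_from_degrees(neighbor_degrees: list[int]) -> int:
    """Largest h such that >= h neighbors each have degree >= h (lobby index)."""
    degs = sorted(neighbor_degrees, reverse=True)
    h = 0
    for i, d in enumerate(degs, start=1):
        if d >= i:
            h = i
        else:
            break
    return h


def compute_centralities(network: ReferralNetwork) -> CentralityTable:
    """Centrality table for every actor of a network.

    PageRank uses damping 0.85 on the directed count-weighted graph; the
    clustering coefficient is taken on the undirected unweighted projection;
    the h-index is the lobby index over undirected neighbor degrees.
    """
    if len(network) == 0:
        raise ValueError("cannot compute centralities of an empty network")
    G = nx.DiGraph()
    G.add_nodes_from(network.actors)
    for (s, d), c in network.edges.items():
        G.add_edge(s, d, weight=c)
    pagerank = nx.pagerank(G, alpha=PAGERANK_DAMPING, weight="weight")
    U = G.to_undirected()
    clustering = nx.clustering(U)
    degree = dict(U.degree())
    out: dict[str, ActorCentrality] = {}
    for a, profile in network.actors.items():
        nbr_degs = [degree[n] for n in U.neighbors(a)]
        cross = sum(
            1
            for (s, d) in network.edges
            if s == a and network.actors[d].region != profile.region
        )
        out[a] = ActorCentrality(
            pagerank=float(pagerank[a]),
            clustering=float(clustering[a]),
            h_index=h_index_from_degrees(nbr_degs),
            cross_region_out=cross,
        )
    return CentralityTable(out)


def _observed_prefix(walk: InformationWalk, up_to: int):
    visits = [v for v in walk.visits if v.day <= up_to]
    if not visits:
        raise ValueError(
            f"walk {walk.walk_id!r} has no visit at or before day {up_to}"
        )
    return visits


def walk_features(
    walk: InformationWalk,
    network: ReferralNetwork,
    centralities: CentralityTable,
    up_to: int,
) -> np.ndarray:
    """Walk-level feature vector ``p`` of the observed prefix (visits at or
    before ``up_to``).

    Order: (n_nodes, time_range_days, n_mutual_pairs, rvu_sum, n_hospitals,
    mean_pagerank). ``n_nodes`` counts visits with repetition; mutual pairs
    are unordered distinct-actor pairs on the prefix linked in both
    directions; mean PageRank averages over visits with repetition.
    """
    visits = _observed_prefix(walk, up_to)
    actors = [v.actor_id for v in visits]
    distinct = sorted(set(actors))
    n_mutual = sum(
        1
        for i in range(len(distinct))
        for j in range(i + 1, len(distinct))
        if network.edge_count(distinct[i], distinct[j]) > 0
        and network.edge_count(distinct[j], distinct[i]) > 0
    )
    hospitals = {network.actors[a].hospital for a in actors}
    return np.array(
        [
            float(len(visits)),
            float(visits[-1].day - visits[0].day),
            float(n_mutual),
            float(sum(v.rvu for v in visits)),
            float(len(hospitals)),
            float(np.mean([centralities[a].pagerank for a in actors])),
        ]
    )


def candidate_features(actor_id: str, centralities: CentralityTable) -> np.ndarray:
    """Candidate-node vector ``gamma``: (clustering, pagerank, h_index,
    cross_region_out); a deterministic lookup with fixed ordering."""
    c = centralities[actor_id]
    return np.array(
        [c.clustering, c.pagerank, float(c.h_index), float(c.cross_region_out)]
    )


def lastnode_features(
    walk: InformationWalk,
    network: ReferralNetwork,
    centralities: CentralityTable,
    up_to: int,
) -> np.ndarray:
    """Last-node vector ``beta`` for the most recent observed visit.

    The candidate features of the last actor, then: days since that actor's
    previous occurrence on the walk (0 at first occurrence), the RVU of the
    last visit, a flag for multiple occurrences of that actor on the prefix,
    and a flag for the last two visited actors sharing a hospital (0 when the
    prefix has a single visit).
    """
    visits = _observed_prefix(walk, up_to)
    last = visits[-1]
    earlier = [v for v in visits[:-1] if v.actor_id == last.actor_id]
    time_gap = float(last.day - earlier[-1].day) if earlier else 0.0
    multiple = 1.0 if earlier else 0.0
    if len(visits) >= 2:
        h_last = network.actors[last.actor_id].hospital
        h_prev = network.actors[visits[-2].actor_id].hospital
        same_hospital = 1.0 if (h_last == h_prev and h_last != UNKNOWN) else 0.0
    else:
        same_hospital = 0.0
    return np.concatenate(
        [
            candidate_features(last.actor_id, centralities),
            [time_gap, float(last.rvu), multiple, same_hospital],
        ]
    )


def profile_similarity(c: str, j: str, network: ReferralNetwork) -> np.ndarray:
    """Profile-similarity vector ``d(c, j)``: same-specialty, same-residency-
    hospital, and same-region indicators plus the historical referral count
    between the two actors (both directions summed; 0 if no edge).

    The UNKNOWN sentinel never matches, including against itself.
    """
    for a in (c, j):
        if a not in network:
            raise KeyError(f"actor {a!r} not in network")
    pc, pj = network.actors[c], network.actors[j]

    def same(x: str, y: str) -> float:
        return 1.0 if (x == y and x != UNKNOWN) else 0.0

    count = network.edge_count(c, j) + network.edge_count(j, c)
    return np.array(
        [
            same(pc.specialty, pj.specialty),
            same(pc.residency_hospital, pj.residency_hospital),
            same(pc.region, pj.region),
            float(count),
        ]
    )


class FeatureScaler:
    """Per-coordinate scaler fit on training vectors and reusable on test data.

    ``kind='zscore'`` maps to (x - mean)/sd with sd=0 coordinates sent to 0;
    ``kind='minmax'`` maps to (x - min)/(max - min) with constant coordinates
    sent to 0.
    """

    def __init__(self, kind: str = "zscore") -> None:
        if kind not in ("zscore", "minmax"):
            raise ValueError(f"unknown scaler kind {kind!r}")
        self.kind = kind
        self.loc: np.ndarray | None = None
        self.scale: np.ndarray | None = None

    def fit(self, vectors: np.ndarray) -> "FeatureScaler":
        X = np.asarray(vectors, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of row vectors")
        if self.kind == "zscore":
            self.loc = X.mean(axis=0)
            self.scale = X.std(axis=0)
        else:
            self.loc = X.min(axis=0)
            self.scale = X.max(axis=0) - self.loc
        return self

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        if self.loc is None:
            raise RuntimeError("scaler not fitted")
        X = np.asarray(vectors, dtype=float)
        if X.shape[-1] != self.loc.shape[0]:
            raise ValueError(
                f"dimension mismatch: scaler fit on {self.loc.shape[0]}, got {X.shape[-1]}"
            )
        scale = np.where(self.scale == 0, 1.0, self.scale)
        out = (X - self.loc) / scale
        return np.where(self.scale == 0, 0.0, out)


def normalize_features(vectors) -> tuple[np.ndarray, FeatureScaler]:
    """Z-score a collection of row vectors; returns (normalized, fitted scaler).

    Coordinates with zero variance map to 0 so a single vector normalizes to
    the zero vector.
    """
    X = np.asarray(list(vectors), dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one vector of consistent dimension")
    scaler = FeatureScaler("zscore").fit(X)
    return scaler.transform(X), scaler
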