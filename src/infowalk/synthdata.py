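"""Seeded generator of referral-style networks and walk corpora.

The generator emulates the shape of a shared-patient physician network and
its referral sequences: a directed graph with heavy-tailed degrees grown by
preferential attachment, actors carrying hierarchical metadata (hospitals
nested within regions, plus specialty and residency hospital), and walks of
at least six visits with day-resolution non-decreasing timestamps and
occasional revisits.

Walk transitions follow a *planted* preference: the next actor is drawn from
a softmax over a linear score combining the directed adjacency count, a
same-specialty match, a same-region match, and a PageRank pull. The signal
is deliberately expressed in features the prediction model can observe, so
learning is testable; nothing attempts to match the empirical distributions
of real claims data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .netcore import ActorProfile, InformationWalk, ReferralNetwork, Visit, WalkCorpus
from .outlier import simulate_outliers
from .temporal_split import SplitResult, split_at


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for the synthetic benchmark.

    The default corpus (800 walks over 250 actors, observation day 300)
    yields about 500 training walks after the temporal split — the benchmark
    scale used throughout the test suite. Walk lengths span 6–10 visits
    (matching the at-least-six-visit corpus filter) with 1–30 day gaps.
    """

    n_actors: int = 250
    n_regions: int = 4
    hospitals_per_region: int = 3
    n_specialties: int = 8
    edges_per_actor: int = 2
    within_region_prob: float = 0.8
    n_walks: int = 800
    min_walk_length: int = 6
    max_walk_length: int = 10
    start_day_range: tuple[int, int] = (0, 300)
    max_gap_days: int = 30
    observation_day: int = 300
    # planted next-node preference weights; the pagerank pull applies to
    # standardized log-pagerank so hubs attract without monopolizing
    w_adjacency: float = 2.0
    w_same_specialty: float = 2.0
    w_same_region: float = 1.0
    w_pagerank: float = 1.0
    temperature: float = 1.0
    n_outlier_normal: int = 200
    n_outlier_planted: int = 200
    seed: int = 0

    @staticmethod
    def outlier_cohort(seed: int = 0) -> "SynthConfig":
        """Conditions for the outlier-detection benchmark: walks beginning
        within a single month, following strongly stereotyped referral
        routes (low softmax temperature), observed at the end of that month.

        The prediction benchmark uses the year-wide, more diverse default
        corpus; the outlier simulation deliberately samples a homogeneous
        cohort, so planted random-middle walks stand apart from the habitual
        trajectories around them.
        """
        return SynthConfig(
            temperature=0.3,
            start_day_range=(0, 30),
            observation_day=31,
            seed=seed,
        )

    def __post_init__(self) -> None:
        for name in ("n_actors", "n_regions", "hospitals_per_region",
                     "n_specialties", "edges_per_actor", "n_walks",
                     "max_walk_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_walk_length < 2:
            raise ValueError("min_walk_length must be >= 2")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def generate_network(cfg: SynthConfig) -> ReferralNetwork:
    """Directed referral network with preferential-attachment growth.

    Each new actor sends ``edges_per_actor`` referrals to existing actors
    chosen with probability proportional to (degree + 1), preferring targets
    in its own region with probability ``within_region_prob``; a reciprocal
    edge is added with probability 0.3. Edge counts are 1 + Poisson(1).
    Metadata is hierarchical: each actor belongs to one hospital inside its
    region; specialty and residency hospital are uniform draws.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_actors
    ids = [f"a{i:04d}" for i in range(n)]
    regions = [f"region{r}" for r in range(cfg.n_regions)]
    hospitals = {
        r: [f"{r}_hosp{h}" for h in range(cfg.hospitals_per_region)] for r in regions
    }
    all_hospitals = [h for r in regions for h in hospitals[r]]
    specialties = [f"spec{s}" for s in range(cfg.n_specialties)]
    actor_region = [regions[rng.integers(cfg.n_regions)] for _ in range(n)]
    profiles = [
        ActorProfile(
            actor_id=ids[i],
            specialty=specialties[rng.integers(cfg.n_specialties)],
            hospital=hospitals[actor_region[i]][rng.integers(cfg.hospitals_per_region)],
            residency_hospital=all_hospitals[rng.integers(len(all_hospitals))],
            region=actor_region[i],
        )
        for i in range(n)
    ]
    degree = np.zeros(n, dtype=float)
    edges: dict[tuple[str, str], int] = {}

    def add_edge(si: int, ti: int) -> None:
        key = (ids[si], ids[ti])
        if key in edges:
            edges[key] += 1
        else:
            edges[key] = 1 + int(rng.poisson(1.0))
            degree[si] += 1
            degree[ti] += 1

    seed_size = min(3, n)
    for i in range(1, seed_size):
        add_edge(i, i - 1)
    for i in range(seed_size, n):
        same_region = [
            j for j in range(i) if actor_region[j] == actor_region[i]
        ]
        for _ in range(cfg.edges_per_actor):
            candidates = (
                same_region
                if same_region and rng.random() < cfg.within_region_prob
                else list(range(i))
            )
            w = degree[candidates] + 1.0
            t = candidates[rng.choice(len(candidates), p=w / w.sum())]
            add_edge(i, t)
            if rng.random() < 0.3:
                add_edge(t, i)
    return ReferralNetwork(profiles, edges)


def _planted_scores(network: ReferralNetwork, cfg: SynthConfig) -> np.ndarray:
    """Planted preference score matrix score[c, j] over actor indices."""
    ids = sorted(network.actors)
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n))
    for (s, d), c in network.edges.items():
        adj[idx[s], idx[d]] = c
    spec = np.array([network.actors[a].specialty for a in ids])
    reg = np.array([network.actors[a].region for a in ids])
    G = nx.DiGraph()
    G.add_nodes_from(ids)
    for (s, d), c in network.edges.items():
        G.add_edge(s, d, weight=c)
    pr = nx.pagerank(G, alpha=0.85, weight="weight")
    logpr = np.log(np.array([pr[a] for a in ids]))
    pr_z = (logpr - logpr.mean()) / (logpr.std() if logpr.std() else 1.0)
    score = (
        cfg.w_adjacency * np.log1p(adj)
        + cfg.w_same_specialty * (spec[:, None] == spec[None, :])
        + cfg.w_same_region * (reg[:, None] == reg[None, :])
        + cfg.w_pagerank * pr_z[None, :]
    )
    np.fill_diagonal(score, -np.inf)  # no immediate self-transition
    return score


def generate_walks(network: ReferralNetwork, cfg: SynthConfig) -> WalkCorpus:
    """Walk corpus with the planted next-node preference.

    Each walk starts at a uniformly drawn actor on a uniform day in
    ``start_day_range``; successive actors are softmax draws over the planted
    score row of the current actor (temperature 0 degenerates to argmax with
    deterministic index tie-break); gaps are uniform 1..max_gap_days; RVUs
    are positive lognormal draws.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = sorted(network.actors)
    score = _planted_scores(network, cfg)
    n = len(ids)
    walks = []
    lo, hi = cfg.start_day_range
    for k in range(cfg.n_walks):
        length = int(rng.integers(cfg.min_walk_length, cfg.max_walk_length + 1))
        cur = int(rng.integers(n))
        day = int(rng.integers(lo, hi))
        visits = [Visit(ids[cur], day, float(rng.lognormal(1.0, 0.5)))]
        for _ in range(length - 1):
            row = score[cur]
            if cfg.temperature == 0:
                nxt = int(np.argmax(row))
            else:
                z = row / cfg.temperature
                z = z - z[np.isfinite(z)].max()
                p = np.where(np.isfinite(z), np.exp(z), 0.0)
                p /= p.sum()
                nxt = int(rng.choice(n, p=p))
            day += int(rng.integers(1, cfg.max_gap_days + 1))
            visits.append(Visit(ids[nxt], day, float(rng.lognormal(1.0, 0.5))))
            cur = nxt
        walks.append(InformationWalk(f"w{k:05d}", visits))
    return WalkCorpus(walks, network)


@dataclass
class Benchmark:
    """Everything the evaluation pipelines need from one generator call."""

    network: ReferralNetwork
    corpus: WalkCorpus
    split: SplitResult
    outlier_walks: list[InformationWalk] = field(default_factory=list)
    outlier_labels: dict[str, int] = field(default_factory=dict)


def make_benchmark(cfg: SynthConfig | None = None) -> Benchmark:
    """Network + walks + temporal split + labeled outlier benchmark, all
    derived deterministically from the config seed."""
    cfg = cfg or SynthConfig()
    network = generate_network(cfg)
    corpus = generate_walks(network, cfg)
    split = split_at(corpus, cfg.observation_day, min_visits=cfg.min_walk_length)
    walks, labels = simulate_outliers(
        corpus,
        n_normal=cfg.n_outlier_normal,
        n_outlier=cfg.n_outlier_planted,
        seed=cfg.seed + 2,
    )
    return Benchmark(
        network=network,
        corpus=corpus,
        split=split,
        outlier_walks=walks,
        outlier_labels=labels,
    )
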