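"""Proximity-based outlier detection for whole information walks.

Each walk is summarized as a *step series*: for every prefix length t, an
11-entry vector of measures describing the walk-subnetwork — the focal
prefix together with the reference walks sharing at least one actor with
it, plus the mutual overlap edges among those reference walks. A walk of T
visits therefore yields an 11 x T matrix.

Five distance metrics compare two per-measure arrays of (possibly) unequal
length — sliding substring matching, an edit-distance / dynamic-time-warping
recursion with a skip penalty, linear interpolation onto a common [0, 1]
grid, a thresholded longest common subsequence, and sliding-window
averaging. The walk-level distance sums the per-measure distances with equal
weights after corpus-level per-measure min-max scaling.

The detector scores every walk by its distance to its M-th nearest
neighbor and flags the top-K scores (an O(n^2) pairwise scheme). A
simulator plants outliers by keeping a walk's endpoints and redrawing all
middle actors uniformly from a pool; precision@K measures recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .netcore import InformationWalk, ReferralNetwork, Visit, WalkCorpus

N_MEASURES = 11
DEFAULT_LCS_THRESHOLD = 0.05
DEFAULT_DTW_LAMBDA = 1.0
METRIC_NAMES = ("ssm", "dtw", "interp", "lcs", "ssa")
DEFAULT_M_GRID = (1, 2, 5, 10, 20)


@dataclass(frozen=True)
class StepSeries:
    """Per-walk time series: 11 measures x T steps, column t from prefix t+1."""

    walk_id: str
    values: np.ndarray  # shape (11, T)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != N_MEASURES:
            raise ValueError(f"expected ({N_MEASURES}, T) matrix")

    @property
    def length(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Walk-subnetwork step measures


class SubnetworkIndex:
    """Precomputed incidence and overlap structures for a reference corpus,
    shared across all prefix evaluations.

    Holds the actor x walk incidence matrix, the pairwise distinct-common
    counts and Jaccard weights between reference walks, and the actor
    neighborhood matrix of the referral network.
    """

    def __init__(self, reference, network: ReferralNetwork) -> None:
        self.walks = sorted(reference, key=lambda w: w.walk_id)
        self.walk_index = {w.walk_id: i for i, w in enumerate(self.walks)}
        self.actors = sorted(network.actors)
        self.actor_index = {a: i for i, a in enumerate(self.actors)}
        n_a, n_w = len(self.actors), len(self.walks)
        self.inc = np.zeros((n_a, n_w), dtype=bool)
        for j, w in enumerate(self.walks):
            for a in w.actor_set:
                self.inc[self.actor_index[a], j] = True
        self.inc_int = self.inc.astype(np.int64)
        sizes = self.inc.sum(axis=0).astype(float)
        common = self.inc_int.T @ self.inc_int
        np.fill_diagonal(common, 0)
        self.n_common = common
        with np.errstate(divide="ignore", invalid="ignore"):
            union = sizes[:, None] + sizes[None, :] - common
            self.jaccard = np.where(common > 0, common / union, 0.0)
        self.walk_sizes = sizes
        # undirected actor adjacency of the referral network
        self.nbr = np.zeros((n_a, n_a), dtype=bool)
        for s, d in network.edges:
            si, di = self.actor_index[s], self.actor_index[d]
            self.nbr[si, di] = True
            self.nbr[di, si] = True

    def actor_vector(self, actor_ids) -> np.ndarray:
        v = np.zeros(len(self.actors), dtype=bool)
        for a in actor_ids:
            v[self.actor_index[a]] = True
        return v


def _prefix_measures(
    index: SubnetworkIndex, prefix_actors: frozenset[str], exclude_walk: str | None
) -> np.ndarray:
    """The 11 measures of one prefix against the indexed reference corpus."""
    pv = index.actor_vector(prefix_actors)
    common = pv.astype(np.int64) @ index.inc_int  # shared-actor counts per walk
    if exclude_walk is not None and exclude_walk in index.walk_index:
        common[index.walk_index[exclude_walk]] = 0
    member = common > 0
    k = int(member.sum())

    out = np.zeros(N_MEASURES)
    out[0] = k
    out[1] = float(np.count_nonzero(index.nbr[pv].any(axis=0)))
    if k == 0:
        return out
    sub_actor_mask = index.inc[:, member].any(axis=1)
    out[2] = float(np.count_nonzero(index.nbr[sub_actor_mask].any(axis=0)))
    out[3] = out[2] / out[0]

    idx = np.where(member)[0]
    Wc = index.n_common[np.ix_(idx, idx)]  # mutual distinct-common counts
    Wj = index.jaccard[np.ix_(idx, idx)]
    iu = np.triu_indices(k, 1)
    mutual_nc = Wc[iu]
    mutual_edges = mutual_nc > 0
    # focal edges: prefix vs each member walk
    focal_nc = common[idx].astype(float)
    focal_union = len(prefix_actors) + index.walk_sizes[idx] - focal_nc
    focal_jac = focal_nc / focal_union

    edge_nc = np.concatenate([focal_nc, mutual_nc[mutual_edges].astype(float)])
    edge_jac = np.concatenate([focal_jac, Wj[iu][mutual_edges]])
    out[4] = float(edge_jac.mean()) if edge_nc.size else 0.0
    out[5] = float(edge_nc.sum())
    out[6] = float(edge_nc.var()) if edge_nc.size else 0.0

    # binary subnetwork of k member walks + focal node
    A = np.zeros((k + 1, k + 1), dtype=np.int64)
    A[1:, 1:] = (Wc > 0).astype(np.int64)
    A[0, 1:] = 1
    A[1:, 0] = 1
    deg = A.sum(axis=1)
    triples = float((deg * (deg - 1)).sum()) / 2.0
    triangles = float(np.sum((A @ A) * A)) / 6.0
    out[7] = 3.0 * triangles / triples if triples > 0 else 0.0

    total_edges = k + int(mutual_edges.sum())
    remaining_edges = int(mutual_edges.sum())
    out[8] = remaining_edges / total_edges if total_edges else 0.0
    out[9] = remaining_edges / (k * (k - 1) / 2.0) if k >= 2 else 0.0
    if k:
        G = csr_matrix((Wc > 0).astype(np.int8))
        n_comp, labels = connected_components(G, directed=False)
        out[10] = float(np.bincount(labels).max())
    return out


def step_measures(
    prefix: InformationWalk,
    reference,
    network: ReferralNetwork,
    index: SubnetworkIndex | None = None,
) -> np.ndarray:
    """11-entry measure vector of one walk prefix against a reference corpus.

    The focal walk (matched by walk_id) is excluded from the reference. An
    empty reference yields the degenerate zero vector (measure 2, the count
    of actors neighboring the prefix, is still populated) with a warning.
    """
    if index is None:
        ref = list(reference)
        if not ref:
            warnings.warn("empty reference corpus: degenerate measures", stacklevel=2)
            nbrs = set()
            for a in prefix.actor_set:
                nbrs |= set(network.neighbors(a))
            out = np.zeros(N_MEASURES)
            out[1] = float(len(nbrs))
            return out
        index = SubnetworkIndex(ref, network)
    return _prefix_measures(index, prefix.actor_set, exclude_walk=prefix.walk_id)


def compute_step_series(
    walks,
    reference,
    network: ReferralNetwork,
) -> list[StepSeries]:
    """Step series for every walk, sharing one precomputed reference index."""
    walks = list(walks)
    index = SubnetworkIndex(list(reference), network)
    out = []
    for w in walks:
        cols = []
        seen: set[str] = set()
        for t in range(1, len(w) + 1):
            seen.add(w.visits[t - 1].actor_id)
            cols.append(_prefix_measures(index, frozenset(seen), exclude_walk=w.walk_id))
        out.append(StepSeries(w.walk_id, np.column_stack(cols)))
    return out


def minmax_scale_series(series: list[StepSeries]) -> list[StepSeries]:
    """Per-measure min-max scaling across the whole corpus; constant measures
    scale to 0. Applied before any distance computation."""
    allv = np.concatenate([s.values for s in series], axis=1)
    lo = allv.min(axis=1, keepdims=True)
    hi = allv.max(axis=1, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    return [
        StepSeries(s.walk_id, np.where(hi - lo == 0, 0.0, (s.values - lo) / span))
        for s in series
    ]


# ---------------------------------------------------------------------------
# Distance metrics between per-measure arrays.
#
# Batch cores operate on stacked arrays of shape (P, l) and (P, s) — one row
# per measure — returning a (P,) distance vector; the public scalar functions
# wrap them for 1-D inputs. All metrics require the first argument to be the
# longer array; ``walk_distance`` orients automatically.


def _as_batch(LA, SA):
    LA = np.atleast_2d(np.asarray(LA, dtype=float))
    SA = np.atleast_2d(np.asarray(SA, dtype=float))
    if LA.shape[0] != SA.shape[0]:
        raise ValueError("measure dimensions differ")
    if LA.shape[1] == 0 or SA.shape[1] == 0:
        raise ValueError("empty array")
    if LA.shape[1] < SA.shape[1]:
        raise ValueError("first argument must be the longer array")
    return LA, SA


def _ssm_batch(LA: np.ndarray, SA: np.ndarray) -> np.ndarray:
    l, s = LA.shape[1], SA.shape[1]
    windows = np.stack([LA[:, i : i + s] for i in range(l - s + 1)])  # (l-s+1, P, s)
    return np.abs(windows - SA[None]).sum(axis=2).min(axis=0)


def _dtw_batch(LA: np.ndarray, SA: np.ndarray, lam: float) -> np.ndarray:
    if lam < 0:
        raise ValueError("lambda penalty must be >= 0")
    P, l = LA.shape
    s = SA.shape[1]
    prev = np.tile(np.arange(s + 1, dtype=float) * lam, (P, 1))  # d(0, j) = j*lam
    for i in range(1, l + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i * lam  # d(i, 0) = i*lam
        cost = np.abs(LA[:, i - 1 : i] - SA)  # (P, s)
        for j in range(1, s + 1):
            cur[:, j] = np.minimum(
                prev[:, j - 1] + cost[:, j - 1],
                np.minimum(cur[:, j - 1] + lam, prev[:, j] + lam),
            )
        prev = cur
    return prev[:, s]


def _interp_batch(LA: np.ndarray, SA: np.ndarray) -> np.ndarray:
    l, s = LA.shape[1], SA.shape[1]
    if l < 2 or s < 2:
        raise ValueError("interpolation needs arrays of length >= 2")
    tl = interp_time_grid(l)
    ts = interp_time_grid(s)
    aligned = np.stack([np.interp(ts, tl, row) for row in LA])
    return np.abs(aligned - SA).sum(axis=1)


def _lcs_batch(LA: np.ndarray, SA: np.ndarray, threshold: float) -> np.ndarray:
    if threshold <= 0:
        raise ValueError("equality threshold must be > 0")
    P, l = LA.shape
    s = SA.shape[1]
    prev = np.zeros((P, s + 1), dtype=np.int64)
    for i in range(1, l + 1):
        cur = np.zeros_like(prev)
        eq = np.abs(LA[:, i - 1 : i] - SA) < threshold  # (P, s)
        for j in range(1, s + 1):
            cur[:, j] = np.where(
                eq[:, j - 1],
                prev[:, j - 1] + 1,
                np.maximum(prev[:, j], cur[:, j - 1]),
            )
        prev = cur
    m = prev[:, s].astype(float)
    return (l + s - 2 * m) / (l + s)


def _ssa_batch(LA: np.ndarray, SA: np.ndarray) -> np.ndarray:
    l, s = LA.shape[1], SA.shape[1]
    w = l - s + 1
    means = np.stack([LA[:, i : i + w].mean(axis=1) for i in range(s)], axis=1)
    return np.abs(means - SA).sum(axis=1)


def interp_time_grid(n: int) -> np.ndarray:
    """Equal-interval time allocation of an n-element array on [0, 1]: the
    first element sits at 0 and the last at 1 (for n = 5: 0, 0.25, 0.5,
    0.75, 1.0)."""
    if n < 2:
        raise ValueError("need at least 2 elements for a time grid")
    return np.linspace(0.0, 1.0, n)


def dist_ssm(LA, SA) -> float:
    """Minimum Manhattan distance between SA and any s-length consecutive
    window of the longer array LA."""
    return float(_ssm_batch(*_as_batch(LA, SA))[0])


def dist_dtw(LA, SA, lambda_penalty: float = DEFAULT_DTW_LAMBDA) -> float:
    """Edit-distance / DTW recursion: match costs |LA[i]-SA[j]|, skips cost
    lambda; boundary d(i,0) = i*lambda, d(0,j) = j*lambda."""
    LA, SA = _as_batch(LA, SA)
    return float(_dtw_batch(LA, SA, lambda_penalty)[0])


def dist_interp(LA, SA) -> float:
    """Manhattan distance after linearly interpolating LA onto SA's
    equal-interval time grid on [0, 1]; works for either orientation."""
    LA = np.atleast_2d(np.asarray(LA, dtype=float))
    SA = np.atleast_2d(np.asarray(SA, dtype=float))
    return float(_interp_batch(LA, SA)[0])


def dist_lcs(LA, SA, eq_threshold: float = DEFAULT_LCS_THRESHOLD) -> float:
    """Thresholded longest-common-subsequence distance (l + s - 2m)/(l + s),
    where m is the LCS length under |x - y| < threshold equality."""
    LA, SA = _as_batch(LA, SA)
    return float(_lcs_batch(LA, SA, eq_threshold)[0])


def dist_ssa(LA, SA) -> float:
    """Slide a window of length l-s+1 over LA, one step per iteration, to get
    s window means; Manhattan distance between those means and SA."""
    return float(_ssa_batch(*_as_batch(LA, SA))[0])


def _metric_batch(metric: str, LA: np.ndarray, SA: np.ndarray, params: dict) -> np.ndarray:
    if metric == "ssm":
        return _ssm_batch(LA, SA)
    if metric == "dtw":
        return _dtw_batch(LA, SA, params.get("lambda_penalty", DEFAULT_DTW_LAMBDA))
    if metric == "interp":
        return _interp_batch(LA, SA)
    if metric == "lcs":
        return _lcs_batch(LA, SA, params.get("eq_threshold", DEFAULT_LCS_THRESHOLD))
    if metric == "ssa":
        return _ssa_batch(LA, SA)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")


def walk_distance(a: StepSeries, b: StepSeries, metric: str, **params) -> float:
    """Equal-weighted sum over the 11 measures of the chosen per-array metric,
    orienting (longer, shorter) by series length; symmetric by construction."""
    if a.length >= b.length:
        LA, SA = a.values, b.values
    else:
        LA, SA = b.values, a.values
    return float(_metric_batch(metric, LA, SA, params).sum())


# ---------------------------------------------------------------------------
# M-th nearest-neighbor outlier scoring


@dataclass
class OutlierScores:
    scores: dict[str, float]
    ranked: list[str]  # top-K walk ids by descending score, ties by walk_id

    def to_frame(self) -> pd.DataFrame:
        rows = [(wid, self.scores[wid], r + 1) for r, wid in enumerate(self.ranked)]
        return pd.DataFrame(rows, columns=["walk_id", "score", "rank"])


def pairwise_distances(series: list[StepSeries], metric: str, **params) -> np.ndarray:
    """Symmetric n x n distance matrix between scaled step series."""
    n = len(series)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = walk_distance(series[i], series[j], metric, **params)
    return D


def knn_outlier_scores(
    series: list[StepSeries],
    metric: str,
    m_nn: int,
    k: int,
    distances: np.ndarray | None = None,
    **params,
) -> OutlierScores:
    """Score each walk by its distance to its m_nn-th nearest neighbor among
    the other walks; return the descending top-k list (ties by walk id)."""
    n = len(series)
    if m_nn < 1:
        raise ValueError("m_nn must be >= 1")
    if n <= m_nn:
        raise ValueError(f"need more than m_nn={m_nn} walks, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    D = pairwise_distances(series, metric, **params) if distances is None else distances
    ids = [s.walk_id for s in series]
    scores: dict[str, float] = {}
    for i in range(n):
        others = np.delete(D[i], i)
        scores[ids[i]] = float(np.partition(others, m_nn - 1)[m_nn - 1])
    ranked = sorted(ids, key=lambda w: (-scores[w], w))[: min(k, n)]
    return OutlierScores(scores=scores, ranked=ranked)


def precision_at_k(scores: OutlierScores, labels: dict[str, int]) -> float:
    """Fraction of true outliers (label 1) among the returned top-K walks."""
    missing = [w for w in scores.scores if w not in labels]
    if missing:
        raise ValueError(f"labels missing for walks: {missing[:3]}...")
    if not scores.ranked:
        return 0.0
    return sum(labels[w] for w in scores.ranked) / len(scores.ranked)


def tune_m_nn(
    series: list[StepSeries],
    metric: str,
    labels: dict[str, int],
    k: int,
    grid=DEFAULT_M_GRID,
    distances: np.ndarray | None = None,
    **params,
) -> tuple[int, float]:
    """Grid-search the neighbor parameter, maximizing precision@k on a
    labeled benchmark; ties resolve to the smaller M. Returns (M, precision)."""
    if distances is None:
        distances = pairwise_distances(series, metric, **params)
    best: tuple[int, float] | None = None
    for m in grid:
        if m >= len(series):
            continue
        sc = knn_outlier_scores(series, metric, m, k, distances=distances, **params)
        prec = precision_at_k(sc, labels)
        if best is None or prec > best[1]:
            best = (m, prec)
    if best is None:
        raise ValueError("no feasible M in grid for this corpus size")
    return best


# ---------------------------------------------------------------------------
# Outlier simulation


def write_labels(labels: dict[str, int], path) -> None:
    """Benchmark labels as TSV (walk_id, is_outlier)."""
    pd.DataFrame(sorted(labels.items()), columns=["walk_id", "is_outlier"]).to_csv(
        path, sep="\t", index=False
    )


def simulate_outliers(
    pool: WalkCorpus | list[InformationWalk],
    n_normal: int = 2500,
    n_outlier: int = 2500,
    seed: int = 0,
) -> tuple[list[InformationWalk], dict[str, int]]:
    """Build a labeled benchmark: ``n_normal`` walks kept verbatim (label 0)
    and ``n_outlier`` walks corrupted into outliers (label 1).

    A corrupted walk keeps its first and last actor plus all timestamps and
    RVUs; every middle actor is replaced by an independent uniform draw from
    the set of actors appearing anywhere on the pool's walks. Only walks of
    length >= 3 are eligible for corruption.
    """
    walks = sorted(pool, key=lambda w: w.walk_id)
    eligible = [w for w in walks if len(w) >= 3]
    if len(walks) < n_normal + n_outlier or len(eligible) < n_outlier:
        raise ValueError(
            f"pool too small: {len(walks)} walks ({len(eligible)} eligible) "
            f"for {n_normal}+{n_outlier}"
        )
    rng = np.random.default_rng(seed)
    actor_pool = sorted({a for w in walks for a in w.actor_set})
    chosen_out = list(rng.choice(len(eligible), size=n_outlier, replace=False))
    out_ids = {eligible[i].walk_id for i in chosen_out}
    remaining = [w for w in walks if w.walk_id not in out_ids]
    chosen_norm = list(rng.choice(len(remaining), size=n_normal, replace=False))
    benchmark: list[InformationWalk] = []
    labels: dict[str, int] = {}
    for i in chosen_norm:
        w = remaining[i]
        benchmark.append(w)
        labels[w.walk_id] = 0
    for i in chosen_out:
        w = eligible[i]
        middles = rng.integers(0, len(actor_pool), size=len(w) - 2)
        visits = [w.visits[0]] + [
            Visit(actor_pool[m], v.day, v.rvu)
            for m, v in zip(middles, w.visits[1:-1])
        ] + [w.visits[-1]]
        benchmark.append(InformationWalk(w.walk_id, visits))
        labels[w.walk_id] = 1
    benchmark.sort(key=lambda w: w.walk_id)
    return benchmark, labels
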