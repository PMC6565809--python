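"""End-to-end orchestration: next-node prediction runs, walk-network pattern
reports, and the outlier-detection benchmark.

These functions are what the CLI and the examples call; each is a pure
function of its inputs plus a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, evaluation, features, outlier, walknet
from .bpr import (
    BPRHyper,
    BPRParams,
    CandidatePool,
    TrainPair,
    rank_candidates,
    train,
)
from .features import CentralityTable, FeatureScaler
from .netcore import ReferralNetwork, WalkCorpus
from .temporal_split import SplitExample, SplitResult

logger = logging.getLogger(__name__)


@dataclass
class FeatureContext:
    """Scaled feature providers shared by training and prediction.

    Scalers are fit on training data only; candidate (gamma) vectors are
    precomputed for the candidate set J.
    """

    network: ReferralNetwork
    centralities: CentralityTable
    pool: CandidatePool
    p_scaler: FeatureScaler
    beta_scaler: FeatureScaler
    d_scaler: FeatureScaler
    gamma_scaler: FeatureScaler
    train_pairs: list[TrainPair]
    train_examples: list[SplitExample]

    def scaled_p_beta(self, ex: SplitExample) -> tuple[np.ndarray, np.ndarray]:
        up_to = ex.observed.end_day
        p = features.walk_features(ex.observed, self.network, self.centralities, up_to)
        b = features.lastnode_features(ex.observed, self.network, self.centralities, up_to)
        return (
            self.p_scaler.transform(p),
            self.beta_scaler.transform(b),
        )

    def scaled_d(self, c: str, j: str) -> np.ndarray:
        return self.d_scaler.transform(features.profile_similarity(c, j, self.network))

    def d_matrix(self, c: str, candidate_ids: list[str]) -> np.ndarray:
        D = np.stack(
            [features.profile_similarity(c, j, self.network) for j in candidate_ids]
        )
        return self.d_scaler.transform(D)


def build_feature_context(
    split: SplitResult,
    network: ReferralNetwork,
    centralities: CentralityTable,
) -> FeatureContext:
    """Compute raw training features, fit the scalers, and assemble the
    candidate pool over J."""
    if not split.train:
        raise ValueError("empty training set")
    raw_p, raw_beta, raw_d = [], [], []
    for ex in split.train:
        up_to = ex.observed.end_day
        raw_p.append(features.walk_features(ex.observed, network, centralities, up_to))
        raw_beta.append(
            features.lastnode_features(ex.observed, network, centralities, up_to)
        )
        raw_d.append(features.profile_similarity(ex.last_actor, ex.f, network))
    p_scaler = FeatureScaler("zscore").fit(np.stack(raw_p))
    beta_scaler = FeatureScaler("zscore").fit(np.stack(raw_beta))
    d_scaler = FeatureScaler("zscore").fit(np.stack(raw_d))
    cand_ids = sorted(split.candidates)
    gammas_raw = np.stack(
        [features.candidate_features(a, centralities) for a in cand_ids]
    ) if cand_ids else np.zeros((0, features.H_CANDIDATE))
    gamma_scaler = FeatureScaler("zscore")
    if len(cand_ids):
        gamma_scaler.fit(gammas_raw)
        gammas = gamma_scaler.transform(gammas_raw)
    else:
        gammas = gammas_raw
    pool = CandidatePool(cand_ids, gammas)
    pairs = []
    for ex, p_raw, b_raw, d_raw in zip(split.train, raw_p, raw_beta, raw_d):
        gamma_f = (
            pool.gammas[pool.index[ex.f]]
            if ex.f in pool.index
            else gamma_scaler.transform(features.candidate_features(ex.f, centralities))
        )
        pairs.append(
            TrainPair(
                p=p_scaler.transform(p_raw),
                beta=beta_scaler.transform(b_raw),
                gamma_f=np.asarray(gamma_f, float),
                d_f=d_scaler.transform(d_raw),
            )
        )
    return FeatureContext(
        network=network,
        centralities=centralities,
        pool=pool,
        p_scaler=p_scaler,
        beta_scaler=beta_scaler,
        d_scaler=d_scaler,
        gamma_scaler=gamma_scaler,
        train_pairs=pairs,
        train_examples=list(split.train),
    )


def train_bpr(
    ctx: FeatureContext,
    candidates: frozenset[str],
    hyper: BPRHyper,
    freeze_su: bool = False,
) -> tuple[BPRParams, list[float]]:
    """Train the ranking model on the context's training pairs with uniform
    negative sampling from J \\ {c_i, f_i}."""
    cand_sorted = sorted(candidates)
    per_pair = [
        [j for j in cand_sorted if j not in (ex.last_actor, ex.f)]
        for ex in ctx.train_examples
    ]
    d_cache: dict[tuple[str, str], np.ndarray] = {}

    def d_lookup(pair_idx: int, j: str) -> np.ndarray:
        c = ctx.train_examples[pair_idx].last_actor
        key = (c, j)
        if key not in d_cache:
            d_cache[key] = ctx.scaled_d(c, j)
        return d_cache[key]

    return train(
        ctx.train_pairs, per_pair, ctx.pool, d_lookup, hyper=hyper, freeze_su=freeze_su
    )


def _scores_for_example(
    model: str,
    ex: SplitExample,
    ctx: FeatureContext,
    params: BPRParams | None,
    nbr_index: baselines.NeighborIndex,
    transitions: baselines.TransitionCounts,
) -> dict[str, float]:
    c = ex.last_actor
    cand_ids = [j for j in ctx.pool.actor_ids if j != c]
    if model in ("bpr_iw", "bpr_no_iw"):
        assert params is not None
        p, beta = ctx.scaled_p_beta(ex)
        idxs = [ctx.pool.index[j] for j in cand_ids]
        G = ctx.pool.gammas[idxs]
        D = ctx.d_matrix(c, cand_ids)
        s = (p @ params.S) @ G.T + (beta @ params.U) @ G.T + D @ params.w
        return dict(zip(cand_ids, s.tolist()))
    if model == "mp":
        return {j: baselines.score_mp(c, j, ctx.network) for j in cand_ids}
    if model == "cn":
        return {j: baselines.score_cn(c, j, nbr_index) for j in cand_ids}
    if model == "pa":
        return {j: baselines.score_pa(c, j, nbr_index) for j in cand_ids}
    if model == "aa":
        return {j: baselines.score_aa(c, j, nbr_index) for j in cand_ids}
    if model == "jaccard":
        return {j: baselines.score_jaccard(c, j, nbr_index) for j in cand_ids}
    if model == "mc2":
        seq = ex.observed.actor_sequence
        prev = seq[-2] if len(seq) >= 2 else None
        return {
            j: baselines.score_mc2(prev, c, j, transitions) for j in cand_ids
        }
    raise ValueError(f"unknown model {model!r}; choose from {baselines.MODEL_NAMES}")


@dataclass
class PredictionRun:
    model: str
    k: int
    batch: evaluation.PredictionBatch
    hr: float
    mpr: float | None
    objective_trace: list[float] = field(default_factory=list)
    params: BPRParams | None = None


def run_prediction(
    split: SplitResult,
    network: ReferralNetwork,
    centralities: CentralityTable,
    model: str,
    k: int = 20,
    hyper: BPRHyper | None = None,
    ctx: FeatureContext | None = None,
) -> PredictionRun:
    """Evaluate one model on a temporal split: train (for the ranking
    models), rank J \\ {c_i} for every test walk, and compute HR / MPR."""
    if k < 1:
        raise ValueError("K must be >= 1")
    if not split.test:
        raise ValueError("empty test set")
    if ctx is None:
        ctx = build_feature_context(split, network, centralities)
    params, trace = None, []
    if model in ("bpr_iw", "bpr_no_iw"):
        hyper = hyper or BPRHyper()
        params, trace = train_bpr(
            ctx, split.candidates, hyper, freeze_su=(model == "bpr_no_iw")
        )
    nbr_index = baselines.NeighborIndex(network)
    transitions = baselines.TransitionCounts.from_walks(
        ex.observed for ex in split.train
    )
    preds = []
    for ex in split.test:
        scores = _scores_for_example(model, ex, ctx, params, nbr_index, transitions)
        ranked = rank_candidates(scores, k, exclude={ex.last_actor})
        preds.append(evaluation.Prediction(ex.walk_id, tuple(ranked), ex.f))
    batch = evaluation.PredictionBatch(preds, k)
    hr = evaluation.hit_rate(batch)
    mpr_val = evaluation.mpr(batch) if hr > 0 else None
    return PredictionRun(
        model=model, k=k, batch=batch, hr=hr, mpr=mpr_val,
        objective_trace=trace, params=params,
    )


def prediction_report(runs: list[PredictionRun], T: int) -> pd.DataFrame:
    rows = [
        (r.model, T, r.k, r.hr, r.mpr if r.mpr is not None else float("nan"))
        for r in runs
    ]
    return pd.DataFrame(rows, columns=["model", "T", "K", "HR", "MPR"])


def grouped_recall_reports(
    run: PredictionRun, split: SplitResult, n_groups: int = 5
) -> dict[str, pd.DataFrame]:
    """Quintile-grouped recall tables by observed walk length and time range."""
    by_id = {ex.walk_id: ex for ex in split.test}
    lengths = {w: float(len(by_id[w].observed)) for w in by_id}
    spans = {
        w: float(by_id[w].observed.end_day - by_id[w].observed.start_day)
        for w in by_id
    }
    return {
        "length": evaluation.grouped_recall(run.batch, lengths, n_groups),
        "time_range": evaluation.grouped_recall(run.batch, spans, n_groups),
    }


CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, params: BPRParams, ctx: FeatureContext) -> None:
    """Persist a trained model as a single JSON archive: parameters, the four
    fitted scalers, hyperparameters, and a schema version."""
    import dataclasses
    import json

    def scaler(s: FeatureScaler) -> dict:
        return {"kind": s.kind,
                "loc": None if s.loc is None else s.loc.tolist(),
                "scale": None if s.scale is None else s.scale.tolist()}

    payload = {
        "schema": CHECKPOINT_SCHEMA,
        "S": params.S.tolist(),
        "U": params.U.tolist(),
        "w": params.w.tolist(),
        "V": None if params.V is None else params.V.tolist(),
        "hyper": dataclasses.asdict(params.hyper),
        "scalers": {
            "p": scaler(ctx.p_scaler), "beta": scaler(ctx.beta_scaler),
            "d": scaler(ctx.d_scaler), "gamma": scaler(ctx.gamma_scaler),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[BPRParams, dict[str, FeatureScaler]]:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {payload.get('schema')!r}")
    params = BPRParams(
        S=np.array(payload["S"]), U=np.array(payload["U"]),
        w=np.array(payload["w"]),
        V=None if payload["V"] is None else np.array(payload["V"]),
        hyper=BPRHyper(**payload["hyper"]),
    )
    scalers = {}
    for name, s in payload["scalers"].items():
        sc = FeatureScaler(s["kind"])
        sc.loc = None if s["loc"] is None else np.array(s["loc"])
        sc.scale = None if s["scale"] is None else np.array(s["scale"])
        scalers[name] = sc
    return params, scalers


# ---------------------------------------------------------------------------
# Walk-network pattern report


def run_walknet(corpus: WalkCorpus) -> dict:
    """Build the walk network, detect the three structural patterns, and
    contrast homotopic vs non-homotopic edge weights with Welch t-tests."""
    wn = walknet.build_walk_network(corpus)
    homotopic = walknet.find_homotopic_pairs(corpus)
    lifting = walknet.find_lifting_pairs(corpus)
    composition = walknet.find_composition_triples(corpus)
    contrasts = {}
    for attr in ("jaccard", "shared_visits", "shared_rvu"):
        a = [getattr(e, attr) for pair, e in wn.edges.items() if pair in homotopic]
        b = [getattr(e, attr) for pair, e in wn.edges.items() if pair not in homotopic]
        if len(a) >= 2 and len(b) >= 2:
            t, p, means = walknet.compare_groups(a, b)
            contrasts[attr] = {
                "t": t, "p": p, "mean_homotopic": means[0], "mean_other": means[1]
            }
    return {
        "walk_network": wn,
        "homotopic_pairs": homotopic,
        "lifting_pairs": lifting,
        "composition_triples": composition,
        "contrasts": contrasts,
        "pagerank": walknet.walknet_pagerank(wn) if wn.nodes else {},
    }


# ---------------------------------------------------------------------------
# Outlier benchmark


def run_outlier_benchmark(
    walks,
    labels: dict[str, int],
    network: ReferralNetwork,
    k: int = 50,
    metrics=outlier.METRIC_NAMES,
    m_grid=outlier.DEFAULT_M_GRID,
) -> pd.DataFrame:
    """Step series -> scaled distances -> tuned M-th-NN scoring -> precision@K
    for each metric; returns one row per metric."""
    series = outlier.compute_step_series(walks, walks, network)
    series = outlier.minmax_scale_series(series)
    rows = []
    for metric in metrics:
        D = outlier.pairwise_distances(series, metric)
        m_best, prec = outlier.tune_m_nn(
            series, metric, labels, k, grid=m_grid, distances=D
        )
        rows.append((metric, m_best, k, prec))
    return pd.DataFrame(rows, columns=["metric", "m_nn", "K", "precision_at_k"])
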