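"""Pairwise-ranking next-node model for information walks (BPR-IW).

The preference score between an observed walk (summary vector ``p``, last
node ``beta``) and a candidate node (``gamma``, profile similarity ``d``) is

    X(p, c, j) = p^T S gamma_j + beta_c^T U gamma_j + w . d(c, j)

where S (M x H), U (N x H) and w (length L) are trained. The full score also
admits a candidate-independent term p^T V beta; since it cancels in every
score difference and within-walk ranking, V is never updated and the term is
disabled by default (it can be re-enabled, initialized but frozen, for
literal fidelity).

Training maximizes the pairwise-ranking posterior: for each training walk
with ground-truth next node f and sampled negative j,

    sum log sigmoid(X(..., f) - X(..., j)) - (lambda/2) ||Theta||^2

by stochastic gradient ascent with uniform negative sampling from the
candidate pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.001
DEFAULT_STEP_SIZE = 0.05
DEFAULT_EPOCHS = 20
INIT_SD = 0.01


@dataclass(frozen=True)
class BPRHyper:
    lambda_reg: float = DEFAULT_LAMBDA
    step_size: float = DEFAULT_STEP_SIZE
    epochs: int = DEFAULT_EPOCHS
    negatives_per_pair: int = 1
    seed: int = 0
    include_v: bool = False

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negatives_per_pair < 1:
            raise ValueError("negatives_per_pair must be >= 1")


@dataclass
class BPRParams:
    """Trainable parameters: S (M x H), U (N x H), w (L,), optional frozen V."""

    S: np.ndarray
    U: np.ndarray
    w: np.ndarray
    V: np.ndarray | None = None
    hyper: BPRHyper = field(default_factory=BPRHyper)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.w = np.asarray(self.w, dtype=float).ravel()
        if self.S.ndim != 2 or self.U.ndim != 2 or self.S.shape[1] != self.U.shape[1]:
            raise ValueError("S and U must be 2-D with a common candidate dimension H")
        for arr in (self.S, self.U, self.w):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @classmethod
    def init_random(
        cls,
        m: int,
        n: int,
        h: int,
        l: int,
        hyper: BPRHyper | None = None,
        rng: np.random.Generator | None = None,
    ) -> "BPRParams":
        """Gaussian initialization (mean 0, sd 0.01) under the hyper seed."""
        hyper = hyper or BPRHyper()
        if rng is None:
            rng = np.random.default_rng(hyper.seed)
        V = rng.normal(0.0, INIT_SD, (m, n)) if hyper.include_v else None
        return cls(
            S=rng.normal(0.0, INIT_SD, (m, h)),
            U=rng.normal(0.0, INIT_SD, (n, h)),
            w=rng.normal(0.0, INIT_SD, l),
            V=V,
            hyper=hyper,
        )

    @classmethod
    def zeros(cls, m: int, n: int, h: int, l: int, hyper: BPRHyper | None = None):
        return cls(
            S=np.zeros((m, h)), U=np.zeros((n, h)), w=np.zeros(l),
            hyper=hyper or BPRHyper(),
        )

    def copy(self) -> "BPRParams":
        return BPRParams(
            S=self.S.copy(), U=self.U.copy(), w=self.w.copy(),
            V=None if self.V is None else self.V.copy(), hyper=self.hyper,
        )

    def sq_norm(self) -> float:
        """||Theta||^2 over the trained parameters S, U, w (V excluded)."""
        return float(
            np.sum(self.S**2) + np.sum(self.U**2) + np.sum(self.w**2)
        )


def sigmoid(x):
    """Numerically stable logistic function, elementwise; never under/overflows
    into an exception for |x| up to ~745 (subnormal but positive output)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    with np.errstate(under="ignore"):
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def log_sigmoid(x):
    """log(sigmoid(x)) without intermediate underflow."""
    x = np.asarray(x, dtype=float)
    with np.errstate(under="ignore"):
        out = np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))), x - np.log1p(np.exp(x)))
    return out if out.ndim else float(out)


def preference_score(
    p: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    d: np.ndarray,
    params: BPRParams,
) -> float:
    """Preference score X(p, c, j); deterministic in its inputs.

    With ``include_v`` the candidate-independent p^T V beta offset is added;
    it never changes candidate rankings for a fixed walk.
    """
    p = np.asarray(p, float)
    beta = np.asarray(beta, float)
    gamma = np.asarray(gamma, float)
    d = np.asarray(d, float)
    if (
        p.shape[0] != params.S.shape[0]
        or beta.shape[0] != params.U.shape[0]
        or gamma.shape[0] != params.S.shape[1]
        or d.shape[0] != params.w.shape[0]
    ):
        raise ValueError("feature/parameter dimension mismatch")
    score = float(p @ params.S @ gamma + beta @ params.U @ gamma + params.w @ d)
    if params.hyper.include_v and params.V is not None:
        score += float(p @ params.V @ beta)
    return score


@dataclass(frozen=True)
class TrainPair:
    """One training observation: walk summary p, last-node beta, ground-truth
    candidate features, and a pool of negative candidate features with the
    matching profile-similarity vectors."""

    p: np.ndarray
    beta: np.ndarray
    gamma_f: np.ndarray
    d_f: np.ndarray


def pair_log_likelihood(
    pair: TrainPair, gamma_j: np.ndarray, d_j: np.ndarray, params: BPRParams
) -> float:
    """log sigmoid of the preference gap between ground truth and negative j."""
    delta = preference_score(pair.p, pair.beta, pair.gamma_f, pair.d_f, params) - \
        preference_score(pair.p, pair.beta, gamma_j, d_j, params)
    return float(log_sigmoid(delta))


def bpr_objective(
    pairs: list[tuple[TrainPair, np.ndarray, np.ndarray]], params: BPRParams
) -> float:
    """The sampled ranking objective: sum of pairwise log-likelihoods minus
    (lambda/2) ||Theta||^2 over the supplied (pair, gamma_j, d_j) triples."""
    if not pairs:
        raise ValueError("empty training set")
    total = sum(
        pair_log_likelihood(pair, gamma_j, d_j, params)
        for pair, gamma_j, d_j in pairs
    )
    return total - 0.5 * params.hyper.lambda_reg * params.sq_norm()


def sgd_step(
    pair: TrainPair,
    gamma_j: np.ndarray,
    d_j: np.ndarray,
    params: BPRParams,
    in_place: bool = False,
) -> BPRParams:
    """One stochastic gradient-ascent update on a (positive, negative) pair.

    theta <- theta + step * ((1 - sigmoid(delta)) d(delta)/d(theta) - lambda theta)
    with d(delta)/dS = p (gamma_f - gamma_j)^T, d(delta)/dU = beta (gamma_f -
    gamma_j)^T, d(delta)/dw = d_f - d_j. V, if present, is never updated.
    """
    out = params if in_place else params.copy()
    dgamma = np.asarray(pair.gamma_f, float) - np.asarray(gamma_j, float)
    dd = np.asarray(pair.d_f, float) - np.asarray(d_j, float)
    delta = (
        pair.p @ out.S @ dgamma + pair.beta @ out.U @ dgamma + out.w @ dd
    )
    if not np.isfinite(delta):
        raise FloatingPointError("non-finite preference gap in SGD step")
    coef = 1.0 - sigmoid(delta)
    lam, step = out.hyper.lambda_reg, out.hyper.step_size
    out.S += step * (coef * np.outer(pair.p, dgamma) - lam * out.S)
    out.U += step * (coef * np.outer(pair.beta, dgamma) - lam * out.U)
    out.w += step * (coef * dd - lam * out.w)
    if not (np.all(np.isfinite(out.S)) and np.all(np.isfinite(out.U))
            and np.all(np.isfinite(out.w))):
        raise FloatingPointError("non-finite parameters after SGD step")
    return out


class CandidatePool:
    """Candidate features indexed by actor id, supporting vectorized scoring."""

    def __init__(self, actor_ids: list[str], gammas: np.ndarray) -> None:
        self.actor_ids = list(actor_ids)
        self.index = {a: i for i, a in enumerate(self.actor_ids)}
        self.gammas = np.asarray(gammas, dtype=float)
        if self.gammas.shape[0] != len(self.actor_ids):
            raise ValueError("one gamma row per actor required")

    def __len__(self) -> int:
        return len(self.actor_ids)


def train(
    pairs: list[TrainPair],
    candidate_ids_per_pair: list[list[str]],
    pool: CandidatePool,
    d_lookup,
    hyper: BPRHyper | None = None,
    params: BPRParams | None = None,
    freeze_su: bool = False,
) -> tuple[BPRParams, list[float]]:
    """SGD training loop over epochs with uniform negative sampling.

    Parameters
    ----------
    pairs
        Training observations (one per training walk).
    candidate_ids_per_pair
        For each pair, the eligible negative candidates J \\ {c_i, f_i}.
        Pairs with an empty pool are skipped with a logged warning.
    pool
        Candidate feature pool holding the gamma vector of every actor in J.
    d_lookup
        Callable ``(pair_index, actor_id) -> d`` giving the profile-similarity
        vector between the pair's last node and a candidate.
    freeze_su
        Train only w (S and U pinned at zero) — the profile-only model.

    Returns the trained parameters and the per-epoch mean of the sampled
    pairwise objective (log-likelihood minus the regularizer contribution).
    """
    if not pairs:
        raise ValueError("empty training set")
    if len(pairs) != len(candidate_ids_per_pair):
        raise ValueError("one candidate list per training pair required")
    hyper = hyper if hyper is not None else BPRHyper()
    rng = np.random.default_rng(hyper.seed)
    if params is None:
        m = pairs[0].p.shape[0]
        n = pairs[0].beta.shape[0]
        h = pairs[0].gamma_f.shape[0]
        l = pairs[0].d_f.shape[0]
        params = BPRParams.init_random(m, n, h, l, hyper=hyper, rng=rng)
        if freeze_su:
            params.S[:] = 0.0
            params.U[:] = 0.0
    params = params.copy()
    trace: list[float] = []
    order = np.arange(len(pairs))
    skipped = set()
    for _epoch in range(hyper.epochs):
        rng.shuffle(order)
        total, count = 0.0, 0
        for idx in order:
            pair = pairs[idx]
            cands = candidate_ids_per_pair[idx]
            if not cands:
                if idx not in skipped:
                    logger.warning(
                        "no negative candidates for training pair %d; skipping", idx
                    )
                    skipped.add(idx)
                continue
            for _ in range(hyper.negatives_per_pair):
                j = cands[rng.integers(len(cands))]
                gamma_j = pool.gammas[pool.index[j]]
                d_j = d_lookup(idx, j)
                total += pair_log_likelihood(pair, gamma_j, d_j, params)
                count += 1
                params = sgd_step(pair, gamma_j, d_j, params, in_place=True)
                if freeze_su:
                    params.S[:] = 0.0
                    params.U[:] = 0.0
        reg = 0.5 * hyper.lambda_reg * params.sq_norm()
        trace.append((total / max(count, 1)) - reg)
    return params, trace


def rank_candidates(scores: dict[str, float], k: int, exclude: set[str] | frozenset[str] = frozenset()) -> list[str]:
    """Top-k candidates by descending score, ties broken by ascending actor id.

    ``exclude`` removes actors (typically the last observed node c) before
    ranking. Raises on an empty candidate set or k < 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items = [(a, s) for a, s in scores.items() if a not in exclude]
    if not items:
        raise ValueError("empty candidate set")
    items.sort(key=lambda t: (-t[1], t[0]))
    return [a for a, _ in items[:k]]
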