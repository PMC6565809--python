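"""Preference score, pairwise objective, SGD gradients, and ranking."""

import numpy as np
import pytest

from infowalk.bpr import (
    BPRHyper,
    BPRParams,
    CandidatePool,
    TrainPair,
    bpr_objective,
    log_sigmoid,
    pair_log_likelihood,
    preference_score,
    rank_candidates,
    sgd_step,
    sigmoid,
    train,
)


def scalar_params(s=1.0, u=1.0, w=1.0, **hyper) -> BPRParams:
    return BPRParams(S=[[s]], U=[[u]], w=[w], hyper=BPRHyper(**hyper))


class TestSigmoid:
    def test_zero(self):
        assert sigmoid(0.0) == 0.5

    def test_symmetry_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 50, 100)
        np.testing.assert_allclose(sigmoid(x) + sigmoid(-x), 1.0, atol=1e-12)

    def test_extreme_negative_no_underflow_exception(self):
        v = sigmoid(-745.0)
        assert 0 < v <= 1e-300

    def test_log_sigmoid_matches_naive_in_safe_range(self):
        x = np.linspace(-30, 30, 13)
        np.testing.assert_allclose(log_sigmoid(x), np.log(sigmoid(x)), atol=1e-12)


class TestPreferenceScore:
    def test_zero_parameters_give_zero(self):
        params = scalar_params(0, 0, 0)
        assert preference_score([1.0], [2.0], [3.0], [4.0], params) == 0.0

    def test_scalar_example(self):
        # p=1, beta=2, gamma=3, d=4 with unit parameters: 1*3 + 2*3 + 4 = 13
        params = scalar_params()
        assert preference_score([1.0], [2.0], [3.0], [4.0], params) == 13.0

    def test_candidate_independent_shift_preserves_order(self):
        rng = np.random.default_rng(1)
        params = BPRParams(S=rng.normal(size=(2, 3)), U=rng.normal(size=(4, 3)),
                           w=rng.normal(size=2))
        p, beta = rng.normal(size=2), rng.normal(size=4)
        g1, g2 = rng.normal(size=3), rng.normal(size=3)
        d1, d2 = rng.normal(size=2), rng.normal(size=2)
        s1 = preference_score(p, beta, g1, d1, params)
        s2 = preference_score(p, beta, g2, d2, params)
        # the frozen V term is the same additive constant for both candidates
        params_v = BPRParams(S=params.S, U=params.U, w=params.w,
                             V=rng.normal(size=(2, 4)),
                             hyper=BPRHyper(include_v=True))
        t1 = preference_score(p, beta, g1, d1, params_v)
        t2 = preference_score(p, beta, g2, d2, params_v)
        assert (s1 > s2) == (t1 > t2)
        assert t1 - s1 == pytest.approx(t2 - s2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            preference_score([1.0, 2.0], [2.0], [3.0], [4.0], scalar_params())


class TestObjective:
    def test_equal_scores_give_log_half(self):
        pair = TrainPair(p=np.array([1.0]), beta=np.array([2.0]),
                         gamma_f=np.array([3.0]), d_f=np.array([4.0]))
        params = scalar_params(lambda_reg=0.0)
        # identical negative features: delta = 0 -> log sigmoid(0)
        val = bpr_objective([(pair, np.array([3.0]), np.array([4.0]))], params)
        assert val == pytest.approx(np.log(0.5), abs=1e-12)

    def test_zero_parameters_no_regularizer_contribution(self):
        pair = TrainPair(p=np.array([1.0]), beta=np.array([1.0]),
                         gamma_f=np.array([1.0]), d_f=np.array([1.0]))
        params = scalar_params(0, 0, 0, lambda_reg=5.0)
        val = bpr_objective([(pair, np.array([0.0]), np.array([0.0]))], params)
        assert val == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_composition_of_preference_scores(self):
        rng = np.random.default_rng(7)
        params = BPRParams(S=rng.normal(size=(2, 2)), U=rng.normal(size=(3, 2)),
                           w=rng.normal(size=2), hyper=BPRHyper(lambda_reg=0.1))
        triples = []
        expected = 0.0
        for _ in range(3):
            pair = TrainPair(p=rng.normal(size=2), beta=rng.normal(size=3),
                             gamma_f=rng.normal(size=2), d_f=rng.normal(size=2))
            gj, dj = rng.normal(size=2), rng.normal(size=2)
            triples.append((pair, gj, dj))
            xf = preference_score(pair.p, pair.beta, pair.gamma_f, pair.d_f, params)
            xj = preference_score(pair.p, pair.beta, gj, dj, params)
            expected += np.log(sigmoid(xf - xj))
        expected -= 0.5 * 0.1 * params.sq_norm()
        assert bpr_objective(triples, params) == pytest.approx(expected, abs=1e-10)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            bpr_objective([], scalar_params())


class TestSGDStep:
    def test_identical_features_no_update_without_reg(self):
        pair = TrainPair(p=np.array([1.0]), beta=np.array([2.0]),
                         gamma_f=np.array([3.0]), d_f=np.array([4.0]))
        params = scalar_params(lambda_reg=0.0)
        out = sgd_step(pair, np.array([3.0]), np.array([4.0]), params)
        assert out.S[0, 0] == 1.0 and out.U[0, 0] == 1.0 and out.w[0] == 1.0

    def test_pure_decay_with_regularization(self):
        pair = TrainPair(p=np.array([1.0]), beta=np.array([1.0]),
                         gamma_f=np.array([2.0]), d_f=np.array([2.0]))
        params = scalar_params(lambda_reg=0.5)
        out = sgd_step(pair, np.array([2.0]), np.array([2.0]), params)
        assert 0 < out.S[0, 0] < 1 and 0 < out.U[0, 0] < 1 and 0 < out.w[0] < 1

    @pytest.mark.parametrize("seed", range(10))
    def test_analytic_gradient_matches_finite_differences(self, seed):
        """Central finite differences of the per-pair summand agree with the
        closed-form gradient used by the SGD update (1e-5 relative)."""
        rng = np.random.default_rng(seed)
        m, n, h, l = rng.integers(1, 4, size=4)
        lam = float(rng.uniform(0, 0.2))
        hyper = BPRHyper(lambda_reg=lam)
        params = BPRParams(S=rng.normal(size=(m, h)), U=rng.normal(size=(n, h)),
                           w=rng.normal(size=l), hyper=hyper)
        pair = TrainPair(p=rng.normal(size=m), beta=rng.normal(size=n),
                         gamma_f=rng.normal(size=h), d_f=rng.normal(size=l))
        gj, dj = rng.normal(size=h), rng.normal(size=l)

        def summand(pp: BPRParams) -> float:
            return (pair_log_likelihood(pair, gj, dj, pp)
                    - 0.5 * lam * pp.sq_norm())

        delta = (pair.p @ params.S @ (pair.gamma_f - gj)
                 + pair.beta @ params.U @ (pair.gamma_f - gj)
                 + params.w @ (pair.d_f - dj))
        coef = 1.0 - sigmoid(delta)
        grads = {
            "S": coef * np.outer(pair.p, pair.gamma_f - gj) - lam * params.S,
            "U": coef * np.outer(pair.beta, pair.gamma_f - gj) - lam * params.U,
            "w": coef * (pair.d_f - dj) - lam * params.w,
        }
        eps = 1e-6
        for name, grad in grads.items():
            arr = getattr(params, name)
            num = np.zeros_like(arr)
            for idx in np.ndindex(arr.shape):
                pp, pm = params.copy(), params.copy()
                getattr(pp, name)[idx] += eps
                getattr(pm, name)[idx] -= eps
                num[idx] = (summand(pp) - summand(pm)) / (2 * eps)
            np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-7)


def make_training_setup(rng, n_pairs=6, n_cands=5):
    ids = [f"j{i}" for i in range(n_cands)]
    pool = CandidatePool(ids, rng.normal(size=(n_cands, 2)))
    pairs = [
        TrainPair(p=rng.normal(size=2), beta=rng.normal(size=3),
                  gamma_f=rng.normal(size=2), d_f=rng.normal(size=2))
        for _ in range(n_pairs)
    ]
    cands = [ids for _ in pairs]
    d_vecs = {j: rng.normal(size=2) for j in ids}
    return pairs, cands, pool, lambda i, j: d_vecs[j]


class TestTrain:
    def test_same_seed_same_trajectory(self):
        rng = np.random.default_rng(3)
        pairs, cands, pool, d_lookup = make_training_setup(rng)
        hyper = BPRHyper(epochs=3, seed=11)
        p1, t1 = train(pairs, cands, pool, d_lookup, hyper=hyper)
        p2, t2 = train(pairs, cands, pool, d_lookup, hyper=hyper)
        np.testing.assert_array_equal(p1.S, p2.S)
        np.testing.assert_array_equal(p1.U, p2.U)
        np.testing.assert_array_equal(p1.w, p2.w)
        assert t1 == t2

    def test_zero_epochs_forbidden(self):
        with pytest.raises(ValueError):
            BPRHyper(epochs=0)

    def test_empty_training_set_rejected(self):
        rng = np.random.default_rng(3)
        _, _, pool, d_lookup = make_training_setup(rng)
        with pytest.raises(ValueError):
            train([], [], pool, d_lookup)

    def test_empty_candidate_pool_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        pairs, cands, pool, d_lookup = make_training_setup(rng, n_pairs=2)
        cands = [cands[0], []]
        import logging
        with caplog.at_level(logging.WARNING, logger="infowalk.bpr"):
            train(pairs, cands, pool, d_lookup, hyper=BPRHyper(epochs=1))
        assert any("skipping" in r.message for r in caplog.records)

    def test_freeze_su_trains_only_w(self):
        rng = np.random.default_rng(3)
        pairs, cands, pool, d_lookup = make_training_setup(rng)
        params, _ = train(pairs, cands, pool, d_lookup,
                          hyper=BPRHyper(epochs=2, seed=4), freeze_su=True)
        assert np.all(params.S == 0) and np.all(params.U == 0)
        assert np.any(params.w != 0)


class TestRankCandidates:
    def test_top_score_first(self):
        assert rank_candidates({"a": 2.0, "b": 1.0}, 1) == ["a"]

    def test_tie_breaks_by_id(self):
        assert rank_candidates({"b": 1.0, "a": 1.0, "c": 0.5}, 2) == ["a", "b"]

    def test_k_larger_than_pool_returns_all_sorted(self):
        assert rank_candidates({"b": 1.0, "a": 3.0}, 10) == ["a", "b"]

    def test_exclusion_and_empty_pool(self):
        assert rank_candidates({"a": 1.0, "c": 2.0}, 5, exclude={"c"}) == ["a"]
        with pytest.raises(ValueError):
            rank_candidates({"c": 2.0}, 5, exclude={"c"})
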