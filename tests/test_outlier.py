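"""Step measures, the five distance metrics (with brute-force oracles),
M-th-NN scoring, and the outlier simulator."""

import itertools

import numpy as np
import pytest

from infowalk.netcore import ReferralNetwork
from infowalk.outlier import (
    StepSeries,
    compute_step_series,
    dist_dtw,
    dist_interp,
    dist_lcs,
    dist_ssa,
    dist_ssm,
    interp_time_grid,
    knn_outlier_scores,
    minmax_scale_series,
    precision_at_k,
    simulate_outliers,
    step_measures,
    tune_m_nn,
    walk_distance,
)
from conftest import make_profile, random_walks, walk


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_dtw(LA, SA, lam):
    """Minimum cost over all monotone lattice paths from (0,0) to (l,s):
    diagonal steps cost |LA[i]-SA[j]|, axis steps cost lambda."""
    l, s = len(LA), len(SA)
    best = [np.inf]

    def go(i, j, cost):
        if cost >= best[0]:
            return
        if i == l and j == s:
            best[0] = cost
            return
        if i < l and j < s:
            go(i + 1, j + 1, cost + abs(LA[i] - SA[j]))
        if i < l:
            go(i + 1, j, cost + lam)
        if j < s:
            go(i, j + 1, cost + lam)

    go(0, 0, 0.0)
    return best[0]


def brute_lcs_length(LA, SA, thr):
    """Longest subsequence of SA matching (within thr) some subsequence of
    LA, by exhaustive enumeration of SA's subsequences."""
    def is_sub(sub):
        i = 0
        for x in LA:
            if i < len(sub) and abs(x - sub[i]) < thr:
                i += 1
        return i == len(sub)

    best = 0
    for r in range(len(SA), 0, -1):
        for combo in itertools.combinations(SA, r):
            if is_sub(combo):
                return r
    return best


class TestSSM:
    def test_window_match(self):
        assert dist_ssm([1, 2, 3], [2, 3]) == 0.0

    def test_identical_zero(self):
        assert dist_ssm([4.0, 5.0], [4.0, 5.0]) == 0.0

    def test_all_windows_equal(self):
        assert dist_ssm([0, 0, 0], [1]) == 1.0

    def test_enumeration(self):
        LA, SA = [1.0, 5.0, 2.0], [3.0, 3.0]
        expected = min(abs(1 - 3) + abs(5 - 3), abs(5 - 3) + abs(2 - 3))
        assert dist_ssm(LA, SA) == expected


class TestDTW:
    def test_identical_zero(self):
        for lam in (0.0, 1.0, 3.5):
            assert dist_dtw([1, 2, 3], [1, 2, 3], lam) == 0.0

    def test_skip_example(self):
        assert dist_dtw([1, 2, 3], [1, 3], 1.0) == 1.0

    def test_empty_side_boundary(self):
        # d(l, 0) = l * lambda by the initialization: SA of one far element
        # forces (l-1) skips plus a match
        assert dist_dtw([0.0, 0.0], [0.0], 2.0) == 2.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            dist_dtw([1.0], [1.0], -0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_alignment_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(1, 7))
        s = int(rng.integers(1, l + 1))
        LA = rng.uniform(0, 2, size=l)
        SA = rng.uniform(0, 2, size=s)
        lam = float(rng.uniform(0, 1.5))
        assert dist_dtw(LA, SA, lam) == pytest.approx(brute_dtw(LA, SA, lam))


class TestInterp:
    def test_five_element_time_allocation(self):
        np.testing.assert_allclose(interp_time_grid(5), [0, 0.25, 0.5, 0.75, 1.0])

    def test_identical_zero(self):
        assert dist_interp([1, 2, 3], [1, 2, 3]) == 0.0

    def test_linear_midpoint(self):
        assert dist_interp([0.0, 1.0], [0.0, 0.5, 1.0]) == pytest.approx(0.0)

    def test_short_array_rejected(self):
        with pytest.raises(ValueError):
            dist_interp([1.0, 2.0], [1.0])


class TestLCS:
    def test_identical_zero(self):
        assert dist_lcs([1, 2, 3], [1, 2, 3], 0.1) == 0.0

    def test_nothing_matches_gives_one(self):
        assert dist_lcs([0.0, 0.0], [5.0, 9.0], 0.1) == 1.0

    def test_nonconsecutive_match(self):
        # LCS (1, 2) across gaps: (4 + 2 - 4) / 6
        assert dist_lcs([1, 5, 2, 6], [1, 2], 0.1) == pytest.approx(1 / 3)

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            dist_lcs([1.0], [1.0], 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_subsequence_search(self, seed):
        rng = np.random.default_rng(seed)
        l = int(rng.integers(1, 9))
        s = int(rng.integers(1, l + 1))
        LA = rng.integers(0, 4, size=l).astype(float)
        SA = rng.integers(0, 4, size=s).astype(float)
        thr = 0.5
        m = brute_lcs_length(LA, SA, thr)
        assert dist_lcs(LA, SA, thr) == pytest.approx((l + s - 2 * m) / (l + s))


class TestSSA:
    def test_equal_length_reduces_to_manhattan(self):
        assert dist_ssa([1.0, 4.0], [2.0, 2.0]) == pytest.approx(3.0)

    def test_window_means(self):
        # window length 2: means (1.5, 2.5) vs (2, 3) -> 1.0
        assert dist_ssa([1, 2, 3], [2, 3]) == pytest.approx(1.0)

    def test_identical_zero(self):
        assert dist_ssa([1, 2, 3], [1, 2, 3]) == 0.0


class TestWalkDistanceAxioms:
    @staticmethod
    def _random_series(rng, wid, t):
        return StepSeries(wid, rng.uniform(0, 1, size=(11, t)))

    @pytest.mark.parametrize("metric", ["ssm", "dtw", "interp", "lcs", "ssa"])
    def test_zero_self_distance_nonneg_symmetry(self, metric):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = self._random_series(rng, "a", int(rng.integers(2, 9)))
            b = self._random_series(rng, "b", int(rng.integers(2, 9)))
            assert walk_distance(a, a, metric) == pytest.approx(0.0, abs=1e-12)
            dab = walk_distance(a, b, metric)
            assert dab >= 0
            assert dab == pytest.approx(walk_distance(b, a, metric))

    def test_additivity_over_measures(self):
        base = np.zeros((11, 3))
        a = StepSeries("a", base.copy())
        vals = base.copy()
        vals[2] += 1.0   # per-measure Manhattan distance 3.0
        vals[7] += 0.5   # 1.5
        b = StepSeries("b", vals)
        assert walk_distance(a, b, "ssm") == pytest.approx(3.0 + 1.5)

    def test_unknown_metric_rejected(self):
        a = StepSeries("a", np.zeros((11, 2)))
        with pytest.raises(ValueError):
            walk_distance(a, a, "nope")


@pytest.fixture
def fig9_setup():
    """A focal walk overlapping four reference walks; two of those share one
    extra actor, giving the 5-node, 5-edge subnetwork used as a worked
    example (one mutual edge survives removing the focal node)."""
    ids = [f"c{i}" for i in range(1, 5)] + [f"x{i}" for i in range(1, 5)] + ["z"]
    net = ReferralNetwork([make_profile(a) for a in ids],
                          {("c1", "c2"): 1, ("c2", "c3"): 1, ("c3", "c4"): 1})
    focal = walk("focal", ["c1", "c2", "c3", "c4"])
    reference = [
        walk("iw1", ["c1", "x1", "z"]),
        walk("iw2", ["c2", "x2"]),
        walk("iw3", ["c3", "x3", "z"]),
        walk("iw4", ["c4", "x4"]),
    ]
    return net, focal, reference


class TestStepMeasures:
    def test_four_connected_walks(self, fig9_setup):
        net, focal, reference = fig9_setup
        m = step_measures(focal, reference, net)
        assert m[0] == 4

    def test_survival_density_component(self, fig9_setup):
        net, focal, reference = fig9_setup
        m = step_measures(focal, reference, net)
        assert m[8] == pytest.approx(1 / 5)   # 1 of 5 edges survives
        assert m[9] == pytest.approx(1 / 6)   # 1 edge among 4 remaining nodes
        assert m[10] == 2                     # iw1 - iw3 component

    def test_no_overlap_degenerate_vector(self, fig9_setup):
        net, _, reference = fig9_setup
        lone = walk("lone", ["x1"])  # x1 is on iw1 -> overlaps; use z-free actor
        lone = walk("lone", ["c1"])
        # build a reference that shares nothing with the prefix
        far = [walk("far", ["x2", "x3"])]
        m = step_measures(lone, far, net)
        assert m[0] == 0
        assert m[1] == 1.0  # c1 neighbors only c2
        assert np.all(m[2:] == 0)

    def test_empty_reference_warns(self, fig9_setup):
        net, focal, _ = fig9_setup
        with pytest.warns(UserWarning):
            m = step_measures(focal, [], net)
        assert m[0] == 0

    def test_series_causality_and_shape(self, fig9_setup):
        net, focal, reference = fig9_setup
        series = compute_step_series([focal], reference, net)[0]
        assert series.values.shape == (11, 4)
        # column t depends only on the length-(t+1) prefix
        for t in range(1, 5):
            col = step_measures(focal.prefix(t), reference, net)
            np.testing.assert_allclose(series.values[:, t - 1], col)

    def test_focal_excluded_from_reference(self, fig9_setup):
        net, focal, reference = fig9_setup
        series = compute_step_series([focal], reference + [focal], net)[0]
        direct = compute_step_series([focal], reference, net)[0]
        np.testing.assert_allclose(series.values, direct.values)


class TestScaling:
    def test_minmax_to_unit_interval_constant_to_zero(self):
        rng = np.random.default_rng(0)
        raw = [StepSeries(f"w{i}", np.vstack([rng.uniform(5, 9, size=(10, 4)),
                                              np.full((1, 4), 7.0)]))
               for i in range(3)]
        scaled = minmax_scale_series(raw)
        allv = np.concatenate([s.values for s in scaled], axis=1)
        assert allv.min() >= 0 and allv.max() <= 1
        assert np.all(allv[10] == 0)  # constant measure maps to 0


class TestKnnScoring:
    def _series_with_distances(self):
        # 1-step series whose pairwise Manhattan distances are AB=1, AC=5, BC=4
        vals = {"a": 0.0, "b": 1.0, "c": 5.0}
        return [StepSeries(k, np.vstack([[v]] + [[0.0]] * 10))
                for k, v in vals.items()]

    def test_furthest_nearest_neighbor_wins(self):
        series = self._series_with_distances()
        sc = knn_outlier_scores(series, "ssm", m_nn=1, k=1)
        assert sc.ranked == ["c"]
        assert sc.scores["c"] == pytest.approx(4.0)

    def test_duplicates_score_zero(self):
        series = self._series_with_distances()
        series.append(StepSeries("c2", series[2].values.copy()))
        sc = knn_outlier_scores(series, "ssm", m_nn=1, k=4)
        assert sc.scores["c"] == 0.0 and sc.scores["c2"] == 0.0

    def test_k_at_least_n_returns_full_ranking(self):
        series = self._series_with_distances()
        sc = knn_outlier_scores(series, "ssm", m_nn=1, k=10)
        assert len(sc.ranked) == 3

    def test_m_nn_must_be_below_n(self):
        series = self._series_with_distances()
        with pytest.raises(ValueError):
            knn_outlier_scores(series, "ssm", m_nn=3, k=1)

    def test_precision_fraction(self):
        series = self._series_with_distances()
        sc = knn_outlier_scores(series, "ssm", m_nn=1, k=2)
        labels = {"a": 0, "b": 0, "c": 1}
        assert precision_at_k(sc, labels) == pytest.approx(0.5)

    def test_precision_at_n_equals_base_rate(self):
        series = self._series_with_distances()
        sc = knn_outlier_scores(series, "ssm", m_nn=1, k=3)
        labels = {"a": 1, "b": 0, "c": 1}
        assert precision_at_k(sc, labels) == pytest.approx(2 / 3)

    def test_tune_prefers_smaller_m_on_ties(self):
        series = self._series_with_distances()
        m, _ = tune_m_nn(series, "ssm", {"a": 0, "b": 0, "c": 1}, k=1,
                         grid=(1, 2))
        assert m == 1


class TestSimulator:
    def test_endpoints_length_timestamps_preserved(self, small_network):
        rng = np.random.default_rng(0)
        pool = random_walks(rng, small_network, n=20, min_len=5, max_len=7)
        bench, labels = simulate_outliers(pool, n_normal=5, n_outlier=5, seed=3)
        by_id = {w.walk_id: w for w in pool}
        for w in bench:
            orig = by_id[w.walk_id]
            assert len(w) == len(orig)
            if labels[w.walk_id] == 1:
                assert w.visits[0] == orig.visits[0]
                assert w.visits[-1] == orig.visits[-1]
                assert [v.day for v in w.visits] == [v.day for v in orig.visits]

    def test_same_seed_identical_benchmark(self, small_network):
        rng = np.random.default_rng(1)
        pool = random_walks(rng, small_network, n=20, min_len=4)
        b1, l1 = simulate_outliers(pool, 5, 5, seed=7)
        b2, l2 = simulate_outliers(pool, 5, 5, seed=7)
        assert l1 == l2 and b1 == b2

    def test_middles_drawn_from_pool_actor_set(self, small_network):
        # pool walks never visit G, so no corrupted middle may introduce it
        rng = np.random.default_rng(2)
        pool = []
        while len(pool) < 30:
            for w in random_walks(rng, small_network, n=10, min_len=5):
                if "G" not in w.actor_set:
                    pool.append(walk(f"p{len(pool):03d}", w.actor_sequence,
                                     start=w.start_day))
        pool_actors = {a for w in pool for a in w.actor_set}
        assert "G" not in pool_actors
        for seed in range(5):
            bench, labels = simulate_outliers(pool, 10, 10, seed=seed)
            for w in bench:
                if labels[w.walk_id] == 1:
                    assert set(w.actor_sequence[1:-1]) <= pool_actors

    def test_insufficient_pool_rejected(self, small_network):
        rng = np.random.default_rng(3)
        pool = random_walks(rng, small_network, n=4)
        with pytest.raises(ValueError):
            simulate_outliers(pool, 10, 10, seed=0)
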