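"""Tests for the competing-risks random survival forest.

The split statistic is checked against a literal term-by-term transcription
of its definition (an independent loop over event times), against a hand
calculation, and — in the single-cause uncensored case — against the
classical two-sample log-rank statistic from lifelines.  Terminal curves are
checked against lifelines' Aalen-Johansen estimator.
"""

import json

import numpy as np
import pytest
from lifelines import AalenJohansenFitter
from lifelines.statistics import logrank_test

from crbench.forest import (
    CRTree,
    ForestConfig,
    _aalen_johansen,
    crlogrank_split_stat,
    grow_forest,
    grow_tree,
    predict_cif_forest,
)
from crbench.simulate import CompetingRisksSample, ScenarioSpec, simulate_dataset
from conftest import random_competing_sample


def brute_force_split_stat(time, event, x, s, cause, tau):
    """Independent literal transcription: loop over distinct cause-k event
    times accumulating the numerator and variance term by term."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    left = np.asarray(x) <= s
    num = 0.0
    var = 0.0
    for tj in np.unique(time[(event == cause) & (time <= tau)]):
        R = np.sum(time >= tj)
        R_a = np.sum((time >= tj) & left)
        d_a = np.sum((time == tj) & (event == cause) & left)
        d_g = np.sum((time == tj) & (event == cause) & ~left)
        d = d_a + d_g
        num += d_a - d * R_a / R
        if R > 1:
            var += d * (R_a / R) * (1 - R_a / R) * ((R - d) / (R - 1))
    return num / np.sqrt(var) if var > 0 else 0.0


class TestSplitStatistic:
    def test_matches_brute_force_on_random_nodes(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 31))
            node = random_competing_sample(rng, n)
            x = node.X[:, int(rng.integers(12))]
            uv = np.unique(x)
            if len(uv) < 2:
                continue
            s = float(rng.choice(uv[:-1]))
            tau = float(np.quantile(node.time, rng.uniform(0.5, 1.0)))
            if not np.any((node.event == 1) & (node.time <= tau)):
                continue
            ours = crlogrank_split_stat(node.time, node.event, x, s,
                                        cause=1, tau=tau)
            ref = brute_force_split_stat(node.time, node.event, x, s, 1, tau)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_hand_calculation_single_event(self):
        # one cause-1 event at the earliest time, falling left;
        # R(t1) = 10, R_left(t1) = 4:
        #   numerator = 1 - 4/10 = 0.6
        #   variance  = 1 * 0.4 * 0.6 * (10-1)/(10-1) = 0.24
        time = np.arange(1.0, 11.0)
        event = np.array([1] + [2] * 9)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1], float)  # 4 subjects <= 0
        stat = crlogrank_split_stat(time, event, x, split_point=0.0)
        assert stat == pytest.approx(0.6 / np.sqrt(0.24))

    def test_sign_flips_when_daughters_swap(self, rng):
        node = random_competing_sample(rng, 25)
        x = node.X[:, 0]
        s = float(np.median(x))
        a = crlogrank_split_stat(node.time, node.event, x, s)
        b = crlogrank_split_stat(node.time, node.event, -x, -s - 1e-12)
        assert a == pytest.approx(-b, abs=1e-10)

    def test_proportional_daughters_give_zero(self):
        # right daughter is an exact copy of the left: d_a = d/2, R_a = R/2
        # at every event time, so every numerator term vanishes
        t = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        e = np.array([1, 2, 1, 0] * 2)
        x = np.repeat([0.0, 1.0], 4)
        assert crlogrank_split_stat(t, e, x, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_classical_logrank(self, rng):
        # one cause, no censoring: i_k^2 equals the log-rank chi-square
        for _ in range(5):
            n = int(rng.integers(20, 40))
            t = rng.exponential(10, n)
            x = (rng.random(n) > 0.5).astype(float)
            if len(np.unique(x)) < 2:
                continue
            stat = crlogrank_split_stat(t, np.ones(n, dtype=int), x, 0.5)
            ref = logrank_test(t[x <= 0.5], t[x > 0.5])
            assert stat ** 2 == pytest.approx(ref.test_statistic, rel=1e-10)

    def test_empty_daughter_rejected(self):
        with pytest.raises(ValueError):
            crlogrank_split_stat([1, 2], [1, 1], [1.0, 1.0], 2.0)

    def test_compiled_and_numpy_paths_agree(self, rng):
        from crbench.forest import _split_stats_numpy, _split_stats_sorted

        for _ in range(30):
            n = int(rng.integers(8, 60))
            ts = np.sort(rng.exponential(10, n).round(1))  # with ties
            es = rng.integers(0, 3, n)
            Ls = (rng.random((n, 6)) < 0.5).astype(float)
            tau = float(np.quantile(ts, 0.8))
            a_stat, a_var = _split_stats_sorted(ts, es, Ls, 1, tau)
            b_stat, b_var = _split_stats_numpy(ts, es, Ls, 1, tau)
            assert np.allclose(a_stat, b_stat, atol=1e-10)
            assert np.allclose(a_var, b_var, atol=1e-10)


class TestAalenJohansen:
    def test_matches_lifelines(self, rng):
        for _ in range(5):
            s = random_competing_sample(rng, int(rng.integers(15, 50)))
            times, cif = _aalen_johansen(s.time, s.event)
            for cause in (1, 2):
                aj = AalenJohansenFitter(calculate_variance=False).fit(
                    s.time, s.event, event_of_interest=cause)
                theirs = aj.cumulative_density_.iloc[:, 0]
                idx = np.searchsorted(theirs.index.to_numpy(), times, "right") - 1
                assert np.allclose(cif[cause - 1], theirs.to_numpy()[idx],
                                   atol=1e-12)

    def test_cause_cifs_sum_below_one(self, rng):
        s = random_competing_sample(rng, 60, censor_frac=0.1)
        _, cif = _aalen_johansen(s.time, s.event)
        assert np.all(cif.sum(axis=0) <= 1 + 1e-12)


class TestGrowTree:
    def test_small_node_is_root_only(self, linear_sample):
        cfg = ForestConfig(ntree=1, nodesize=15)
        rows = np.arange(20)  # < 2 * nodesize
        tree = grow_tree(linear_sample, rows, cfg, np.random.default_rng(0))
        assert len(tree.feature) == 1 and tree.feature[0] == -1

    def test_constant_covariates_give_root_only(self):
        n = 80
        rng = np.random.default_rng(1)
        s = CompetingRisksSample(np.ones((n, 12)), rng.exponential(10, n),
                                 rng.integers(1, 3, n))
        tree = grow_tree(s, np.arange(n), ForestConfig(ntree=1), rng)
        assert len(tree.feature) == 1

    def test_exhaustive_split_matches_brute_force(self, rng):
        # 12 subjects, one informative binary covariate, exhaustive nsplit
        n = 12
        x_inf = np.repeat([0.0, 1.0], n // 2)
        X = np.column_stack([rng.standard_normal(n), x_inf,
                             rng.standard_normal(n)])
        time = np.where(x_inf > 0, rng.exponential(2, n), rng.exponential(40, n))
        event = np.ones(n, dtype=int)
        s = CompetingRisksSample(X, time, event)
        cfg = ForestConfig(ntree=1, nodesize=2, nsplit=None, mtry=None)
        tree = grow_tree(s, np.arange(n), cfg, np.random.default_rng(3))

        best = (None, None, -1.0)
        tau = time.max()
        for f in range(3):
            for cut in np.unique(X[:, f])[:-1]:
                nl = np.sum(X[:, f] <= cut)
                if nl < 2 or n - nl < 2:
                    continue
                stat = abs(brute_force_split_stat(time, event, X[:, f], cut,
                                                  1, tau))
                if stat > best[2] + 1e-12:
                    best = (f, cut, stat)
        assert tree.feature[0] == best[0]
        assert tree.threshold[0] == pytest.approx(best[1])

    def test_daughters_respect_nodesize(self, linear_sample):
        cfg = ForestConfig(ntree=1, nodesize=15)
        rng = np.random.default_rng(5)
        tree = grow_tree(linear_sample, np.arange(len(linear_sample)), cfg, rng)
        sizes = _leaf_sizes(tree, linear_sample.X[np.arange(len(linear_sample))])
        assert all(sz >= cfg.nodesize for sz in sizes)

    def test_json_dump_well_formed(self, linear_sample):
        cfg = ForestConfig(ntree=1, nodesize=30)
        tree = grow_tree(linear_sample, np.arange(100), cfg,
                         np.random.default_rng(2))
        payload = json.loads(tree.to_json())
        assert len(payload["nodes"]) == len(tree.feature)


def _leaf_sizes(tree: CRTree, X: np.ndarray):
    leaves = tree.apply(X)
    return np.bincount(leaves, minlength=tree.n_leaves)


@pytest.fixture(scope="module")
def grid(linear_sample):
    return np.linspace(1.0, float(linear_sample.time.max()), 30)


class TestForestPrediction:
    def test_single_tree_forest_equals_tree(self, linear_sample, grid):
        forest = grow_forest(linear_sample, ForestConfig(ntree=1, seed=9))
        pred = predict_cif_forest(forest, linear_sample.X[:7], grid)
        tree = forest[0]
        direct = tree.leaf_cif_on_grid(grid, 1)[tree.apply(linear_sample.X[:7])]
        assert np.allclose(pred.values, direct)

    def test_root_only_forest_is_covariate_free(self, linear_sample, grid):
        cfg = ForestConfig(ntree=10, nodesize=1000, seed=4)
        forest = grow_forest(linear_sample, cfg)
        assert all(len(t.feature) == 1 for t in forest)
        pred = predict_cif_forest(forest, linear_sample.X[:9], grid)
        assert np.allclose(pred.values, pred.values[0])
        # equals the average of the whole-bootstrap Aalen-Johansen curves
        avg = np.mean([t.leaf_cif_on_grid(grid, 1)[0] for t in forest], axis=0)
        assert np.allclose(pred.values[0], avg)

    def test_deterministic_given_seed(self, linear_sample, grid):
        cfg = ForestConfig(ntree=5, seed=123)
        a = predict_cif_forest(grow_forest(linear_sample, cfg),
                               linear_sample.X[:5], grid)
        b = predict_cif_forest(grow_forest(linear_sample, cfg),
                               linear_sample.X[:5], grid)
        assert np.array_equal(a.values, b.values)

    def test_cause_cifs_conserve_probability(self, linear_sample, grid):
        forest = grow_forest(linear_sample, ForestConfig(ntree=20, seed=6))
        c1 = predict_cif_forest(forest, linear_sample.X[:25], grid, cause=1)
        c2 = predict_cif_forest(forest, linear_sample.X[:25], grid, cause=2)
        total = c1.values + c2.values
        assert np.all(total <= 1 + 1e-10)
        assert np.all(np.diff(c1.values, axis=1) >= -1e-12)

    def test_dimension_mismatch_rejected(self, linear_sample, grid):
        forest = grow_forest(linear_sample, ForestConfig(ntree=2, seed=1))
        with pytest.raises(IndexError):
            predict_cif_forest(forest, np.zeros((2, 3)), grid)

    def test_empty_forest_rejected(self, grid):
        with pytest.raises(ValueError):
            predict_cif_forest([], np.zeros((1, 12)), grid)

    def test_informative_covariate_separates_predictions(self):
        # strong single-covariate signal: subjects with opposite x1 sign
        # should receive clearly different cause-1 CIFs
        spec = ScenarioSpec(kind="linear", n=400)
        s = simulate_dataset(spec, seed=44)
        forest = grow_forest(s, ForestConfig(ntree=50, seed=3))
        x_hi = np.zeros((1, 12))
        x_hi[0, 0] = 2.0
        x_lo = np.zeros((1, 12))
        x_lo[0, 0] = -2.0
        grid = np.linspace(1, 80, 20)
        hi = predict_cif_forest(forest, x_hi, grid).values[0, -1]
        lo = predict_cif_forest(forest, x_lo, grid).values[0, -1]
        assert hi > lo
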