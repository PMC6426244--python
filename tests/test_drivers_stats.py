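"""Group comparisons, forward selection and the regression tree."""

import itertools

import numpy as np
import pandas as pd
import pytest

from underice.drivers_stats import (
    _grow,
    _leaves,
    _prune_path,
    compare_groups,
    correlate,
    fit_urt,
    forward_mlr,
    paired_test,
    transform_covariates,
)


class TestCompareGroups:
    def test_rank_oracle_two_groups(self):
        # {1,2,3} vs {10,11,12}: ranks 1–3 vs 4–6,
        # H = 12/(6·7)·(6²/3 + 15²/3) − 3·7 = 27/7
        res = compare_groups([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        assert res.h_statistic == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, rel=1e-12)

    def test_identical_groups_share_a_letter(self):
        values = [1, 2, 3, 1, 2, 3, 1, 2, 3]
        res = compare_groups(values, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-9)
        letters = set(res.letters.values())
        assert letters == {"a"}

    def test_holm_smallest_p_scaled_by_m_first(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(5, 1, 8), rng.normal(0.3, 1, 8)])
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = compare_groups(values, groups)
        pw = res.pairwise
        m = len(pw)
        i = pw["p_raw"].idxmin()
        assert pw.loc[i, "p_adj"] == pytest.approx(min(1.0, pw.loc[i, "p_raw"] * m))
        assert np.all(pw["p_adj"].to_numpy() >= pw["p_raw"].to_numpy())

    def test_all_tied_is_degenerate(self):
        with pytest.raises(ValueError, match="tied"):
            compare_groups([1, 1, 1, 1], ["a", "a", "b", "b"])


class TestPairedAndPearson:
    def test_equal_pairs(self):
        t, p = paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_hand_worked_t(self):
        # pairs (1,2),(2,4),(3,5): differences {1,2,2}, t = (5/3)/(sd/√3) = 5
        t, _ = paired_test([2.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(5.0, rel=1e-12)

    def test_pearson_extremes_and_worked_set(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert correlate(a, a)[0] == pytest.approx(1.0)
        assert correlate(a, [-x for x in a])[0] == pytest.approx(-1.0)
        # hand covariance arithmetic for b = {1,3,2,5}
        r, _ = correlate(a, [1.0, 3.0, 2.0, 5.0])
        assert r == pytest.approx(5.5 / np.sqrt(5.0 * 8.75), rel=1e-12)
        with pytest.raises(ValueError, match="zero variance"):
            correlate(a, [2.0, 2.0, 2.0, 2.0])


class TestForwardMLR:
    def test_planted_signal_recovered_exactly_once(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 1, 40)
        x2 = rng.normal(0, 1, 40)
        y = 5 * x1 + rng.normal(0, 0.01, 40)
        model = forward_mlr(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert model.selected == ["x1"]
        assert model.r2 > 0.999

    def test_pure_noise_selects_nothing(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=["a", "b", "c"])
        y = rng.normal(0, 1, 40)
        model = forward_mlr(y, X)
        assert model.selected == []
        assert model.r2 == 0.0

    def test_single_covariate_equals_simple_regression(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 30)
        y = 2 * x + rng.normal(0, 0.5, 30)
        model = forward_mlr(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert model.r2 == pytest.approx(r**2, rel=1e-9)

    def test_collinear_duplicate_skipped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 30)
        y = 3 * x + rng.normal(0, 0.1, 30)
        model = forward_mlr(y, pd.DataFrame({"x": x, "x_copy": x}))
        assert len(model.selected) == 1

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            forward_mlr([1.0] * 5, pd.DataFrame({"x": [1.0] * 5}))


class TestRegressionTree:
    def test_noiseless_step_split_at_midpoint(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0])
        y = np.where(x < 2, 0.0, 100.0)
        tree = fit_urt(y, pd.DataFrame({"x": x}), cv_folds=5, seed=0)
        assert tree.chosen_size == 2
        var, thr = tree.splits[0]
        assert var == "x"
        assert thr == pytest.approx(2.0)  # midpoint of 1.5 and 2.5
        assert tree.r2 == pytest.approx(1.0)
        assert sorted(tree.leaf_means) == [0.0, 100.0]

    def test_constant_response_single_leaf(self):
        y = np.full(12, 7.0)
        tree = fit_urt(y, pd.DataFrame({"x": np.arange(12.0)}), cv_folds=4, seed=0)
        assert tree.chosen_size == 1
        assert tree.splits == []

    def test_root_split_matches_brute_force(self):
        """The greedy root split equals exhaustive enumeration of every
        (variable, threshold) candidate by SSE."""
        rng = np.random.default_rng(4)
        table = pd.DataFrame({"u": rng.normal(0, 1, 12), "v": rng.normal(0, 1, 12)})
        y = rng.normal(0, 1, 12)

        def sse(vals):
            return np.sum((vals - vals.mean()) ** 2) if len(vals) else 0.0

        best = None
        for col in table.columns:
            xs = np.sort(table[col].unique())
            for lo, hi in zip(xs[:-1], xs[1:]):
                thr = (lo + hi) / 2
                mask = table[col].to_numpy() <= thr
                if mask.sum() < 3 or (~mask).sum() < 3:
                    continue
                score = sse(y[mask]) + sse(y[~mask])
                if best is None or score < best[0]:
                    best = (score, col, thr)
        root = _grow(table, y, 3, 6)
        assert root.var == best[1]
        assert root.threshold == pytest.approx(best[2])

    def test_factor_split_by_subset_search(self):
        seasons = np.array(["winter", "spring", "summer", "autumn"] * 5)
        y = np.where(np.isin(seasons, ["winter", "spring"]), 100.0, 0.0)
        tree = fit_urt(y, pd.DataFrame({"season": seasons}), cv_folds=5, seed=1)
        var, subset = tree.splits[0]
        assert var == "season"
        assert subset in ({"winter", "spring"}, {"summer", "autumn"})
        assert tree.r2 == pytest.approx(1.0)

    def test_training_sse_decreases_with_size(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"x": rng.uniform(0, 10, 40)})
        y = table["x"].to_numpy() ** 2 + rng.normal(0, 5, 40)
        full = _grow(table, y, 3, 6)
        path = _prune_path(full)
        sizes = [len(_leaves(t)) for _, t in path]
        sses = [sum(l.sse for l in _leaves(t)) for _, t in path]
        order = np.argsort(sizes)
        assert np.all(np.diff(np.array(sses)[order]) <= 1e-9)

    def test_leaf_means_equal_member_means(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({"x": rng.uniform(0, 1, 30)})
        y = (table["x"] > 0.5).to_numpy() * 10.0 + rng.normal(0, 1, 30)
        tree = fit_urt(y, table, cv_folds=5, seed=0)
        preds = tree.predict(table)
        for leaf_mean in tree.leaf_means:
            members = y[np.isclose(preds, leaf_mean)]
            assert np.mean(members) == pytest.approx(leaf_mean, rel=1e-9)


def test_transform_covariates_logs_skewed_columns():
    rng = np.random.default_rng(8)
    skewed = np.exp(rng.normal(0, 1.5, 200))
    symmetric = rng.normal(10, 1, 200)
    out, meta = transform_covariates(pd.DataFrame({"s": skewed, "n": symmetric}))
    assert "s" in meta and "n" not in meta
    assert np.allclose(out["s"], np.log10(skewed + meta["s"]))
    assert np.allclose(out["n"], symmetric)
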