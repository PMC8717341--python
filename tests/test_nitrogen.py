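"""Correlation pruning, stratified splits, RF protocol, repeated evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from canopyn.nitrogen import (NitrogenForestRegressor, _aggregate,
                              evaluate_repeated, plot_level_regression,
                              prune_correlated, stratified_partition)


class TestPruneCorrelated:
    def test_perfectly_correlated_pair_keeps_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "b": 2 * a + 1, "c": rng.normal(size=50)})
        kept = prune_correlated(df, 0.8)
        assert "c" in kept and len(kept) == 2

    def test_uncorrelated_features_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(200, 4)),
                          columns=list("abcd"))
        assert prune_correlated(df, 0.8) == list("abcd")

    def test_matches_exhaustive_maximal_subset_oracle(self):
        # construct six features with a controlled correlation pattern
        rng = np.random.default_rng(2)
        z1, z2, z3 = rng.normal(size=(3, 400))
        eps = lambda: rng.normal(scale=0.1, size=400)
        df = pd.DataFrame({
            "f1": z1, "f2": z1 + eps(),              # f1 ~ f2
            "f3": z2, "f4": z2 + eps(),              # f3 ~ f4
            "f5": z3, "f6": rng.normal(size=400)})   # independent
        kept = prune_correlated(df, 0.8)
        # oracle: maximal subsets with no pair above threshold
        corr = df.corr().abs()
        valid = []
        cols = list(df.columns)
        for r in range(len(cols), 0, -1):
            for sub in itertools.combinations(cols, r):
                if all(corr.loc[a, b] < 0.8
                       for a, b in itertools.combinations(sub, 2)):
                    valid.append(set(sub))
            if valid:
                break
        assert set(kept) in valid
        assert len(kept) == len(valid[0])

    def test_constant_feature_dropped_first_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"flat": np.ones(30),
                           "x": rng.normal(size=30),
                           "y": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            kept = prune_correlated(df, 0.8)
        assert "flat" not in kept

    def test_too_few_rows_or_features_rejected(self):
        with pytest.raises(ValueError):
            prune_correlated(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            prune_correlated(pd.DataFrame({"a": [1.0, 2.0],
                                           "b": [2.0, 1.0]}))


class TestStratifiedPartition:
    def test_150_rows_split_105_and_45(self):
        y = np.random.default_rng(4).normal(size=150)
        tr, te = stratified_partition(y, seed=0)
        assert len(tr) == 105 and len(te) == 45
        assert len(np.union1d(tr, te)) == 150

    def test_every_quantile_bin_contributes_its_share(self):
        y = np.arange(100.0)
        tr, _ = stratified_partition(y, n_bins=5, seed=1)
        for b in range(5):
            in_bin = np.arange(20 * b, 20 * (b + 1))
            assert len(np.intersect1d(tr, in_bin)) == 14   # 70% of 20

    def test_test_range_overlaps_train_range_in_most_partitions(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(size=80)
        hits = 0
        n_trials = 200
        for s in range(n_trials):
            tr, te = stratified_partition(y, seed=s)
            # substantial interval overlap: the test range is nearly covered
            # by the train range (within one bin width on each side)
            bin_w = np.ptp(y) / 5
            if (y[te].min() >= y[tr].min() - bin_w
                    and y[te].max() <= y[tr].max() + bin_w):
                hits += 1
        assert hits / n_trials >= 0.95

    def test_partition_is_disjoint_and_exhaustive(self):
        y = np.random.default_rng(6).normal(size=37)
        tr, te = stratified_partition(y, seed=2)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == 37


def linear_dataset(n=120, p=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.uniform(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    y = 2.0 * X["x0"].to_numpy() + noise * rng.normal(size=n)
    return X, y


class TestForestProtocol:
    def test_pure_noise_response_has_near_zero_oob_r2(self):
        from sklearn.metrics import r2_score

        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(150, 5)),
                         columns=list("abcde"))
        y = rng.normal(size=150)
        m = NitrogenForestRegressor(n_estimators=200, random_state=0,
                                    importance_threshold=None).fit(X, y)
        r2 = r2_score(y, m.oob_prediction_)
        assert abs(r2) <= 0.15 or r2 < 0

    def test_noise_free_linear_signal_recovered(self):
        from sklearn.metrics import r2_score

        X, y = linear_dataset(noise=0.0)
        m = NitrogenForestRegressor(n_estimators=200, random_state=0).fit(X, y)
        assert r2_score(y, m.oob_prediction_) >= 0.9
        assert "x0" in m.selected_features_

    def test_same_seed_gives_identical_predictions(self):
        X, y = linear_dataset(noise=0.2, seed=8)
        m1 = NitrogenForestRegressor(n_estimators=100, random_state=5).fit(X, y)
        m2 = NitrogenForestRegressor(n_estimators=100, random_state=5).fit(X, y)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_pure_noise_variable_dropped_by_importance_selection(self):
        dropped = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 150
            signals = rng.uniform(size=(n, 5))
            X = pd.DataFrame(signals, columns=[f"signal_{i}" for i in range(5)])
            X["noise"] = rng.normal(size=n)
            y = signals.sum(axis=1) + 0.3 * rng.normal(size=n)
            m = NitrogenForestRegressor(n_estimators=150,
                                        random_state=s).fit(X, y)
            if "noise" not in m.selected_features_:
                dropped += 1
        assert dropped >= 9

    def test_all_important_variables_survive_selection(self):
        rng = np.random.default_rng(9)
        n = 150
        X = pd.DataFrame({"a": rng.uniform(size=n), "b": rng.uniform(size=n)})
        y = X["a"].to_numpy() + X["b"].to_numpy()
        m = NitrogenForestRegressor(n_estimators=200, random_state=0).fit(X, y)
        assert m.selected_features_ == ["a", "b"]

    def test_single_row_training_rejected(self):
        X = pd.DataFrame({"a": [1.0], "b": [0.5]})
        with pytest.raises(ValueError):
            NitrogenForestRegressor().fit(X, [1.0])

    def test_missing_cells_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="missing"):
            NitrogenForestRegressor().fit(X, [1.0, 2.0, 3.0])

    def test_sklearn_param_interface_round_trips(self):
        m = NitrogenForestRegressor(n_estimators=123, corr_threshold=0.9)
        params = m.get_params()
        assert params["n_estimators"] == 123
        m2 = NitrogenForestRegressor().set_params(**params)
        assert m2.corr_threshold == 0.9


class TestEvaluateRepeated:
    def test_aggregates_match_direct_recomputation(self):
        X, y = linear_dataset(noise=0.3, seed=10)
        ev = evaluate_repeated(X, y, n_repeats=5, base_seed=0,
                               n_estimators=60)
        for metric in ev.metric_columns:
            v = ev.per_repeat[metric].to_numpy()
            agg = ev.aggregates.loc[metric]
            assert agg["mean"] == pytest.approx(v.mean())
            assert agg["median"] == pytest.approx(np.median(v))
            assert agg["sd"] == pytest.approx(v.std(ddof=1))
            assert agg["se"] == pytest.approx(v.std(ddof=1) / np.sqrt(len(v)))

    def test_se_is_sd_over_sqrt_of_repeats(self):
        per = pd.DataFrame({"m": [0.6, 0.7, 0.8]})
        agg = _aggregate(per, ["m"])
        assert agg.loc["m", "mean"] == pytest.approx(0.7)
        assert agg.loc["m", "median"] == pytest.approx(0.7)
        assert agg.loc["m", "se"] == pytest.approx(
            agg.loc["m", "sd"] / np.sqrt(3))

    def test_best_repeats_identified_from_stored_vectors(self):
        X, y = linear_dataset(noise=0.3, seed=11)
        ev = evaluate_repeated(X, y, n_repeats=4, base_seed=3,
                               n_estimators=60)
        assert ev.best_r2_repeat == int(ev.per_repeat["cv_r2"].idxmax())
        assert ev.best_rmse_repeat == int(ev.per_repeat["cv_rmse"].idxmin())
        assert (ev.per_repeat["seed"] == 3 + ev.per_repeat["repeat"]).all()


class TestPlotLevelRegression:
    def test_perfect_predictions_give_unit_r2(self):
        obs = [1.0, 1.2, 1.4, 1.6]
        plots = [0, 0, 1, 1]
        _, r2 = plot_level_regression(obs, obs, plots)
        assert r2 == pytest.approx(1.0)

    def test_single_plot_r2_is_missing(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            _, r2 = plot_level_regression([1.0, 1.1], [1.05, 1.2], [0, 0])
        assert np.isnan(r2)

    def test_per_plot_means_match_hand_computation(self):
        obs = [1.0, 1.2, 1.5, 1.7]
        pred = [1.1, 1.3, 1.4, 1.8]
        plots = ["a", "a", "b", "b"]
        table, _ = plot_level_regression(obs, pred, plots)
        table = table.set_index("plot_id")
        assert table.loc["a", "observed"] == pytest.approx(1.1)
        assert table.loc["a", "predicted"] == pytest.approx(1.2)
        assert table.loc["b", "observed"] == pytest.approx(1.6)
        assert table.loc["b", "predicted"] == pytest.approx(1.6)


class TestSyntheticRecovery:
    def test_mean_cv_r2_at_low_noise(self, model_scene):
        """Parameter recovery: the documented reflectance link at low noise
        supports cross-validation R2 well above chance."""
        df = model_scene.summaries
        X = df[model_scene.feature_columns]
        y = df["n_pct_dm"].to_numpy()
        ev = evaluate_repeated(X, y, n_repeats=20, base_seed=0,
                               n_estimators=100)
        assert ev.aggregates.loc["cv_r2", "mean"] >= 0.6

    def test_noise_never_helps_cross_validation(self):
        """Increasing reflectance noise cannot increase mean CV R2."""
        import canopyn as cn

        r2s = []
        for noise in (0.0, 0.05, 0.15):
            cfg = cn.SceneConfig(extent_m=200.0, n_plots=1, trees_per_plot=5,
                                 background_trees_per_plot=45,
                                 noise_sd=noise, seed=30)
            scene = cn.prepare_scene(cfg, sampling_seed=0)
            df = scene.summaries
            ev = evaluate_repeated(df[scene.feature_columns],
                                   df["n_pct_dm"].to_numpy(),
                                   n_repeats=5, base_seed=0, n_estimators=80)
            r2s.append(ev.aggregates.loc["cv_r2", "mean"])
        assert r2s[0] >= r2s[1] - 0.05 and r2s[1] >= r2s[2] - 0.05
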