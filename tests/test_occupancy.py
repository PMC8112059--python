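"""SES cutoff, sigmoid occupancy, ensemble classifier, binding energy."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from arena.config import SimulationConfig
from arena import simulate as sim
from arena.occupancy import (
    binding_energy,
    build_occupancy_table,
    evaluate,
    feature_downsample_eval,
    fit_bagged_multinomial_lasso,
    make_training_set,
    occupancy_transform,
    predict,
    region_feature,
    ses_cutoff,
    sigmoid_params,
)


class TestSesCutoff:
    def test_scan_example(self):
        # gaps: 0,0,.25,.5,.25,0 over pooled scores -> cutoff 4
        res = ses_cutoff([1, 2, 9, 10], [1, 2, 3, 4])
        assert res.cutoff == 4.0
        assert res.gap == pytest.approx(0.5)

    def test_identical_distributions_degenerate(self):
        with pytest.warns(UserWarning, match="no specific binding"):
            res = ses_cutoff([1, 2, 3], [1, 2, 3])
        assert res.cutoff == 1.0
        assert res.gap == 0.0

    def test_stochastically_larger_observed(self, rng):
        obs = rng.normal(3, 1, 500)
        ctl = rng.normal(0, 1, 500)
        res = ses_cutoff(obs, ctl)
        assert np.isfinite(res.cutoff)
        assert res.gap > 0.5

    def test_tie_takes_smallest_score(self):
        # gaps at x=1 and x=2 are both 0.5; smallest candidate wins
        res = ses_cutoff([2, 9], [1, 2])
        assert res.gap == pytest.approx(0.5)
        assert res.cutoff == 1.0

    def test_empty_input_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            ses_cutoff([], [1.0])


class TestOccupancyTransform:
    def test_midpoint_maps_to_half(self, rng):
        scores = rng.gamma(2, 1, 300)
        params = sigmoid_params(scores, 1.0)
        assert occupancy_transform(np.array([params.midpoint]), 1.0, params)[0] \
            == pytest.approx(0.5)

    def test_cutoff_maps_to_tenth(self, rng):
        scores = rng.gamma(2, 1, 300)
        cutoff = 1.5
        occ = occupancy_transform(np.array([cutoff]), cutoff,
                                  sigmoid_params(scores, cutoff))
        assert occ[0] == pytest.approx(0.1, abs=1e-9)

    def test_monotone(self, rng):
        scores = rng.gamma(2, 1, 300)
        params = sigmoid_params(scores, 1.0)
        x = np.sort(rng.uniform(0, 10, 100))
        occ = occupancy_transform(x, 1.0, params)
        assert (np.diff(occ) >= 0).all()

    def test_no_scores_above_cutoff_flags_uninformative(self):
        params = sigmoid_params([0.1, 0.2], 5.0)
        assert params.uninformative
        occ = occupancy_transform(np.array([0.1, 0.2]), 5.0, params)
        np.testing.assert_array_equal(occ, 0.0)

    def test_missing_scores_become_zero(self, rng):
        scores = rng.gamma(2, 1, 50)
        occ = occupancy_transform(np.array([np.nan, scores.max()]), 0.5,
                                  sigmoid_params(scores, 0.5))
        assert occ[0] == 0.0 and occ[1] > 0.5

    def test_table_bounds_and_mask(self, small_dataset):
        table = build_occupancy_table(small_dataset["occ_raw"],
                                      small_dataset["occ_ctrl"])
        occ = table.occupancy.to_numpy()
        assert ((occ >= 0) & (occ <= 1)).all()
        assert table.missing_mask.to_numpy().sum() > 0
        assert (table.occupancy.to_numpy()[table.missing_mask.to_numpy()] == 0).all()


class TestRegionFeature:
    def test_constant_profile(self):
        assert region_feature([0.3] * 15) == 0.3

    def test_single_spike(self):
        profile = [0.1] * 14 + [0.9]
        assert region_feature(profile) == 0.9

    def test_max_oracle(self, rng):
        profile = rng.uniform(0, 1, 15)
        assert region_feature(profile) == profile.max()

    def test_no_coverage_missing(self):
        assert np.isnan(region_feature([]))
        assert np.isnan(region_feature([np.nan, np.nan]))


@pytest.fixture(scope="module")
def planted_training():
    """Occupancy with one strongly informative factor of 20 + truth labels."""
    cfg = SimulationConfig(n_clinical=1000, n_are_only=0, n_positive_ctrl=0,
                           n_factors=20, informative_factors=1,
                           occupancy_effect_sd=3.0, missing_rate=0.0, seed=33)
    regions, truth = sim.simulate_regions(cfg)
    raw, ctrl = sim.simulate_occupancy(regions, truth, cfg)
    table = build_occupancy_table(raw, ctrl)
    calls = regions.set_index("region_id")["true_class"]
    return table.occupancy, calls, truth


class TestTrainingSet:
    def test_balanced_dataset_arithmetic(self, rng):
        # class sizes (286, 465, 2479): dataset = 286 + 465 + 500 = 1251,
        # per-class floor(0.8 n) -> 228 + 372 + 400 = 1000 training rows
        idx = [f"r{i}" for i in range(3230)]
        calls = pd.Series(["inducible"] * 286 + ["constitutive"] * 465
                          + ["inactive"] * 2479, index=idx)
        occ = pd.DataFrame(rng.random((3230, 4)), index=idx, columns=list("abcd"))
        split = make_training_set(occ, calls, seed=1)
        assert len(split.x_train) + len(split.x_test) == 1251
        assert len(split.x_train) == 1000

    def test_same_seed_identical(self, planted_training):
        occ, calls, _ = planted_training
        s1 = make_training_set(occ, calls, seed=4)
        s2 = make_training_set(occ, calls, seed=4)
        pd.testing.assert_frame_equal(s1.x_train, s2.x_train)
        pd.testing.assert_series_equal(s1.y_test, s2.y_test)

    def test_train_test_disjoint_exhaustive(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=200, seed=5)
        train, test = set(split.x_train.index), set(split.x_test.index)
        assert not train & test
        assert len(train | test) == len(split.x_train) + len(split.x_test)

    def test_too_few_inactive_warns_and_uses_all(self, planted_training):
        occ, calls, _ = planted_training
        n_inactive = (calls == "inactive").sum()
        with pytest.warns(UserWarning, match="using all"):
            split = make_training_set(occ, calls, n_noninducible=n_inactive + 100)
        got = (split.y_train == "inactive").sum() + (split.y_test == "inactive").sum()
        assert got == n_inactive


class TestEnsembleFit:
    def test_informative_factor_gets_top_positive_weight(self, planted_training):
        occ, calls, truth = planted_training
        split = make_training_set(occ, calls, n_noninducible=400, seed=6)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=500, seed=6,
                                             record_metadata=False)
        w = model.weights.loc["inducible"]
        assert w["F001"] > 0
        assert w.abs().rank(ascending=False)["F001"] <= 3

    def test_huge_penalty_zero_weights_prior_predictions(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=400, seed=7)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=50, l1_penalty=1e6,
                                             seed=7, record_metadata=False)
        assert np.allclose(model.weights.to_numpy(), 0.0)
        probs = predict(model, split.x_test)[list(model.classes)]
        # all rows identical: prior-only prediction
        assert np.allclose(probs.to_numpy() - probs.to_numpy()[0], 0.0, atol=1e-9)

    def test_permuted_labels_at_chance(self, planted_training):
        occ, calls, _ = planted_training
        rng = np.random.default_rng(8)
        shuffled = pd.Series(rng.permutation(calls.to_numpy()), index=calls.index)
        split = make_training_set(occ, shuffled, n_noninducible=400, seed=8)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=300, seed=8,
                                             record_metadata=False)
        metrics = evaluate(model, split.x_test, split.y_test)
        majority = split.y_test.value_counts(normalize=True).max()
        n = len(split.y_test)
        se = np.sqrt(majority * (1 - majority) / n)
        assert metrics["accuracy"] <= majority + 3 * se

    def test_metadata_records_subsamples(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=9)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=10, seed=9)
        assert len(model.estimator_factors) == 10
        assert all(len(c) == 5 for c in model.estimator_factors)
        assert all(len(r) <= 50 for r in model.estimator_rows)


class TestPredictEvaluate:
    def test_probabilities_sum_to_one(self, planted_training, rng):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=10)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=100, seed=10,
                                             record_metadata=False)
        probs = predict(model, split.x_test)[list(model.classes)].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_monotone_in_positive_weight_feature(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=11)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=200, seed=11,
                                             record_metadata=False)
        grid = pd.DataFrame(0.5, index=range(5), columns=occ.columns)
        grid["F001"] = np.linspace(0, 1, 5)
        p_ind = predict(model, grid)["inducible"].to_numpy()
        assert (np.diff(p_ind) > 0).all()

    def test_perfect_predictor_metrics(self):
        # model with one decisive feature and an exactly separable layout
        occ = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0]},
                           index=["a", "b", "c", "d"])
        y = pd.Series(["inactive", "inactive", "inducible", "inducible"],
                      index=occ.index)
        model = fit_bagged_multinomial_lasso(occ, y, n_estimators=20,
                                             max_samples=4, max_features=1,
                                             l1_penalty=0.01, seed=12,
                                             record_metadata=False)
        metrics = evaluate(model, occ, y)
        assert metrics["accuracy"] == 1.0
        for cls in model.classes:
            assert metrics["per_class"][cls]["precision"] == 1.0
            assert metrics["per_class"][cls]["auc"] == 1.0

    def test_auc_equals_rank_statistic(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=13)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=100, seed=13,
                                             record_metadata=False)
        metrics = evaluate(model, split.x_test, split.y_test)
        probs = predict(model, split.x_test)["inducible"]
        pos = probs[split.y_test == "inducible"]
        neg = probs[split.y_test != "inducible"]
        u, _ = mannwhitneyu(pos, neg)
        assert metrics["per_class"]["inducible"]["auc"] == pytest.approx(
            u / (len(pos) * len(neg)))

    def test_missing_feature_is_error(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=14)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=10, seed=14,
                                             record_metadata=False)
        with pytest.raises(ValueError, match="missing features"):
            predict(model, split.x_test.drop(columns=["F001"]))


class TestBindingEnergy:
    def test_zero_weight_zero_energy_and_antisymmetry(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=300, seed=15)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=300, seed=15,
                                             record_metadata=False)
        energy = binding_energy(model, occ, calls)
        zero_w = model.weights.loc["inducible"] == 0
        assert (energy.loc[zero_w.to_numpy(), "inducible"] == 0).all()
        np.testing.assert_allclose(
            energy["diff_inducible_vs_inactive"],
            -(energy["inactive"] - energy["inducible"]))

    def test_planted_factor_tops_differential(self, planted_training):
        occ, calls, _ = planted_training
        split = make_training_set(occ, calls, n_noninducible=400, seed=16)
        model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                             n_estimators=500, seed=16,
                                             record_metadata=False)
        energy = binding_energy(model, occ, calls)
        assert energy["diff_inducible_vs_inactive"].idxmax() == "F001"


class TestEnsembleStability:
    @staticmethod
    def _dataset(missing_rate, seed):
        cfg = SimulationConfig(n_clinical=1500, n_are_only=0, n_positive_ctrl=0,
                               n_factors=30, informative_factors=3,
                               missing_rate=missing_rate, seed=seed)
        regions, truth = sim.simulate_regions(cfg)
        raw, ctrl = sim.simulate_occupancy(regions, truth, cfg)
        occ = build_occupancy_table(raw, ctrl).occupancy
        calls = regions.set_index("region_id")["true_class"]
        return make_training_set(occ, calls, n_noninducible=400, seed=seed)

    def test_false_negatives_rise_with_missingness(self):
        # zero-imputed missing scores push inducible regions toward
        # under-calling, mirroring missing-data false negatives
        fn = []
        for rate in (0.0, 0.2, 0.4):
            split = self._dataset(rate, seed=77)
            model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                                 n_estimators=400, seed=77,
                                                 record_metadata=False)
            metrics = evaluate(model, split.x_test, split.y_test)
            fn.append(1 - metrics["per_class"]["inducible"]["recall"])
        assert fn[0] <= fn[1] <= fn[2]
        assert fn[2] > fn[0]

    def test_aggregated_weights_converge_with_ensemble_size(self):
        split = self._dataset(0.1, seed=78)
        weights = {}
        for n_est in (2000, 4000):
            model = fit_bagged_multinomial_lasso(split.x_train, split.y_train,
                                                 n_estimators=n_est, seed=78,
                                                 record_metadata=False)
            weights[n_est] = model.weights
        diff = (weights[2000] - weights[4000]).abs().to_numpy().max()
        scale = np.abs(weights[4000].to_numpy()).max()
        assert diff / scale < 0.05


class TestFeatureDownsample:
    def test_subset_aucs(self, planted_training):
        occ, calls, _ = planted_training
        res = feature_downsample_eval(
            occ, calls,
            {"all": list(occ.columns),
             "planted": ["F001"],
             "uninformative": ["F013"]},
            n_estimators=300, n_noninducible=400, seed=17)
        res = res.set_index("subset")
        assert res.loc["planted", "auc"] > 0.95
        assert res.loc["planted", "auc"] > res.loc["uninformative", "auc"]
        assert abs(res.loc["uninformative", "auc"] - 0.5) < 0.15
        assert res.loc["all", "auc"] > 0.9

    def test_unknown_factor_error(self, planted_training):
        occ, calls, _ = planted_training
        with pytest.raises(ValueError, match="unknown factors"):
            feature_downsample_eval(occ, calls, {"bad": ["nope"]})
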