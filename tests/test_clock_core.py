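"""Elastic-net clock training, imputation, prediction and acceleration."""

import numpy as np
import pandas as pd
import pytest

import methaging as ma
from methaging.clock_core import (
    ClockModel,
    ClockTrainingConfig,
    age_acceleration,
    evaluate_clock,
    impute_clock_sites,
    predict_ages,
    split_train_test,
    train_elastic_net_clock,
)


class TestSplit:
    def test_published_cohort_size_split(self):
        train, test = split_train_test([f"s{i}" for i in range(134)], 0.8, seed=1)
        assert len(train) == 107 and len(test) == 27

    def test_seed_deterministic_and_exhaustive(self):
        ids = [f"s{i}" for i in range(10)]
        a = split_train_test(ids, 0.8, seed=5)
        b = split_train_test(ids, 0.8, seed=5)
        assert a == b
        assert sorted(a[0] + a[1]) == sorted(ids)
        assert not set(a[0]) & set(a[1])

    def test_small_n_rounding(self):
        train, test = split_train_test(list("abcde"), 0.8, seed=0)
        assert len(train) == 4 and len(test) == 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            split_train_test(["only"], 0.8, seed=0)


@pytest.fixture(scope="module")
def trained():
    """A clock trained on a moderate synthetic cohort, shared by tests."""
    config = ma.SimulationConfig(
        n_samples=60, n_sites=300, frac_age_associated=0.15, low_coverage_rate=0.0, seed=21
    )
    cohort = ma.simulate_training_cohort(config)
    complete = ma.mean_impute(
        ma.filter_by_coverage(
            ma.mask_low_coverage(cohort.methylation, cohort.coverage), cohort.coverage
        )
    )
    model = train_elastic_net_clock(
        complete, cohort.truth.reference_ages, ClockTrainingConfig(seed=21, cv_folds=5, n_lambdas=30)
    )
    return cohort, complete, model


class TestTraining:
    def test_recovers_age_signal(self, trained):
        _, _, model = trained
        assert model.test_evaluation.pearson_r > 0.8
        assert len(model.site_keys) > 0

    def test_single_noiseless_site_near_zero_mae(self):
        rng = np.random.default_rng(0)
        ages = pd.Series(rng.uniform(1, 27, 60), index=[f"s{i}" for i in range(60)])
        matrix = pd.DataFrame({"chr1:10": ages / 30.0})
        model = train_elastic_net_clock(
            matrix, ages, ClockTrainingConfig(seed=0, cv_folds=5)
        )
        assert model.test_evaluation.mae <= 0.1

    def test_constant_ages_rejected(self):
        matrix = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (10, 5)))
        matrix.columns = [f"chr1:{i}" for i in range(5)]
        ages = pd.Series(5.0, index=matrix.index)
        with pytest.raises(ValueError, match="constant"):
            train_elastic_net_clock(matrix, ages, ClockTrainingConfig(seed=0, cv_folds=5))

    def test_missing_values_rejected(self):
        matrix = pd.DataFrame({"chr1:1": [0.1, np.nan, 0.3]})
        ages = pd.Series([1.0, 2.0, 3.0], index=matrix.index)
        with pytest.raises(ValueError, match="missing"):
            train_elastic_net_clock(matrix, ages)

    def test_training_deterministic(self, trained):
        cohort, complete, model = trained
        again = train_elastic_net_clock(
            complete, cohort.truth.reference_ages, ClockTrainingConfig(seed=21, cv_folds=5, n_lambdas=30)
        )
        assert again.site_keys == model.site_keys
        np.testing.assert_array_equal(again.weights, model.weights)
        assert again.intercept == model.intercept

    def test_zero_weight_sites_do_not_affect_predictions(self, trained):
        _, complete, model = trained
        base = predict_ages(complete, model)
        dropped = complete.drop(
            columns=[c for c in complete.columns if c not in model.site_keys][:20]
        )
        pd.testing.assert_series_equal(base, predict_ages(dropped, model))


class TestNoiseFloor:
    @staticmethod
    def _holdout_mae(n, sigma, seed):
        rng = np.random.default_rng(seed)
        ages = pd.Series(rng.uniform(1, 27, n), index=[f"s{i}" for i in range(n)])
        # one perfectly informative site carrying age + noise (in age units)
        matrix = pd.DataFrame({"chr1:10": (ages + rng.normal(0, sigma, n)) / 30.0})
        model = train_elastic_net_clock(
            matrix, ages, ClockTrainingConfig(seed=seed, cv_folds=5)
        )
        return model.test_evaluation.mae

    def test_holdout_mae_bounded_below_by_noise_floor(self):
        """With observation noise sigma, no clock beats MAE ~ sigma*sqrt(2/pi);
        the trained clock approaches that floor as n grows."""
        sigma = 2.0
        floor = sigma * np.sqrt(2 / np.pi)
        mae_small = self._holdout_mae(60, sigma, seed=3)
        mae_large = self._holdout_mae(240, sigma, seed=3)
        assert mae_small >= 0.75 * floor
        assert mae_large >= 0.75 * floor
        assert mae_large <= 1.35 * floor


class TestImputation:
    def _model(self, sites):
        return ClockModel(
            site_keys=sites,
            weights=np.ones(len(sites)),
            intercept=0.0,
            site_means=pd.Series(0.5, index=sites),
            reference_regression=(1.0, 0.0),
        )

    def test_complete_profile_identity(self):
        model = self._model(["chr1:1", "chr1:2"])
        matrix = pd.DataFrame({"chr1:1": [0.1, 0.2], "chr1:2": [0.3, 0.4]}, index=["a", "b"])
        pd.testing.assert_frame_equal(impute_clock_sites(matrix, model), matrix)

    def test_missing_cell_gets_cohort_site_mean(self):
        model = self._model(["chr1:1", "chr1:2"])
        matrix = pd.DataFrame(
            {"chr1:1": [0.1, np.nan, 0.3], "chr1:2": [0.5, 0.5, 0.5]}, index=["a", "b", "c"]
        )
        filled = impute_clock_sites(matrix, model)
        assert filled.loc["b", "chr1:1"] == pytest.approx(0.2)

    def test_two_stage_matches_enumeration_oracle(self, rng):
        sites = [f"chr1:{i}" for i in range(8)]
        model = self._model(sites)
        values = rng.uniform(0, 1, (6, 8))
        holes = rng.random((6, 8)) < 0.4
        values[holes] = np.nan
        values[:, 3] = np.nan  # one site covered in no sample
        values[0, :] = rng.uniform(0, 1, 8)  # keep every sample partially covered
        values[0, 3] = np.nan
        matrix = pd.DataFrame(values, columns=sites)
        filled = impute_clock_sites(matrix, model)
        for i in range(6):
            for j in range(8):
                if not np.isnan(values[i, j]):
                    assert filled.iat[i, j] == values[i, j]
                else:
                    col = values[:, j]
                    if np.isnan(col).all():
                        expected = np.nanmean(values[i, :])
                    else:
                        expected = np.nanmean(col)
                    assert filled.iat[i, j] == pytest.approx(expected)

    def test_fully_missing_profile_rejected(self):
        model = self._model(["chr1:1"])
        matrix = pd.DataFrame({"chr1:1": [np.nan]}, index=["a"])
        with pytest.raises(ValueError, match="covers no clock site"):
            impute_clock_sites(matrix, model)


class TestPrediction:
    def test_affine_identities(self):
        model = ClockModel(
            site_keys=["chr1:1", "chr1:2"],
            weights=np.array([2.0, -1.0]),
            intercept=10.0,
            site_means=pd.Series(0.5, index=["chr1:1", "chr1:2"]),
            reference_regression=(1.0, 0.0),
        )
        zeros = pd.DataFrame({"chr1:1": [0.0], "chr1:2": [0.0]}, index=["a"])
        assert predict_ages(zeros, model).iloc[0] == 10.0
        empty_model = ClockModel(
            site_keys=[], weights=np.array([]), intercept=7.0,
            site_means=pd.Series(dtype=float), reference_regression=(1.0, 0.0),
        )
        assert (predict_ages(zeros, empty_model) == 7.0).all()

    def test_matches_dot_product_oracle(self, rng):
        sites = [f"chr1:{i}" for i in range(5)]
        weights = rng.normal(0, 3, 5)
        model = ClockModel(
            site_keys=sites, weights=weights, intercept=2.5,
            site_means=pd.Series(0.5, index=sites), reference_regression=(1.0, 0.0),
        )
        profile = rng.uniform(0, 1, (3, 5))
        matrix = pd.DataFrame(profile, columns=sites)
        expected = 2.5 + profile @ weights
        np.testing.assert_allclose(predict_ages(matrix, model).to_numpy(), expected)

    def test_prediction_order_invariant_to_site_permutation(self, rng):
        sites = [f"chr1:{i}" for i in range(5)]
        model = ClockModel(
            site_keys=sites, weights=rng.normal(0, 1, 5), intercept=0.0,
            site_means=pd.Series(0.5, index=sites), reference_regression=(1.0, 0.0),
        )
        matrix = pd.DataFrame(rng.uniform(0, 1, (2, 5)), columns=sites)
        shuffled = matrix[list(reversed(sites))]
        pd.testing.assert_series_equal(predict_ages(matrix, model), predict_ages(shuffled, model))


class TestEvaluation:
    def test_perfect_and_shifted(self):
        chron = pd.Series([10.0, 15.0, 20.0, 25.0])
        perfect = evaluate_clock(chron, chron)
        assert perfect.mae == 0 and perfect.pearson_r == pytest.approx(1.0)
        shifted = evaluate_clock(chron + 2, chron)
        assert shifted.mae == pytest.approx(2.0)
        assert shifted.pearson_r == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        pred = pd.Series(rng.normal(20, 5, 40))
        chron = pd.Series(rng.normal(20, 5, 40))
        ev = evaluate_clock(pred, chron)
        assert ev.mae == pytest.approx(np.mean(np.abs(pred - chron)))
        assert ev.medae == pytest.approx(np.median(np.abs(pred - chron)))
        x, y = pred - pred.mean(), chron - chron.mean()
        r_oracle = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
        assert ev.pearson_r == pytest.approx(r_oracle)


class TestAcceleration:
    def test_point_on_line_and_zero_sum(self, rng):
        chron = pd.Series(rng.uniform(5, 25, 30))
        pred = 0.8 * chron + 3 + pd.Series(rng.normal(0, 1, 30))
        from scipy.stats import linregress

        fit = linregress(chron, pred)
        acc = age_acceleration(pred, chron, (fit.slope, fit.intercept))
        assert abs(acc["acceleration"].sum()) < 1e-9  # least-squares identity
        on_line = age_acceleration(
            pd.Series([fit.slope * 10 + fit.intercept]), pd.Series([10.0]),
            (fit.slope, fit.intercept),
        )
        assert on_line["acceleration"].iloc[0] == pytest.approx(0.0)

    def test_uniform_offset_recovered(self, trained):
        cohort, complete, model = trained
        pred = predict_ages(complete, model) + 3.0
        chron = cohort.truth.reference_ages
        base = age_acceleration(pred - 3.0, chron, model.reference_regression)
        shifted = age_acceleration(pred, chron, model.reference_regression)
        assert (shifted["acceleration"] - base["acceleration"]).mean() == pytest.approx(3.0)

    def test_invariant_to_age_shift_with_refit(self, rng):
        from scipy.stats import linregress

        chron = pd.Series(rng.uniform(5, 25, 30))
        pred = 0.9 * chron + rng.normal(0, 1, 30)
        fit1 = linregress(chron, pred)
        acc1 = age_acceleration(pred, chron, (fit1.slope, fit1.intercept))
        fit2 = linregress(chron + 100, pred)
        acc2 = age_acceleration(pred, chron + 100, (fit2.slope, fit2.intercept))
        np.testing.assert_allclose(
            acc1["acceleration"].to_numpy(), acc2["acceleration"].to_numpy(), atol=1e-8
        )

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            age_acceleration(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]), None)


def test_save_load_round_trip(tmp_path, trained):
    _, complete, model = trained
    ma.clock_core.save_clock(model, tmp_path / "clock")
    back = ma.clock_core.load_clock(tmp_path / "clock")
    assert back.site_keys == model.site_keys
    np.testing.assert_allclose(back.weights, model.weights)
    assert back.intercept == pytest.approx(model.intercept)
    pd.testing.assert_series_equal(
        predict_ages(complete, back), predict_ages(complete, model)
    )
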