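"""rDNA feature tables, the four imputers, and the model grid."""

import numpy as np
import pandas as pd
import pytest

import methaging as ma
from methaging.clock_core import ClockTrainingConfig
from methaging.methylation_io import write_bismark_cov
from methaging.rdna_clock import (
    ImputationSpec,
    _FittedImputer,
    build_rdna_table,
    feature_age_correlations,
    impute,
    restrict_to_common_features,
    run_model_grid,
    select_best,
)


def _cov_file(tmp_path, name, positions, fracs, chrom="rDNA"):
    table = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "meth_frac": fracs,
            "coverage": [10] * len(positions),
        }
    )
    return write_bismark_cov(table, tmp_path / f"{name}.cov")


class TestFeatureTable:
    def test_union_of_positions(self, tmp_path):
        files = {
            "a": _cov_file(tmp_path, "a", [10, 20], [0.1, 0.2]),
            "b": _cov_file(tmp_path, "b", [20, 30], [0.5, 0.6]),
        }
        table = build_rdna_table(files, "rDNA")
        assert list(table.columns) == [10, 20, 30]
        assert np.isnan(table.loc["a", 30])
        assert table.loc["b", 20] == pytest.approx(50.0)

    def test_single_file_identity(self, tmp_path):
        files = {"a": _cov_file(tmp_path, "a", [5, 15], [0.3, 0.7])}
        table = build_rdna_table(files, "rDNA")
        np.testing.assert_allclose(table.loc["a"], [30.0, 70.0])

    def test_cells_match_brute_force_lookup(self, tmp_path, rng):
        truth = {}
        files = {}
        for sid in ["x", "y", "z"]:
            positions = np.sort(rng.choice(100, 12, replace=False)) + 1
            fracs = rng.integers(0, 11, 12) / 10.0
            truth[sid] = dict(zip(positions, 100 * fracs))
            files[sid] = _cov_file(tmp_path, sid, positions, fracs)
        table = build_rdna_table(files, "rDNA")
        for sid, expected in truth.items():
            for pos in table.columns:
                if pos in expected:
                    assert table.loc[sid, pos] == pytest.approx(expected[pos])
                else:
                    assert np.isnan(table.loc[sid, pos])

    def test_wrong_reference_rejected(self, tmp_path):
        files = {"a": _cov_file(tmp_path, "a", [10], [0.5], chrom="chr1")}
        with pytest.raises(ValueError, match="no rows"):
            build_rdna_table(files, "rDNA")


class TestRestrict:
    def test_identity_and_disjoint(self):
        a = pd.DataFrame(np.ones((2, 3)), columns=[1, 2, 3])
        b = pd.DataFrame(np.ones((2, 3)), columns=[1, 2, 3])
        ra, rb = restrict_to_common_features(a, b)
        assert list(ra.columns) == list(rb.columns) == [1, 2, 3]
        c = pd.DataFrame(np.ones((2, 2)), columns=[8, 9])
        with pytest.raises(ValueError, match="common"):
            restrict_to_common_features(a, c)

    def test_matches_set_oracle(self, rng):
        cols_a = sorted(rng.choice(50, 20, replace=False))
        cols_b = sorted(rng.choice(50, 20, replace=False))
        a = pd.DataFrame(np.ones((2, 20)), columns=cols_a)
        b = pd.DataFrame(np.ones((2, 20)), columns=cols_b)
        expected = sorted(set(cols_a) & set(cols_b))
        ra, rb = restrict_to_common_features(a, b)
        assert list(ra.columns) == expected == list(rb.columns)


class TestImputers:
    def test_mean_fills_column_mean(self):
        table = pd.DataFrame({1: [10.0, np.nan, 20.0]})
        filled = impute(table, ImputationSpec("mean"))
        assert filled.iloc[1, 0] == pytest.approx(15.0)

    def test_knn_recovers_duplicate_row(self, rng):
        base = rng.uniform(0, 100, (5, 8))
        values = np.vstack([base, base[0]])
        values[5, [2, 5]] = np.nan
        table = pd.DataFrame(values)
        filled = impute(table, ImputationSpec("knn", k=1))
        assert filled.iloc[5, 2] == pytest.approx(base[0, 2])
        assert filled.iloc[5, 5] == pytest.approx(base[0, 5])

    def test_soft_impute_recovers_rank_one(self, rng):
        u = rng.uniform(0.5, 1.0, 20)
        v = rng.uniform(10, 90, 15)
        truth = np.outer(u, v) / u.max()  # rank-1, values within [0, 100]
        values = truth.copy()
        holes = rng.random(truth.shape) < 0.1
        values[holes] = np.nan
        table = pd.DataFrame(values)
        filled = impute(table, ImputationSpec("soft_impute", rank=1, tol=1e-10, max_iter=500))
        np.testing.assert_allclose(filled.to_numpy()[holes], truth[holes], atol=1e-6)

    @pytest.mark.parametrize("method", ["mean", "knn", "soft_impute", "pca"])
    def test_observed_entries_untouched(self, method, rng):
        values = rng.uniform(0, 100, (10, 6))
        holes = rng.random(values.shape) < 0.2
        with_holes = values.copy()
        with_holes[holes] = np.nan
        table = pd.DataFrame(with_holes)
        filled = impute(table, ImputationSpec(method, rank=2))
        observed = ~holes
        np.testing.assert_array_equal(filled.to_numpy()[observed], values[observed])
        assert not np.isnan(filled.to_numpy()).any()
        assert (filled.to_numpy() >= 0).all() and (filled.to_numpy() <= 100).all()

    @pytest.mark.parametrize("method", ["mean", "knn", "soft_impute", "pca"])
    def test_identity_on_complete_table(self, method, rng):
        table = pd.DataFrame(rng.uniform(0, 100, (8, 5)))
        filled = impute(table, ImputationSpec(method, rank=2))
        pd.testing.assert_frame_equal(filled, table)

    def test_soft_impute_objective_non_increasing(self, rng):
        """EM SoftImpute decreases 0.5||P_obs(X-Z)||^2 + lam*||Z||_* monotonically."""
        truth = rng.uniform(0, 100, (15, 10))
        values = truth.copy()
        values[rng.random(truth.shape) < 0.3] = np.nan
        mask = ~np.isnan(values)
        lam = 5.0
        col_means = np.nanmean(values, axis=0)
        filled = np.where(mask, values, col_means)
        objectives = []
        z = filled
        for _ in range(25):
            u, s, vt = np.linalg.svd(np.where(mask, values, z), full_matrices=False)
            s_shrunk = np.maximum(s - lam, 0.0)
            z = (u * s_shrunk) @ vt
            obj = 0.5 * np.sum((values[mask] - z[mask]) ** 2) + lam * s_shrunk.sum()
            objectives.append(obj)
        diffs = np.diff(objectives)
        assert (diffs <= 1e-6 * max(objectives)).all()

    def test_all_missing_column_rejected(self):
        table = pd.DataFrame({1: [np.nan, np.nan], 2: [1.0, 2.0]})
        with pytest.raises(ValueError, match="no observed value"):
            impute(table, ImputationSpec("mean"))


@pytest.fixture(scope="module")
def rdna_cohort():
    config = ma.SimulationConfig(
        n_samples=80, n_sites=120, frac_age_associated=0.2, coverage_mean=150.0,
        low_coverage_rate=0.15, seed=41,
    )
    cohort = ma.simulate_training_cohort(config, chrom="rDNA")
    table = 100.0 * ma.mask_low_coverage(cohort.methylation, cohort.coverage)
    return cohort, table.dropna(axis=1, how="all")


class TestModelGrid:
    def test_grid_is_complete_and_deterministic(self, rdna_cohort):
        cohort, table = rdna_cohort
        cfg = ClockTrainingConfig(seed=41, cv_folds=5, n_lambdas=20)
        grid = run_model_grid(table, cohort.truth.reference_ages, cfg)
        assert len(grid) == 12
        assert set(grid["imputation"]) == {"mean", "knn", "soft_impute", "pca"}
        assert set(grid["model"]) == {"elastic_net", "gradient_boosting", "random_forest"}
        again = run_model_grid(table, cohort.truth.reference_ages, cfg)
        pd.testing.assert_frame_equal(grid, again)

    def test_recovers_age_signal(self, rdna_cohort):
        cohort, table = rdna_cohort
        grid = run_model_grid(
            table, cohort.truth.reference_ages, ClockTrainingConfig(seed=41, cv_folds=5, n_lambdas=20)
        )
        assert select_best(grid)["pearson_r"] >= 0.6

    def test_imputer_uses_training_rows_only(self, rdna_cohort):
        """Corrupting test rows must not change the training-side statistics."""
        cohort, table = rdna_cohort
        from methaging.clock_core import split_train_test

        train_ids, test_ids = split_train_test(list(table.index), 0.8, 41)
        spec = ImputationSpec("mean")
        fitted = _FittedImputer(table.loc[train_ids], spec)
        corrupted = table.copy()
        corrupted.loc[test_ids] = 0.0
        refitted = _FittedImputer(corrupted.loc[train_ids], spec)
        np.testing.assert_array_equal(fitted.col_means, refitted.col_means)
        np.testing.assert_array_equal(fitted.train_filled, refitted.train_filled)

    def test_too_few_samples_rejected(self):
        table = pd.DataFrame(np.ones((5, 4)))
        ages = pd.Series(np.arange(5.0), index=table.index)
        with pytest.raises(ValueError, match="at least 10"):
            run_model_grid(table, ages)


class TestSelectBest:
    def _grid(self, rows):
        return pd.DataFrame(rows, columns=["imputation", "model", "mae", "pearson_r"])

    def test_single_row(self):
        grid = self._grid([["mean", "elastic_net", 4.0, 0.9]])
        assert select_best(grid)["mae"] == 4.0

    def test_min_mae_wins(self):
        grid = self._grid(
            [["mean", "elastic_net", 4.0, 0.5], ["knn", "random_forest", 5.0, 0.99]]
        )
        assert select_best(grid)["imputation"] == "mean"

    def test_tie_broken_by_higher_r_then_method_order(self):
        grid = self._grid(
            [["pca", "random_forest", 4.0, 0.7], ["knn", "elastic_net", 4.0, 0.9]]
        )
        assert select_best(grid)["imputation"] == "knn"
        tie = self._grid(
            [["knn", "elastic_net", 4.0, 0.9], ["mean", "elastic_net", 4.0, 0.9]]
        )
        assert select_best(tie)["imputation"] == "mean"

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_best(self._grid([]))


def test_informative_features_all_positively_correlated():
    """When only positively drifting sites carry signal, the top-ranked
    feature-age correlations are all positive."""
    rng = np.random.default_rng(77)
    n = 60
    ages = rng.uniform(1, 27, n)
    informative = np.array([20 + 2.0 * ages + rng.normal(0, 2, n) for _ in range(5)]).T
    noise = rng.uniform(20, 80, (n, 20))
    table = pd.DataFrame(np.hstack([informative, noise]))
    corr = feature_age_correlations(table, pd.Series(ages, index=table.index))
    top5 = corr.abs().sort_values(ascending=False).index[:5]
    assert (corr[top5] > 0).all()
    assert set(top5) == set(range(5))
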