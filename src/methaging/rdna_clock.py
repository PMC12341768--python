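"""Ribosomal-DNA methylation clock: feature table, imputation, model grid.

The rDNA repeat is present in many copies per genome, so bisulfite reads
pile up deeply on its CpGs and an rDNA-restricted age predictor transfers
well across datasets.  This module consumes per-sample Bismark coverage
files aligned to a single rDNA reference, merges them into a sample x
position feature table of methylation *percentages* (0-100; the format the
upstream extraction emits), fills the remaining holes with one of four
imputation techniques — column mean, k-nearest-neighbour, SoftImpute
(iterative SVD with soft-thresholded singular values), or iterative PCA
reconstruction — and evaluates a grid of three regression families
(elastic net, gradient boosting, random forest) over an 80/20 split,
one row per (imputation x model) combination.  The best row is the one
with minimum test MAE (ties: higher Pearson r, then fixed method order).

Leakage control: during grid evaluation every imputer is fitted on the
training rows only and applied to the test rows using training statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.impute import KNNImputer

from .clock_core import ClockTrainingConfig, _fit_elastic_net, split_train_test
from .methylation_io import read_bismark_cov

logger = logging.getLogger("methaging")

IMPUTATION_METHODS = ("mean", "knn", "soft_impute", "pca")
MODEL_FAMILIES = ("elastic_net", "gradient_boosting", "random_forest")


@dataclass(frozen=True)
class ImputationSpec:
    """Imputation technique and its knobs.

    ``k`` applies to knn; ``rank`` to soft_impute/pca (None = min(10,
    n_samples - 1)); ``shrinkage`` is the SoftImpute soft-threshold on the
    singular values (0 = plain iterative hard-rank SVD completion).
    """

    method: str = "mean"
    k: int = 5
    rank: int | None = None
    shrinkage: float = 0.0
    tol: float = 1e-4
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.method not in IMPUTATION_METHODS:
            raise ValueError(f"unknown imputation method {self.method!r}")
        if self.k < 1 or (self.rank is not None and self.rank < 1) or self.tol <= 0:
            raise ValueError("invalid imputation parameters")


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def build_rdna_table(
    cov_files: dict[str, str | Path], rdna_reference_name: str
) -> pd.DataFrame:
    """Merge per-sample coverage files into a sample x position table.

    ``cov_files`` maps sample id -> Bismark .cov path.  Only rows on
    ``rdna_reference_name`` are used; values are methylation percentages,
    absent cells NaN; columns (positions) are strictly increasing.
    """
    columns = {}
    for sample_id, path in cov_files.items():
        table = read_bismark_cov(path)
        table = table[table["chrom"] == rdna_reference_name]
        columns[sample_id] = pd.Series(
            100.0 * table["meth_frac"].to_numpy(dtype=float),
            index=table["pos"].astype(int).to_numpy(),
        )
    merged = pd.DataFrame(columns).T
    if merged.empty or merged.shape[1] == 0:
        raise ValueError(f"no rows found on reference {rdna_reference_name!r}")
    return merged.reindex(sorted(merged.columns), axis=1)


def restrict_to_common_features(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two feature tables to their shared positions, same order."""
    if table_a.empty or table_b.empty:
        raise ValueError("feature tables must be nonempty")
    common = sorted(set(table_a.columns) & set(table_b.columns))
    if not common:
        raise ValueError("no common features between the two tables")
    return table_a[common], table_b[common]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _default_rank(spec: ImputationSpec, n_samples: int) -> int:
    return spec.rank if spec.rank is not None else max(1, min(10, n_samples - 1))


def _svd_complete(
    values: np.ndarray,
    mask: np.ndarray,
    rank: int,
    shrinkage: float,
    tol: float,
    max_iter: int,
    center: bool,
    col_means: np.ndarray,
) -> np.ndarray:
    """EM-style low-rank completion.  ``mask`` flags observed entries.

    With ``center`` (the PCA flavour) columns are centred by ``col_means``
    before each truncated SVD; without it (SoftImpute) the singular values
    are additionally soft-thresholded by ``shrinkage``.
    """
    filled = np.where(mask, values, np.broadcast_to(col_means, values.shape))
    previous = filled.copy()
    for _ in range(max_iter):
        work = filled - col_means if center else filled
        u, s, vt = np.linalg.svd(work, full_matrices=False)
        s = np.maximum(s - shrinkage, 0.0)
        k = min(rank, len(s))
        recon = (u[:, :k] * s[:k]) @ vt[:k]
        if center:
            recon = recon + col_means
        filled = np.where(mask, values, recon)
        delta = np.sqrt(np.mean((filled - previous) ** 2))
        scale = max(np.sqrt(np.mean(previous**2)), 1e-12)
        if delta / scale < tol:
            break
        previous = filled.copy()
    return filled


def impute(table: pd.DataFrame, spec: ImputationSpec = ImputationSpec()) -> pd.DataFrame:
    """Complete a feature table; observed entries are returned untouched and
    imputed values are clipped to [0, 100]."""
    values = table.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if not mask.any():
        raise ValueError("feature table is entirely missing")
    if not mask.any(axis=0).all():
        bad = table.columns[~mask.any(axis=0)][0]
        raise ValueError(f"feature {bad!r} has no observed value")
    col_means = np.nanmean(values, axis=0)

    if spec.method == "mean":
        filled = np.where(mask, values, np.broadcast_to(col_means, values.shape))
    elif spec.method == "knn":
        imputer = KNNImputer(n_neighbors=spec.k)
        filled = imputer.fit_transform(values)
    else:
        rank = _default_rank(spec, len(table))
        filled = _svd_complete(
            values,
            mask,
            rank=rank,
            shrinkage=spec.shrinkage if spec.method == "soft_impute" else 0.0,
            tol=spec.tol,
            max_iter=spec.max_iter,
            center=spec.method == "pca",
            col_means=col_means,
        )
    filled = np.where(mask, values, np.clip(filled, 0.0, 100.0))
    return pd.DataFrame(filled, index=table.index, columns=table.columns)


class _FittedImputer:
    """Imputer state learned from training rows only.

    For mean: column means.  For knn: the training rows as donor pool.  For
    soft_impute/pca: training column means plus the learned row-space
    (``vt``), so test rows are completed by iterative projection onto it.
    """

    def __init__(self, train: pd.DataFrame, spec: ImputationSpec):
        self.spec = spec
        self.columns = train.columns
        values = train.to_numpy(dtype=float)
        mask = ~np.isnan(values)
        if not mask.any(axis=0).all():
            raise ValueError("a feature has no observed training value")
        self.col_means = np.nanmean(values, axis=0)
        if spec.method == "knn":
            self._knn = KNNImputer(n_neighbors=spec.k)
            self.train_filled = self._knn.fit_transform(values)
        elif spec.method in ("soft_impute", "pca"):
            completed = impute(train, spec).to_numpy(dtype=float)
            self.train_filled = completed
            rank = _default_rank(spec, len(train))
            center = spec.method == "pca"
            work = completed - self.col_means if center else completed
            _, _, vt = np.linalg.svd(work, full_matrices=False)
            self._vt = vt[: min(rank, vt.shape[0])]
            self._center = center
        else:
            self.train_filled = np.where(mask, values, self.col_means)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        values = table[self.columns].to_numpy(dtype=float)
        mask = ~np.isnan(values)
        if self.spec.method == "mean":
            filled = np.where(mask, values, self.col_means)
        elif self.spec.method == "knn":
            filled = self._knn.transform(values)
        else:
            filled = np.where(mask, values, self.col_means)
            previous = filled.copy()
            for _ in range(self.spec.max_iter):
                work = filled - self.col_means if self._center else filled
                recon = (work @ self._vt.T) @ self._vt
                if self._center:
                    recon = recon + self.col_means
                filled = np.where(mask, values, recon)
                delta = np.sqrt(np.mean((filled - previous) ** 2))
                if delta / max(np.sqrt(np.mean(previous**2)), 1e-12) < self.spec.tol:
                    break
                previous = filled.copy()
        return np.where(mask, values, np.clip(filled, 0.0, 100.0))


# ---------------------------------------------------------------------------
# Model grid
# ---------------------------------------------------------------------------

def _fit_predict(
    family: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int,
    enet_config: ClockTrainingConfig,
) -> np.ndarray:
    if family == "elastic_net":
        coef, intercept = _fit_elastic_net(X_train, y_train, enet_config)
        return intercept + X_test @ coef
    if family == "gradient_boosting":
        model = GradientBoostingRegressor(n_estimators=100, max_depth=3, random_state=seed)
    elif family == "random_forest":
        model = RandomForestRegressor(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown model family {family!r}")
    model.fit(X_train, y_train)
    return model.predict(X_test)


def run_model_grid(
    table: pd.DataFrame,
    ages: pd.Series,
    split_config: ClockTrainingConfig = ClockTrainingConfig(),
    specs: Sequence[ImputationSpec] | None = None,
) -> pd.DataFrame:
    """Evaluate every (imputation x model family) combination.

    Returns a DataFrame with one row per combination: imputation, model,
    test MAE (months) and Pearson r.  The split, imputers and tree seeds all
    derive from ``split_config.seed``, so the grid is reproducible.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 samples for a meaningful grid")
    ages = ages.loc[table.index].astype(float)
    if np.ptp(ages.to_numpy()) == 0:
        raise ValueError("ages are constant")
    if specs is None:
        specs = [ImputationSpec(method=m) for m in IMPUTATION_METHODS]
    train_ids, test_ids = split_train_test(
        list(table.index), split_config.train_fraction, split_config.seed
    )
    y_train = ages.loc[train_ids].to_numpy()
    y_test = ages.loc[test_ids].to_numpy()

    rows = []
    for spec in specs:
        fitted = _FittedImputer(table.loc[train_ids], spec)
        X_train = fitted.train_filled
        X_test = fitted.transform(table.loc[test_ids])
        for family in MODEL_FAMILIES:
            pred = _fit_predict(family, X_train, y_train, X_test, split_config.seed, split_config)
            mae = float(np.mean(np.abs(pred - y_test)))
            if np.ptp(pred) == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(pred, y_test).statistic)
            rows.append(
                {"imputation": spec.method, "model": family, "mae": mae, "pearson_r": r}
            )
            logger.info("rDNA grid: %s + %s: MAE %.2f, r %.3f", spec.method, family, mae, r)
    return pd.DataFrame(rows)


def select_best(grid: pd.DataFrame) -> pd.Series:
    """Row with minimum MAE; ties broken by higher r, then method order."""
    if grid.empty:
        raise ValueError("empty model grid")
    ranked = grid.copy()
    ranked["_imp"] = ranked["imputation"].map({m: i for i, m in enumerate(IMPUTATION_METHODS)})
    ranked["_mod"] = ranked["model"].map({m: i for i, m in enumerate(MODEL_FAMILIES)})
    ranked["_neg_r"] = -ranked["pearson_r"].fillna(-np.inf)
    ranked = ranked.sort_values(["mae", "_neg_r", "_imp", "_mod"], kind="mergesort")
    best = ranked.iloc[0]
    return grid.loc[best.name]


def feature_age_correlations(table: pd.DataFrame, ages: pd.Series) -> pd.Series:
    """Pearson correlation of each (complete) feature with age, for ranking
    top clock features; NaN for constant features."""
    ages = ages.loc[table.index].to_numpy(dtype=float)
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        if obs.sum() < 3 or np.ptp(x[obs]) == 0 or np.ptp(ages[obs]) == 0:
            out[col] = float("nan")
        else:
            out[col] = float(stats.pearsonr(x[obs], ages[obs]).statistic)
    return pd.Series(out)
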