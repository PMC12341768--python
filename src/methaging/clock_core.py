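"""Elastic-net epigenetic clocks and residual-based age acceleration.

An epigenetic clock here is a penalised linear model predicting
chronological age (months) from CpG methylation fractions.  Training fits
an elastic net (mixing parameter 0.5 between L1 and L2 by default) on a
random 80% of the samples, selecting the penalty strength by internal
k-fold cross-validation, and keeps only the CpG sites with nonzero weight.
The held-out 20% provides the test-set evaluation (MAE, median AE, Pearson
r) and the *reference regression* — the least-squares line of predicted on
chronological age — against which **age acceleration** is later measured:

    acceleration = predicted - (slope * chronological + intercept)

so that over the set the line was fitted on, accelerations sum to zero.

Features are standardised internally during fitting; coefficients are
returned on the original scale (months per methylation-fraction unit), so
weights are directly interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold


@dataclass(frozen=True)
class ClockTrainingConfig:
    """Training hyperparameters.

    ``mixing`` is the elastic-net L1/L2 mixing parameter (0 = ridge,
    1 = lasso); ``lambda_rule`` records how the penalty strength is picked
    ("min" = minimum cross-validated error over a log-spaced path).
    """

    mixing: float = 0.5
    lambda_rule: str = "min"
    cv_folds: int = 10
    train_fraction: float = 0.8
    standardize: bool = True
    n_lambdas: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError(f"mixing must be in [0, 1], got {self.mixing}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.lambda_rule != "min":
            raise ValueError(f"unknown lambda_rule {self.lambda_rule!r}")


@dataclass
class ClockEvaluation:
    mae: float
    medae: float
    pearson_r: float
    pearson_p: float
    n: int
    predictions: pd.Series


@dataclass
class ClockModel:
    """A trained linear clock: nonzero-weight sites, their weights (months
    per fraction), the intercept, per-site training means (for reference /
    serialization) and the reference regression from the held-out test set."""

    site_keys: list[str]
    weights: np.ndarray
    intercept: float
    site_means: pd.Series
    reference_regression: tuple[float, float]  # (slope, intercept)
    config: ClockTrainingConfig = field(default_factory=ClockTrainingConfig)
    test_evaluation: ClockEvaluation | None = None

    def __post_init__(self) -> None:
        if len(self.site_keys) != len(self.weights):
            raise ValueError("site_keys and weights must have equal length")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def split_train_test(
    sample_ids: Sequence[str], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seed-deterministic random train/test split.

    The test size is ``round((1 - train_fraction) * n)`` (banker-free round
    half away from zero), so 134 samples at 80/20 split into 107 train and
    27 test; both parts are guaranteed non-empty.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two samples to split")
    n_test = int(np.floor((1.0 - train_fraction) * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test = sorted(ids[i] for i in order[:n_test])
    train = sorted(ids[i] for i in order[n_test:])
    return train, test


def _fit_elastic_net(
    X: np.ndarray, y: np.ndarray, config: ClockTrainingConfig
) -> tuple[np.ndarray, float]:
    """Fit an elastic net with CV-selected penalty; coefficients returned on
    the original feature scale."""
    if np.ptp(y) == 0:
        raise ValueError("ages are constant; cannot train a clock")
    n = len(y)
    cv_folds = min(config.cv_folds, n)
    if cv_folds < 2:
        raise ValueError("too few samples for cross-validated penalty selection")
    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
        Xs = X
    # l1_ratio=0 is unsupported by ElasticNetCV's coordinate descent path
    l1_ratio = max(config.mixing, 1e-3)
    model = ElasticNetCV(
        l1_ratio=l1_ratio,
        alphas=config.n_lambdas,  # int: length of the automatic log-spaced path
        cv=KFold(cv_folds, shuffle=True, random_state=config.seed),
        max_iter=5000,
        random_state=config.seed,
    )
    model.fit(Xs, y)
    coef = model.coef_ / sd
    intercept = float(model.intercept_ - np.dot(model.coef_, mean / sd))
    return coef, intercept


def train_elastic_net_clock(
    matrix: pd.DataFrame, ages: pd.Series, config: ClockTrainingConfig = ClockTrainingConfig()
) -> ClockModel:
    """Train a clock on a complete (imputed) methylation matrix.

    Splits the cohort per ``config.train_fraction``/``config.seed``, fits the
    elastic net on the training part, evaluates on the held-out part, and
    fits the reference regression (predicted vs chronological) there.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute before training")
    ages = ages.loc[matrix.index].astype(float)
    train_ids, test_ids = split_train_test(list(matrix.index), config.train_fraction, config.seed)
    X_train = matrix.loc[train_ids].to_numpy(dtype=float)
    y_train = ages.loc[train_ids].to_numpy()
    coef, intercept = _fit_elastic_net(X_train, y_train, config)

    nonzero = np.flatnonzero(coef)
    site_keys = [matrix.columns[i] for i in nonzero]
    weights = coef[nonzero]
    site_means = matrix.loc[train_ids, site_keys].mean(axis=0)

    test_pred = pd.Series(
        intercept + matrix.loc[test_ids, site_keys].to_numpy(dtype=float) @ weights,
        index=test_ids,
    )
    evaluation = evaluate_clock(test_pred, ages.loc[test_ids])
    chron = ages.loc[test_ids].to_numpy()
    if np.ptp(chron) == 0:
        reference = (0.0, float(test_pred.mean()))
    else:
        fit = stats.linregress(chron, test_pred.to_numpy())
        reference = (float(fit.slope), float(fit.intercept))
    return ClockModel(
        site_keys=site_keys,
        weights=weights,
        intercept=intercept,
        site_means=site_means,
        reference_regression=reference,
        config=config,
        test_evaluation=evaluation,
    )


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def impute_clock_sites(matrix: pd.DataFrame, model: ClockModel) -> pd.DataFrame:
    """Complete a cohort's profiles over the model's clock sites.

    Two-stage mean imputation within the application cohort: a missing value
    is filled with the cohort mean of that site over the samples that cover
    it; a clock site covered in no sample falls back to each sample's own
    mean over its covered clock sites.  A sample covering no clock site at
    all is an error.
    """
    profile = matrix.reindex(columns=model.site_keys)
    observed = profile.notna()
    uncovered_samples = ~observed.any(axis=1)
    if uncovered_samples.any():
        bad = profile.index[uncovered_samples][0]
        raise ValueError(f"sample {bad!r} covers no clock site")
    site_means = profile.mean(axis=0)  # NaN where no sample covers the site
    filled = profile.fillna(site_means)
    sample_means = profile.mean(axis=1)
    filled = filled.apply(lambda col: col.fillna(sample_means), axis=0)
    return filled


def predict_ages(matrix: pd.DataFrame, model: ClockModel) -> pd.Series:
    """Predicted age (months) per sample: intercept + sum(weight * m)."""
    if len(model.site_keys) == 0:
        return pd.Series(model.intercept, index=matrix.index, dtype=float)
    profile = impute_clock_sites(matrix, model)
    return pd.Series(
        model.intercept + profile.to_numpy(dtype=float) @ model.weights, index=matrix.index
    )


def evaluate_clock(predicted: pd.Series, chronological: pd.Series) -> ClockEvaluation:
    """MAE, median AE (months) and Pearson r of predictions vs truth."""
    pred = np.asarray(predicted, dtype=float)
    chron = np.asarray(chronological, dtype=float)
    if pred.size != chron.size or pred.size < 2:
        raise ValueError("need aligned vectors of length >= 2")
    err = np.abs(pred - chron)
    if np.ptp(pred) == 0 or np.ptp(chron) == 0:
        r, p = float("nan"), float("nan")
    else:
        res = stats.pearsonr(pred, chron)
        r, p = float(res.statistic), float(res.pvalue)
    return ClockEvaluation(
        mae=float(err.mean()),
        medae=float(np.median(err)),
        pearson_r=r,
        pearson_p=p,
        n=int(pred.size),
        predictions=pd.Series(pred, index=getattr(predicted, "index", None)),
    )


def age_acceleration(
    predicted: pd.Series,
    chronological: pd.Series,
    reference_regression: tuple[float, float],
) -> pd.DataFrame:
    """Residual age acceleration against a reference regression line.

    ``acceleration = predicted - (slope * chronological + intercept)``; over
    the samples the line was fitted on this sums to ~0 (a least-squares
    identity).
    """
    if reference_regression is None:
        raise ValueError("reference regression is required")
    slope, intercept = reference_regression
    expected = slope * np.asarray(chronological, dtype=float) + intercept
    acc = np.asarray(predicted, dtype=float) - expected
    return pd.DataFrame(
        {
            "predicted": np.asarray(predicted, dtype=float),
            "expected": expected,
            "acceleration": acc,
        },
        index=getattr(predicted, "index", None),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_clock(model: ClockModel, prefix: str | Path) -> tuple[Path, Path]:
    """Write a clock as ``<prefix>.weights.tsv`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    weights_path = prefix.with_suffix(".weights.tsv")
    header_path = prefix.with_suffix(".json")
    pd.DataFrame(
        {
            "site_key": model.site_keys,
            "weight": model.weights,
            "train_mean": model.site_means.to_numpy(),
        }
    ).to_csv(weights_path, sep="\t", index=False)
    header = {
        "intercept": model.intercept,
        "reference_regression": list(model.reference_regression),
        "config": {
            "mixing": model.config.mixing,
            "lambda_rule": model.config.lambda_rule,
            "cv_folds": model.config.cv_folds,
            "train_fraction": model.config.train_fraction,
            "standardize": model.config.standardize,
            "n_lambdas": model.config.n_lambdas,
            "seed": model.config.seed,
        },
    }
    header_path.write_text(json.dumps(header, indent=2))
    return weights_path, header_path


def load_clock(prefix: str | Path) -> ClockModel:
    prefix = Path(prefix)
    weights = pd.read_csv(prefix.with_suffix(".weights.tsv"), sep="\t")
    header = json.loads(prefix.with_suffix(".json").read_text())
    return ClockModel(
        site_keys=list(weights["site_key"]),
        weights=weights["weight"].to_numpy(dtype=float),
        intercept=float(header["intercept"]),
        site_means=pd.Series(weights["train_mean"].to_numpy(), index=list(weights["site_key"])),
        reference_regression=tuple(header["reference_regression"]),
        config=ClockTrainingConfig(**header["config"]),
    )
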