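"""Per-sample intersection clock.

RRBS covers a partly random subset of the genome in each library, so a
fixed-site clock may find few of its CpGs in a new sample.  The
intersection clock instead maximises site use per test sample: for each
sample it (1) intersects the training site set with the sites covered in
that sample, (2) restricts both to the intersection, (3) partitions the
training samples into five seed-deterministic folds, (4) fits one
elastic-net model per fold on the other four folds (each with its own
nested penalty cross-validation), (5) predicts the sample with all five
models and (6) reports their arithmetic mean (``MeanPred``).

Over a cohort this fits five models per sample (5 x n in total); because
samples sharing an identical covered-site set would produce identical fold
models, fits are cached on the (site set, fold) pair and reused, which
leaves every prediction bit-identical to the uncached computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock_core import ClockTrainingConfig, _fit_elastic_net

logger = logging.getLogger("methaging")

N_FOLDS = 5


@dataclass(frozen=True)
class IntersectionPrediction:
    sample_id: str
    n_common_sites: int
    fold_predictions: tuple[float, ...]
    mean_pred: float


@dataclass
class CohortIntersectionResult:
    predictions: list[IntersectionPrediction]
    n_models_fitted: int  # one per (sample, fold), i.e. 5 x n_samples
    n_models_trained: int  # distinct fits after caching
    failed_samples: list[str]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            row = {"sample_id": p.sample_id, "n_common_sites": p.n_common_sites}
            for i, fp in enumerate(p.fold_predictions, start=1):
                row[f"fold{i}_pred"] = fp
            row["mean_pred"] = p.mean_pred
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")


def _make_folds(n: int, seed: int) -> list[np.ndarray]:
    """Seed-deterministic partition of range(n) into five near-equal folds."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, N_FOLDS)]


def intersection_predict(
    train_matrix: pd.DataFrame,
    train_ages: pd.Series,
    test_profile: pd.Series,
    config: ClockTrainingConfig = ClockTrainingConfig(),
) -> IntersectionPrediction:
    """MeanPred for a single test profile (a Series over site keys, NaN for
    sites the sample does not cover)."""
    result = intersection_predict_cohort(
        train_matrix, train_ages, test_profile.to_frame().T, config
    )
    if result.failed_samples:
        raise ValueError(f"sample {result.failed_samples[0]!r} shares no site with the training set")
    return result.predictions[0]


def intersection_predict_cohort(
    train_matrix: pd.DataFrame,
    train_ages: pd.Series,
    cohort: pd.DataFrame,
    config: ClockTrainingConfig = ClockTrainingConfig(),
) -> CohortIntersectionResult:
    """MeanPred for every sample of a cohort matrix (samples x sites).

    Samples with zero common sites are reported in ``failed_samples``
    rather than silently dropped.  Training samples must number at least
    five (one per fold).
    """
    if train_matrix.isna().any().any():
        raise ValueError("training matrix must be complete (impute first)")
    n_train = len(train_matrix.index)
    if n_train < N_FOLDS:
        raise ValueError(f"need >= {N_FOLDS} training samples, got {n_train}")
    ages = train_ages.loc[train_matrix.index].to_numpy(dtype=float)
    folds = _make_folds(n_train, config.seed)
    train_values = train_matrix.to_numpy(dtype=float)
    col_index = {key: i for i, key in enumerate(train_matrix.columns)}

    cache: dict[tuple[frozenset, int], tuple[np.ndarray, float]] = {}
    predictions: list[IntersectionPrediction] = []
    failed: list[str] = []
    n_fitted = 0
    n_trained = 0
    for sample_id, profile in cohort.iterrows():
        covered = [k for k in profile.index[profile.notna()] if k in col_index]
        if not covered:
            failed.append(str(sample_id))
            logger.warning("intersection clock: sample %s shares no covered site with training", sample_id)
            continue
        cols = np.array([col_index[k] for k in covered])
        x_test = profile[covered].to_numpy(dtype=float)
        cache_key_sites = frozenset(covered)
        fold_preds = []
        for fold_idx, fold in enumerate(folds):
            key = (cache_key_sites, fold_idx)
            if key not in cache:
                mask = np.ones(n_train, dtype=bool)
                mask[fold] = False
                coef, intercept = _fit_elastic_net(
                    train_values[np.ix_(mask, cols)], ages[mask], config
                )
                cache[key] = (coef, intercept)
                n_trained += 1
            coef, intercept = cache[key]
            fold_preds.append(float(intercept + x_test @ coef))
            n_fitted += 1
        predictions.append(
            IntersectionPrediction(
                sample_id=str(sample_id),
                n_common_sites=len(covered),
                fold_predictions=tuple(fold_preds),
                mean_pred=float(np.mean(fold_preds)),
            )
        )
        logger.info(
            "intersection clock: sample %s, %d common sites, MeanPred %.2f months",
            sample_id,
            len(covered),
            predictions[-1].mean_pred,
        )
    return CohortIntersectionResult(
        predictions=predictions,
        n_models_fitted=n_fitted,
        n_models_trained=n_trained,
        failed_samples=failed,
    )
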