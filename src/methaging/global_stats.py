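"""Per-sample global methylation statistics and group comparisons.

Two summary statistics are computed per sample over its observed CpG sites:

* **GMM** (global mean methylation) — the mean methylation fraction;
* **MME** (mean methylation entropy) — the mean of the per-site binary
  Shannon entropy ``H(m) = -m log2 m - (1-m) log2 (1-m)``, in bits.

Both are computed over each sample's observed sites (the number used is
reported), since different samples of an RRBS experiment cover different
site sets.  GMM typically drifts down and MME up with age as the methylome
loses its bimodal structure.

Group comparisons use a two-sided Welch t-test (unequal variances), and
p-values are annotated with the conventional significance stars:
ns for p > 0.05, * for 0.01 < p <= 0.05, ** for 0.001 < p <= 0.01,
*** for p <= 0.001 and **** for p <= 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    statistic: float
    p: float
    mean_per_group: dict[str, float]
    direction: str  # label of the group with the higher mean
    stars: str


def site_entropy(m):
    """Binary Shannon entropy (bits) of a methylation fraction.

    Vectorised; uses the convention 0*log2(0) == 0, so the endpoints map to
    exactly 0 and m = 0.5 to exactly 1.
    """
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("methylation fractions must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -m * np.log2(m) - (1.0 - m) * np.log2(1.0 - m)
    h = np.where((m == 0) | (m == 1), 0.0, h)
    return h if h.ndim else float(h)


def sample_gmm(matrix: pd.DataFrame, sample: str) -> float:
    """Mean methylation over the sample's observed sites."""
    values = matrix.loc[sample].dropna()
    if values.empty:
        raise ValueError(f"sample {sample!r} has no observed sites")
    return float(values.mean())


def sample_mme(matrix: pd.DataFrame, sample: str) -> float:
    """Mean per-site entropy (bits) over the sample's observed sites."""
    values = matrix.loc[sample].dropna()
    if values.empty:
        raise ValueError(f"sample {sample!r} has no observed sites")
    return float(np.mean(site_entropy(values.to_numpy())))


def cohort_global_stats(matrix: pd.DataFrame) -> pd.DataFrame:
    """GMM, MME and site counts for every sample of a matrix."""
    rows = []
    values = matrix.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    if not observed.any(axis=1).all():
        missing = matrix.index[~observed.any(axis=1)][0]
        raise ValueError(f"sample {missing!r} has no observed sites")
    entropies = np.where(observed, site_entropy(np.nan_to_num(values, nan=0.5)), np.nan)
    for i, sid in enumerate(matrix.index):
        obs = observed[i]
        rows.append(
            {
                "sample_id": sid,
                "gmm": float(values[i, obs].mean()),
                "mme": float(entropies[i, obs].mean()),
                "n_sites_used": int(obs.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def age_correlation(stat: pd.Series | np.ndarray, ages: pd.Series | np.ndarray) -> CorrelationResult:
    """Pearson correlation of a per-sample statistic with age (two-sided p)."""
    x = np.asarray(stat, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def group_compare(
    stat: pd.Series, groups: pd.Series, metric: str = "stat"
) -> GroupComparison:
    """Two-sided Welch t-test between the two groups of ``groups``."""
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(labels)}")
    a = stat[groups == labels[0]].dropna().to_numpy(dtype=float)
    b = stat[groups == labels[1]].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    means = {str(labels[0]): float(a.mean()), str(labels[1]): float(b.mean())}
    direction = max(means, key=means.get)
    return GroupComparison(
        metric=metric,
        statistic=float(t),
        p=float(p),
        mean_per_group=means,
        direction=direction,
        stars=stars(float(p)),
    )


def stars(p: float) -> str:
    """Significance stars for a p-value (most significant band first)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if p <= 1.00e-04:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
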