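"""Reading, writing and assembly of CpG methylation matrices.

The central in-memory substrate of the package is a pair of aligned pandas
DataFrames:

* a **methylation matrix** — rows are samples, columns are CpG sites, values
  are methylation fractions in [0, 1]; missing observations are ``NaN``;
* a **coverage matrix** — same axes, values are non-negative integer read
  counts (0 where a site was not observed for a sample).

CpG sites are keyed by ``"chrom:pos"`` strings with 1-based positions.
Strands are not merged: a site is whatever the source file reported.
Percentages appear only at I/O boundaries; internally everything is a
fraction, because the entropy statistics downstream need probabilities.

Supported on-disk formats are the Bismark coverage format (six tab-separated
columns: chrom, start, end, methylation percent, methylated count,
unmethylated count) and the CGmap dialect (eight columns: chrom, nucleotide,
position, context, dinucleotide context, methylation level, methylated
count, total count; only CpG-context rows are used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methaging")

# Columns of a per-sample site table as produced by the parsers below.
SITE_TABLE_COLUMNS = ["chrom", "pos", "meth_frac", "coverage"]

_CGMAP_KNOWN_CONTEXTS = {"CG", "CHG", "CHH"}


def site_key(chrom: str, pos: int) -> str:
    """Canonical string key for a CpG site (1-based position)."""
    return f"{chrom}:{int(pos)}"


def parse_site_key(key: str) -> tuple[str, int]:
    chrom, _, pos = key.rpartition(":")
    return chrom, int(pos)


def sort_site_keys(keys: Iterable[str]) -> list[str]:
    """Total order on site keys: chromosome lexicographic, then position."""
    return sorted(keys, key=parse_site_key)


@dataclass(frozen=True)
class CoverageFilterConfig:
    """Site-retention rule: depth >= ``min_depth`` in at least
    ``min_sample_fraction`` of the samples (defaults 5 reads, 90%)."""

    min_depth: int = 5
    min_sample_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError(f"min_depth must be >= 1, got {self.min_depth}")
        if not 0.0 < self.min_sample_fraction <= 1.0:
            raise ValueError(
                f"min_sample_fraction must be in (0, 1], got {self.min_sample_fraction}"
            )


# ---------------------------------------------------------------------------
# Parsers / writers
# ---------------------------------------------------------------------------

def read_bismark_cov(path: str | Path) -> pd.DataFrame:
    """Read a Bismark ``.cov`` file into a site table.

    Returns a DataFrame with columns ``chrom, pos, meth_frac, coverage``.
    The methylation fraction is recomputed exactly from the read counts
    (methylated / total); the percent column is validated against it within
    rounding.  Rows with zero total reads get a missing fraction.
    """
    path = Path(path)
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "percent", "n_meth", "n_unmeth"],
            dtype={"chrom": str},
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed Bismark coverage file {path}: {exc}") from exc

    for col in ("start", "n_meth", "n_unmeth", "percent"):
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            bad = int(np.flatnonzero(values.isna().to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad}")
        table[col] = values
    if (table[["n_meth", "n_unmeth"]] < 0).any().any():
        bad = int(np.flatnonzero((table[["n_meth", "n_unmeth"]] < 0).any(axis=1))[0]) + 1
        raise ValueError(f"{path}: negative read count at line {bad}")

    coverage = (table["n_meth"] + table["n_unmeth"]).astype(int)
    with np.errstate(invalid="ignore"):
        frac = np.where(coverage > 0, table["n_meth"] / coverage.replace(0, 1), np.nan)
    # Percent column must be consistent with the counts, allowing for the
    # precision it was printed at.
    ok = coverage == 0
    ok |= (table["percent"] / 100.0 - frac).abs() <= 0.005 + 1e-9
    if not ok.all():
        bad = int(np.flatnonzero(~ok.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: methylation percent inconsistent with read counts at line {bad}"
        )
    return pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["start"].astype(int),
            "meth_frac": frac,
            "coverage": coverage,
        }
    )


def write_bismark_cov(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a site table in Bismark coverage format (inverse of the reader)."""
    path = Path(path)
    cov = table["coverage"].to_numpy()
    frac = table["meth_frac"].to_numpy(dtype=float)
    n_meth = np.where(cov > 0, np.rint(np.nan_to_num(frac) * cov), 0).astype(int)
    n_unmeth = cov - n_meth
    percent = np.where(cov > 0, 100.0 * n_meth / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "start": table["pos"].astype(int),
            "end": table["pos"].astype(int),
            "percent": percent,
            "n_meth": n_meth,
            "n_unmeth": n_unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    return path


def read_cgmap(path: str | Path) -> pd.DataFrame:
    """Read a CGmap file, keeping CpG-context rows only.

    The methylation fraction is taken from the methylation-level column and
    coverage from the total-count column.  Rows whose context code is not a
    known bisulfite context (CG/CHG/CHH) are skipped and counted in a log
    message rather than raising.
    """
    path = Path(path)
    names = ["chrom", "nuc", "pos", "context", "dinuc", "level", "n_meth", "n_total"]
    try:
        table = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed CGmap file {path}: {exc}") from exc

    for col in ("pos", "level", "n_total"):
        values = pd.to_numeric(table[col], errors="coerce")
        if values.isna().any():
            bad = int(np.flatnonzero(values.isna().to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {bad}")
        table[col] = values

    unknown = ~table["context"].isin(_CGMAP_KNOWN_CONTEXTS)
    if unknown.any():
        logger.warning("%s: skipped %d rows with unknown context codes", path, int(unknown.sum()))
    cg = table[~unknown & (table["context"] == "CG")]
    return pd.DataFrame(
        {
            "chrom": cg["chrom"].to_numpy(),
            "pos": cg["pos"].astype(int).to_numpy(),
            "meth_frac": cg["level"].astype(float).to_numpy(),
            "coverage": cg["n_total"].astype(int).to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Matrix assembly and filtering
# ---------------------------------------------------------------------------

def assemble_matrix(
    tables: Mapping[str, pd.DataFrame],
    sample_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble per-sample site tables into aligned (methylation, coverage)
    matrices over the union of sites.

    ``tables`` maps sample id -> site table (see :data:`SITE_TABLE_COLUMNS`).
    If ``sample_table`` is given its ``sample_id`` column fixes the row order
    and must match the keys of ``tables``.  Sites absent from a sample are
    NaN in the methylation matrix and 0 in the coverage matrix.
    """
    if sample_table is not None:
        sample_ids = list(sample_table["sample_id"])
        if set(sample_ids) != set(tables):
            raise ValueError("sample sheet ids do not match the per-sample tables")
    else:
        sample_ids = list(tables)

    meth_cols: dict[str, pd.Series] = {}
    cov_cols: dict[str, pd.Series] = {}
    for sid in sample_ids:
        tab = tables[sid]
        keys = [site_key(c, p) for c, p in zip(tab["chrom"], tab["pos"])]
        if len(set(keys)) != len(keys):
            dup = pd.Series(keys).value_counts().idxmax()
            raise ValueError(f"sample {sid!r}: duplicate site {dup}")
        meth_cols[sid] = pd.Series(tab["meth_frac"].to_numpy(dtype=float), index=keys)
        cov_cols[sid] = pd.Series(tab["coverage"].to_numpy(dtype=float), index=keys)

    all_sites = sort_site_keys(set().union(*(s.index for s in meth_cols.values())) if meth_cols else set())
    meth = pd.DataFrame(index=sample_ids, columns=all_sites, dtype=float)
    cov = pd.DataFrame(0.0, index=sample_ids, columns=all_sites)
    for sid in sample_ids:
        meth.loc[sid, meth_cols[sid].index] = meth_cols[sid]
        cov.loc[sid, cov_cols[sid].index] = cov_cols[sid]
    return meth, cov.fillna(0).astype(int)


def _check_aligned(meth: pd.DataFrame, cov: pd.DataFrame) -> None:
    if not (meth.index.equals(cov.index) and meth.columns.equals(cov.columns)):
        raise ValueError("methylation and coverage matrices have mismatched axes")


def mask_low_coverage(
    meth: pd.DataFrame, cov: pd.DataFrame, min_depth: int = 5
) -> pd.DataFrame:
    """Set entries observed with fewer than ``min_depth`` reads to missing.

    Entries at exactly ``min_depth`` reads are retained ("at least five
    reads"); retained values are returned bit-identical.
    """
    _check_aligned(meth, cov)
    return meth.where(cov.to_numpy() >= min_depth)


def filter_by_coverage(
    meth: pd.DataFrame,
    cov: pd.DataFrame,
    config: CoverageFilterConfig = CoverageFilterConfig(),
) -> pd.DataFrame:
    """Keep sites deep enough in a large-enough fraction of samples.

    A site is retained when the fraction of samples with coverage >=
    ``config.min_depth`` is at least ``config.min_sample_fraction``.
    Column order is preserved; the operation is idempotent.
    """
    _check_aligned(meth, cov)
    n = len(meth.index)
    if n == 0:
        raise ValueError("cannot filter a matrix with zero samples")
    deep = (cov.to_numpy() >= config.min_depth).sum(axis=0)
    keep = deep / n >= config.min_sample_fraction
    return meth.loc[:, meth.columns[keep]]


def intersect_common_sites(*matrices: pd.DataFrame) -> list[str]:
    """Sorted intersection of site keys across two or more matrices."""
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].columns)
    for m in matrices[1:]:
        common &= set(m.columns)
    return sort_site_keys(common)


def mean_impute(meth: pd.DataFrame) -> pd.DataFrame:
    """Fill missing entries with the per-site mean over covered samples.

    Sites with no observation at all are dropped (they carry no information
    for model training).
    """
    observed = meth.dropna(axis=1, how="all")
    return observed.fillna(observed.mean(axis=0))


# ---------------------------------------------------------------------------
# TSV serialization of matrices and sample sheets
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    return path


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")


def write_sample_sheet(sample_table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sample_table.to_csv(path, sep="\t", index=False)
    return path


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if table["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if "age_months" in table.columns and (table["age_months"] <= 0).any():
        raise ValueError(f"{path}: ages must be positive")
    return table
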