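"""Promoter-level differential methylation analysis.

A gene's promoter is the window [-upstream, +downstream] bp around its
transcription start site (TSS), following the direction of transcription
(defaults 1500 bp upstream, 500 bp downstream; both bounds inclusive, so the
window spans 2001 bp unless clipped at position 1).  The TSS is taken from
the GTF gene feature: the feature start on the + strand, the feature end on
the - strand.

For every (gene, sample) pair the promoter methylation is the mean of the
sample's observed CpG methylation fractions inside the window; genes whose
promoter contains no matrix CpG are excluded.  Two-group differential
analysis uses a two-sided Welch t-test per gene, Bonferroni correction over
the genes actually tested in that organ, best-hit ranking by uncorrected p,
and cross-organ intersection of significant genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation_io import parse_site_key

logger = logging.getLogger("methaging")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its genomic span; ``tss`` honours the strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r} for gene {self.gene_id}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span for gene {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PromoterWindow:
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 1:
            raise ValueError("invalid promoter window bounds")


@dataclass
class PromoterMethylation:
    """Gene x sample mean promoter methylation plus per-gene CpG counts."""

    values: pd.DataFrame  # genes x samples, fractions or NaN
    n_cpg: pd.Series  # per-gene count of matrix CpGs in the window


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def parse_gtf(path: str | Path) -> list[GeneRecord]:
    """Parse the gene features of a GTF file into :class:`GeneRecord`s.

    Coordinates are 1-based closed intervals as in the format.  Records are
    returned in a deterministic order (chrom, start, gene_id).
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feature = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises plain Exception subclasses
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feature.featuretype != "gene":
                continue
            if feature.strand not in {"+", "-"}:
                raise ValueError(f"{path}: line {lineno}: unknown strand {feature.strand!r}")
            try:
                gene_id = feature.attributes["gene_id"][0]
            except (KeyError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: missing gene_id attribute") from exc
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=feature.seqid,
                    strand=feature.strand,
                    start=feature.start,
                    end=feature.end,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.gene_id))
    return records


def promoter_window(
    record: GeneRecord, upstream: int = 1500, downstream: int = 500
) -> PromoterWindow:
    """Strand-aware promoter window around the TSS, clipped at position 1."""
    if record.strand == "+":
        start, end = record.tss - upstream, record.tss + downstream
    else:
        start, end = record.tss - downstream, record.tss + upstream
    return PromoterWindow(chrom=record.chrom, start=max(1, start), end=end)


def promoter_mean(matrix: pd.DataFrame, window: PromoterWindow, sample: str) -> float:
    """Mean observed methylation of one sample's CpGs inside a window.

    Returns NaN (not an error) when no CpG in the window is observed.
    """
    cols = [
        key
        for key in matrix.columns
        if (lambda ck: ck[0] == window.chrom and window.start <= ck[1] <= window.end)(
            parse_site_key(key)
        )
    ]
    if not cols:
        return float("nan")
    return float(matrix.loc[sample, cols].mean())


def promoter_methylation(
    matrix: pd.DataFrame,
    records: Sequence[GeneRecord],
    upstream: int = 1500,
    downstream: int = 500,
) -> PromoterMethylation:
    """Per-gene per-sample mean promoter methylation over a whole cohort.

    Genes with no matrix CpG in their promoter are excluded (their count
    would be zero).  Uses a sorted position index per chromosome, so it
    scales to large matrices; equivalent to a brute-force window scan.
    """
    site_keys = list(matrix.columns)
    parsed = [parse_site_key(k) for k in site_keys]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = np.array([c for c, _ in parsed])
    positions = np.array([p for _, p in parsed], dtype=int)
    order_all = np.arange(len(site_keys))
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        pos = positions[mask]
        idx = order_all[mask]
        order = np.argsort(pos)
        by_chrom[chrom] = (pos[order], idx[order])

    values = matrix.to_numpy(dtype=float)
    rows, counts, gene_ids = [], [], []
    for record in records:
        window = promoter_window(record, upstream, downstream)
        if window.chrom not in by_chrom:
            continue
        pos, idx = by_chrom[window.chrom]
        lo = np.searchsorted(pos, window.start, side="left")
        hi = np.searchsorted(pos, window.end, side="right")
        if hi <= lo:
            continue
        cols = idx[lo:hi]
        window_values = values[:, cols]
        observed = (~np.isnan(window_values)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            sums = np.nansum(window_values, axis=1)
        means = np.where(observed > 0, sums / np.maximum(observed, 1), np.nan)
        gene_ids.append(record.gene_id)
        counts.append(hi - lo)
        rows.append(means)
    if gene_ids:
        table = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=matrix.index)
    else:
        table = pd.DataFrame(columns=matrix.index)
    return PromoterMethylation(values=table, n_cpg=pd.Series(counts, index=gene_ids, dtype=int))


# ---------------------------------------------------------------------------
# Differential testing
# ---------------------------------------------------------------------------

def test_gene(values: pd.Series, groups: pd.Series) -> tuple[float, str, dict[str, float]]:
    """Welch t-test of one gene's promoter means between two groups.

    Returns ``(p, direction, means)`` where direction is "hyper" when the
    HCR mean exceeds the LCR mean and "hypo" otherwise (generically: the
    second group label relative to the first, in sorted label order).
    """
    labels = sorted(pd.unique(groups.dropna()))
    if len(labels) != 2:
        raise ValueError("test_gene requires exactly two groups")
    first, second = labels  # e.g. HCR, LCR -> direction of HCR vs LCR
    a = values[groups == first].dropna().to_numpy(dtype=float)
    b = values[groups == second].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("insufficient non-missing promoter values")
    if np.array_equal(a, b):
        p = 1.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=False)
    means = {first: float(a.mean()), second: float(b.mean())}
    direction = "hyper" if means[first] > means[second] else "hypo"
    return float(p), direction, means


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * n)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of range: {p}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_promoter_analysis(
    promoters: PromoterMethylation,
    sample_table: pd.DataFrame,
    organ: str | None = None,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-gene two-group test over an organ's samples.

    A gene is testable when both groups have at least ``min_per_group``
    non-missing promoter means; Bonferroni's G is the number of genes
    actually tested.  Returns a DataFrame indexed by gene_id with columns
    p, p_bonf, direction, the group means, n_cpg and n_genes_tested.
    """
    samples = sample_table
    if organ is not None:
        samples = samples[samples["organ"] == organ]
    sample_ids = [s for s in samples["sample_id"] if s in promoters.values.columns]
    if not sample_ids:
        raise ValueError("no overlapping samples between promoter table and sample sheet")
    groups = pd.Series(samples.set_index("sample_id").loc[sample_ids, "group"])
    labels = sorted(pd.unique(groups.dropna()))
    if len(labels) != 2:
        raise ValueError("differential analysis requires exactly two groups")

    sub = promoters.values[sample_ids]
    rows = []
    skipped = 0
    for gene_id, values in sub.iterrows():
        counts = values.groupby(groups).count()
        if (counts.reindex(labels).fillna(0) < min_per_group).any():
            skipped += 1
            continue
        p, direction, means = test_gene(values, groups)
        rows.append(
            {
                "gene_id": gene_id,
                "organ": organ,
                "p": p,
                "direction": direction,
                f"mean_{labels[0]}": means[labels[0]],
                f"mean_{labels[1]}": means[labels[1]],
                "n_cpg": int(promoters.n_cpg[gene_id]),
            }
        )
    if skipped:
        logger.info("differential analysis (%s): skipped %d genes with too few values", organ, skipped)
    if not rows:
        raise ValueError("no testable genes")
    result = pd.DataFrame(rows).set_index("gene_id").sort_index()
    g = len(result)
    result["n_genes_tested"] = g
    result["p_bonf"] = np.minimum(1.0, result["p"] * g)
    return result


def best_hits(results: pd.DataFrame, k: int = 6) -> pd.DataFrame:
    """The k genes with the smallest uncorrected p (ties: gene_id order)."""
    if results.empty:
        raise ValueError("empty results table")
    if k > len(results):
        logger.info("best_hits: k=%d exceeds %d tested genes; returning all", k, len(results))
        k = len(results)
    ordered = results.reset_index().sort_values(["p", "gene_id"], kind="mergesort")
    return ordered.head(k).set_index("gene_id")


def common_significant_genes(
    per_organ: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """Genes significant (p strictly below alpha) in every organ.

    Returns one row per common gene with per-organ p-values and directions
    and a ``direction_consistent`` flag (consistency is reported, not
    required).
    """
    if len(per_organ) < 2:
        raise ValueError("need results for at least two organs")
    universes = [set(res.index) for res in per_organ.values()]
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("empty shared gene universe across organs")
    rows = []
    for gene in sorted(shared):
        ps = {organ: float(res.loc[gene, "p"]) for organ, res in per_organ.items()}
        if not all(p < alpha for p in ps.values()):
            continue
        directions = {organ: str(res.loc[gene, "direction"]) for organ, res in per_organ.items()}
        row = {"gene_id": gene, "direction_consistent": len(set(directions.values())) == 1}
        for organ in per_organ:
            row[f"p_{organ}"] = ps[organ]
            row[f"direction_{organ}"] = directions[organ]
        rows.append(row)
    columns = ["gene_id", "direction_consistent"] + [
        f"{prefix}_{organ}" for organ in per_organ for prefix in ("p", "direction")
    ]
    return pd.DataFrame(rows, columns=columns).set_index("gene_id")
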