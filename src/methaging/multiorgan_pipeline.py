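"""Cross-organ comparisons and end-to-end orchestration.

Given per-individual metrics measured in several organs (epigenetic age,
age acceleration, GMM, MME), this module runs paired t-tests for every
organ pair (within-individual differences), Pearson correlations of age
acceleration across organs, and the full simulate -> filter -> clocks ->
global stats -> promoter analysis -> multi-organ comparison pipeline with
TSV reporting.

Multiple testing across the six organ pairs: raw p-values are reported
with significance stars, and a Benjamini-Hochberg-adjusted column is
emitted alongside for transparency.  Pairs whose within-individual
differences have zero variance carry a ``degenerate`` flag instead of a
p-value (the t statistic is undefined there).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clock_core, global_stats, intersection_clock, promoter_analysis, rdna_clock
from .methylation_io import (
    CoverageFilterConfig,
    assemble_matrix,
    filter_by_coverage,
    intersect_common_sites,
    mask_low_coverage,
    mean_impute,
    read_bismark_cov,
    read_sample_sheet,
    write_matrix_tsv,
)
from .synthetic_data import (
    MultiOrganDesign,
    SimulationConfig,
    make_gene_records,
    simulate_multiorgan_cohort,
    simulate_training_cohort,
)

logger = logging.getLogger("methaging")


def paired_organ_compare(metric_table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Paired t-tests between all organ pairs of an individual x organ table.

    Each row: organ pair, number of complete pairs, mean within-individual
    difference (B - A), t statistic, two-sided p, stars, BH-adjusted p and a
    degenerate flag for zero-variance differences.
    """
    organs = list(metric_table.columns)
    rows = []
    for a, b in itertools.combinations(organs, 2):
        paired = metric_table[[a, b]].dropna()
        if len(paired) < 2:
            raise ValueError(f"fewer than two complete pairs for {a} vs {b}")
        diff = paired[b].to_numpy() - paired[a].to_numpy()
        row = {
            "metric": metric,
            "organ_a": a,
            "organ_b": b,
            "n_pairs": len(paired),
            "mean_difference": float(diff.mean()),
        }
        if np.ptp(diff) == 0:
            row.update({"t": np.nan, "p": np.nan, "stars": "", "degenerate": True})
        else:
            t, p = stats.ttest_rel(paired[b], paired[a])
            row.update(
                {"t": float(t), "p": float(p), "stars": global_stats.stars(float(p)), "degenerate": False}
            )
        rows.append(row)
    result = pd.DataFrame(rows)
    defined = result["p"].notna()
    result["p_bh"] = np.nan
    if defined.any():
        result.loc[defined, "p_bh"] = promoter_analysis.benjamini_hochberg(
            result.loc[defined, "p"].to_list()
        )
    return result


def acceleration_cross_correlation(accel_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of age acceleration between organ pairs.

    ``accel_table`` is individuals x organs.  A consistent, body-wide aging
    rate would show positive correlations; organ-local aging shows none.
    """
    organs = list(accel_table.columns)
    rows = []
    for a, b in itertools.combinations(organs, 2):
        paired = accel_table[[a, b]].dropna()
        if len(paired) < 3:
            raise ValueError(f"fewer than three complete pairs for {a} vs {b}")
        x = paired[a].to_numpy(dtype=float)
        y = paired[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"constant acceleration column in pair {a} vs {b}")
        res = stats.pearsonr(x, y)
        rows.append(
            {
                "organ_a": a,
                "organ_b": b,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "n": len(paired),
                "stars": global_stats.stars(float(res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one input mode is active: simulation (``simulation`` /
    ``design`` set) or real files (``cov_dir``, ``sample_sheet``, ``gtf``).
    """

    outdir: str | Path = "methaging_out"
    seed: int = 0
    # simulation mode
    simulation: SimulationConfig | None = None
    application: SimulationConfig | None = None
    design: MultiOrganDesign | None = None
    n_genes: int = 40
    # real-input mode
    cov_dir: str | Path | None = None
    sample_sheet: str | Path | None = None
    gtf: str | Path | None = None
    # shared settings
    filter: CoverageFilterConfig = field(default_factory=CoverageFilterConfig)
    clock: clock_core.ClockTrainingConfig = field(default_factory=clock_core.ClockTrainingConfig)
    run_intersection_clock: bool = True
    run_rdna_clock: bool = True
    promoter_alpha: float = 0.05
    best_hit_k: int = 6

    def __post_init__(self) -> None:
        simulated = self.simulation is not None
        real = self.cov_dir is not None
        if simulated == real:
            raise ValueError("exactly one of simulation or real inputs must be configured")


@dataclass
class PipelineReport:
    """All tables produced by a run, plus where they were written."""

    tables: dict[str, pd.DataFrame]
    outdir: Path


def _load_real_inputs(config: PipelineConfig):
    samples = read_sample_sheet(config.sample_sheet)
    tables = {
        sid: read_bismark_cov(Path(config.cov_dir) / f"{sid}.cov")
        for sid in samples["sample_id"]
    }
    meth, cov = assemble_matrix(tables, samples)
    records = promoter_analysis.parse_gtf(config.gtf) if config.gtf else []
    return meth, cov, samples, records


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write TSV reports.

    Stages: load or simulate -> depth masking -> coverage filtering -> clock
    training (fixed-site, common-site, intersection, rDNA) -> prediction and
    age acceleration per organ sample -> GMM/MME with group comparisons ->
    per-organ promoter differential analysis with best hits and cross-organ
    common genes -> paired multi-organ comparisons -> cross-organ
    acceleration correlations.  Reruns with the same config are
    deterministic.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # ------------------------------------------------------------------ load
    stage("load")
    if config.simulation is not None:
        sim = replace(config.simulation, seed=config.seed)
        train_cohort = simulate_training_cohort(sim, chrom="chrT")
        records = make_gene_records(config.n_genes, seed=config.seed)
        design = config.design or MultiOrganDesign()
        app_config = config.application or replace(
            sim, n_samples=2 * design.n_per_group, age_range=(23.5, 27.0), seed=config.seed
        )
        app_cohort = simulate_multiorgan_cohort(
            app_config, design, records, shared_truth=train_cohort.truth
        )
        app_meth_raw, app_cov = app_cohort.methylation, app_cohort.coverage
        app_samples = app_cohort.samples
        train_meth_raw, train_cov = train_cohort.methylation, train_cohort.coverage
        train_ages = train_cohort.truth.reference_ages
    else:
        app_meth_raw, app_cov, app_samples, records = _load_real_inputs(config)
        train_meth_raw = train_cov = None
        train_ages = None
        design = None

    # ------------------------------------------------- mask + filter + train
    stage("mask_and_filter")
    app_meth = mask_low_coverage(app_meth_raw, app_cov, config.filter.min_depth)
    clock_models: dict[str, clock_core.ClockModel] = {}
    predictions: dict[str, pd.Series] = {}
    accelerations: dict[str, pd.DataFrame] = {}

    if train_meth_raw is not None:
        train_meth = mask_low_coverage(train_meth_raw, train_cov, config.filter.min_depth)
        train_filtered = filter_by_coverage(train_meth, train_cov, config.filter)
        train_complete = mean_impute(train_filtered)

        stage("train_clock_fixed")
        clock_cfg = replace(config.clock, seed=config.seed)
        clock_models["clock1"] = clock_core.train_elastic_net_clock(
            train_complete, train_ages, clock_cfg
        )
        stage("train_clock_common_sites")
        common = intersect_common_sites(train_complete, app_meth)
        if common:
            clock_models["clock2"] = clock_core.train_elastic_net_clock(
                train_complete[common], train_ages, clock_cfg
            )

        stage("predict")
        for name, model in clock_models.items():
            predictions[name] = clock_core.predict_ages(app_meth, model)
            accelerations[name] = clock_core.age_acceleration(
                predictions[name],
                app_samples.set_index("sample_id")["age_months"],
                model.reference_regression,
            )

        if config.run_intersection_clock:
            stage("intersection_clock")
            result = intersection_clock.intersection_predict_cohort(
                train_complete, train_ages, app_meth, clock_cfg
            )
            tables["intersection_predictions"] = result.as_frame()
            inter_pred = result.as_frame()["mean_pred"]
            predictions["intersection"] = inter_pred
            chron = app_samples.set_index("sample_id").loc[inter_pred.index, "age_months"]
            fit = stats.linregress(chron.to_numpy(), inter_pred.to_numpy())
            accelerations["intersection"] = clock_core.age_acceleration(
                inter_pred, chron, (float(fit.slope), float(fit.intercept))
            )

        if config.run_rdna_clock:
            stage("rdna_clock")
            rdna_cfg = replace(
                sim, n_sites=200, frac_age_associated=0.15, coverage_mean=200.0,
                low_coverage_rate=0.15, seed=config.seed + 7,
            )
            rdna_cohort = simulate_training_cohort(rdna_cfg, chrom="rDNA")
            rdna_table = 100.0 * mask_low_coverage(
                rdna_cohort.methylation, rdna_cohort.coverage, config.filter.min_depth
            )
            rdna_table = rdna_table.dropna(axis=1, how="all")
            grid = rdna_clock.run_model_grid(
                rdna_table, rdna_cohort.truth.reference_ages, replace(config.clock, seed=config.seed)
            )
            tables["rdna_grid"] = grid
            tables["rdna_best"] = pd.DataFrame([rdna_clock.select_best(grid)])

    # ----------------------------------------------------------- global stats
    stage("global_stats")
    gstats = global_stats.cohort_global_stats(app_meth)
    gstats = gstats.join(app_samples.set_index("sample_id")[["organ", "group", "age_months"]])
    tables["global_stats"] = gstats
    comparisons = []
    for organ, sub in gstats.groupby("organ"):
        if sub["group"].nunique() == 2:
            for metric in ("gmm", "mme"):
                cmp_res = global_stats.group_compare(sub[metric], sub["group"], metric=metric)
                comparisons.append(
                    {
                        "organ": organ,
                        "metric": metric,
                        "statistic": cmp_res.statistic,
                        "p": cmp_res.p,
                        "direction": cmp_res.direction,
                        "stars": cmp_res.stars,
                    }
                )
    tables["group_comparisons"] = pd.DataFrame(comparisons)

    # -------------------------------------------------------------- promoters
    stage("promoters")
    per_organ_results: dict[str, pd.DataFrame] = {}
    if records:
        promoters = promoter_analysis.promoter_methylation(app_meth, records)
        best_rows = []
        for organ in sorted(app_samples["organ"].unique()):
            try:
                res = promoter_analysis.differential_promoter_analysis(
                    promoters, app_samples, organ
                )
            except ValueError:
                continue
            per_organ_results[organ] = res
            hits = promoter_analysis.best_hits(res, config.best_hit_k).reset_index()
            best_rows.append(hits)
        if per_organ_results:
            tables["promoter_results"] = pd.concat(
                [r.assign(organ=o).reset_index() for o, r in per_organ_results.items()],
                ignore_index=True,
            )
            tables["best_hits"] = pd.concat(best_rows, ignore_index=True)
        if len(per_organ_results) >= 2:
            tables["common_genes"] = promoter_analysis.common_significant_genes(
                per_organ_results, config.promoter_alpha
            ).reset_index()

    # ------------------------------------------------------------ multi-organ
    stage("multiorgan")
    sample_info = app_samples.set_index("sample_id")
    metric_tables: dict[str, pd.DataFrame] = {}
    if "individual_id" in sample_info.columns:
        ginfo = gstats.join(sample_info[["individual_id"]])
        for metric in ("gmm", "mme"):
            metric_tables[metric] = ginfo.pivot_table(
                index="individual_id", columns="organ", values=metric
            )
    for name, pred in predictions.items():
        wide = pd.DataFrame(
            {
                "individual_id": sample_info.loc[pred.index, "individual_id"].to_numpy(),
                "organ": sample_info.loc[pred.index, "organ"].to_numpy(),
                "value": pred.to_numpy(),
            }
        ).pivot(index="individual_id", columns="organ", values="value")
        metric_tables[f"age_{name}"] = wide
    accel_tables = {}
    for name, acc in accelerations.items():
        wide = pd.DataFrame(
            {
                "individual_id": sample_info.loc[acc.index, "individual_id"].to_numpy(),
                "organ": sample_info.loc[acc.index, "organ"].to_numpy(),
                "value": acc["acceleration"].to_numpy(),
            }
        ).pivot(index="individual_id", columns="organ", values="value")
        metric_tables[f"acceleration_{name}"] = wide
        accel_tables[name] = wide
    if any(table.shape[1] >= 2 for table in metric_tables.values()):
        tables["paired_comparisons"] = pd.concat(
            [
                paired_organ_compare(table, metric)
                for metric, table in metric_tables.items()
                if table.shape[1] >= 2 and table.dropna().shape[0] >= 2
            ],
            ignore_index=True,
        )
    cross_rows = []
    for name, table in accel_tables.items():
        if table.shape[1] >= 2 and table.dropna().shape[0] >= 3:
            cc = acceleration_cross_correlation(table)
            cc.insert(0, "clock", name)
            cross_rows.append(cc)
    if cross_rows:
        tables["cross_organ_correlations"] = pd.concat(cross_rows, ignore_index=True)

    # ----------------------------------------------------------------- report
    stage("write_report")
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=table.index.name is not None)
    write_matrix_tsv(app_meth, outdir / "methylation_matrix.tsv")
    echo = {
        "seed": config.seed,
        "filter": {"min_depth": config.filter.min_depth,
                   "min_sample_fraction": config.filter.min_sample_fraction},
        "clock": {"mixing": config.clock.mixing, "cv_folds": config.clock.cv_folds,
                  "train_fraction": config.clock.train_fraction},
        "mode": "simulation" if config.simulation is not None else "files",
    }
    (outdir / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
    return PipelineReport(tables=tables, outdir=outdir)
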