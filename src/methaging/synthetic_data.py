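"""Synthetic methylome cohorts with known ground truth.

Two kinds of cohorts are generated, emulating the structure of a
multi-organ RRBS aging study:

* a **blood-like training cohort** — samples spanning a months-scale age
  range, with a minority of CpG sites drifting linearly with age
  (``expected methylation = clamp(baseline + slope * age, 0, 1)``) and an
  optional global *entropy drift* that shrinks every site's distance from
  0.5 proportionally to age (so mean methylation entropy rises, and global
  mean methylation falls whenever the site average sits above 0.5);
* a **multi-organ application cohort** — a two-group (LCR/HCR) design with
  four organs per individual, per-organ offsets to global methylation and
  to apparent age, and promoter-level group effects injected at known genes.

Observation model: the true methylation of a (sample, site) pair gets
per-observation Gaussian biological noise, read coverage is drawn from an
overdispersed negative binomial (with a configurable fraction of entries
forced below the 5-read censoring threshold), and the observed fraction is
``methylated_reads / coverage`` with methylated reads binomial.  Entries
with zero coverage are missing; entries under the depth threshold are kept
in the output (masking them is a downstream decision).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation_io import site_key, sort_site_keys, write_bismark_cov
from .promoter_analysis import GeneRecord, promoter_window

DEFAULT_ORGANS = ("hippocampus", "heart", "soleus", "large_intestine")
DEFAULT_GROUPS = ("LCR", "HCR")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror a blood training set of 134 samples spanning a rat
    lifespan (1-27 months), 5,000 CpG sites of which 4% (200) drift with
    age at ~0.01 methylation-fraction per month, biological noise sd 0.05,
    mean read coverage 30 with negative-binomial overdispersion, and 5% of
    entries censored below the 5-read threshold.  ``baseline_shape`` are
    Beta parameters for per-site baseline methylation (the default is
    bimodal with mean 2/3, like a real methylome).  ``entropy_drift`` is the
    per-month shrinkage rate of |m - 0.5| (0 disables it).
    """

    n_samples: int = 134
    age_range: tuple[float, float] = (1.0, 27.0)
    n_sites: int = 5000
    frac_age_associated: float = 0.04
    slope_scale: float = 0.01
    baseline_shape: tuple[float, float] = (0.4, 0.2)
    noise_sd: float = 0.05
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    low_coverage_rate: float = 0.05
    entropy_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            self.n_samples >= 2,
            self.n_sites >= 1,
            0.0 <= self.frac_age_associated <= 1.0,
            self.age_range[0] < self.age_range[1],
            self.age_range[0] > 0,
            self.coverage_mean > 0,
            self.coverage_dispersion > 0,
            self.noise_sd >= 0,
            0.0 <= self.low_coverage_rate <= 1.0,
            self.entropy_drift >= 0,
            self.baseline_shape[0] > 0 and self.baseline_shape[1] > 0,
            all(math.isfinite(v) for v in (*self.age_range, self.slope_scale, self.noise_sd,
                                           self.coverage_mean, self.low_coverage_rate,
                                           self.entropy_drift)),
        ]
        if not all(checks):
            raise ValueError("invalid simulation configuration")


@dataclass(frozen=True)
class MultiOrganDesign:
    """Design of the two-group, four-organ application cohort.

    ``organ_offsets`` maps organ -> (gmm_shift, accel_months): an additive
    shift applied to all of that organ's methylation values and an apparent
    age offset applied through the age-associated sites.  ``affected_genes``
    maps organ -> [(gene_id, signed effect)]; ``common_affected_genes`` maps
    gene_id -> signed effect applied in every organ.  Effects are additive
    methylation-fraction shifts on the promoter CpGs of the second group
    (HCR); negative means hypomethylated in HCR.
    """

    organs: tuple[str, ...] = DEFAULT_ORGANS
    groups: tuple[str, str] = DEFAULT_GROUPS
    n_per_group: int = 8
    organ_offsets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    affected_genes: Mapping[str, Sequence[tuple[str, float]]] = field(default_factory=dict)
    common_affected_genes: Mapping[str, float] = field(default_factory=dict)
    cpg_per_promoter: int = 8

    def __post_init__(self) -> None:
        if len(set(self.organs)) != len(self.organs):
            raise ValueError("organ labels must be unique")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("exactly two distinct group labels required")
        if self.n_per_group < 1 or self.cpg_per_promoter < 1:
            raise ValueError("n_per_group and cpg_per_promoter must be >= 1")
        effects = [e for genes in self.affected_genes.values() for _, e in genes]
        effects += list(self.common_affected_genes.values())
        if any(not -1.0 < e < 1.0 for e in effects):
            raise ValueError("promoter effect sizes must lie in (-1, 1)")
        for organ in self.affected_genes:
            if organ not in self.organs:
                raise ValueError(f"affected_genes references unknown organ {organ!r}")

    def effect_table(self) -> pd.DataFrame:
        """All injected (organ, gene, effect) rows, common genes included."""
        rows = []
        for organ in self.organs:
            for gene_id, effect in self.affected_genes.get(organ, ()):  # organ-specific
                rows.append({"organ": organ, "gene_id": gene_id, "effect": effect})
            for gene_id, effect in self.common_affected_genes.items():
                rows.append({"organ": organ, "gene_id": gene_id, "effect": effect})
        table = pd.DataFrame(rows, columns=["organ", "gene_id", "effect"])
        table["direction"] = np.where(table["effect"] < 0, "hypo", "hyper")
        return table


@dataclass
class GroundTruth:
    """Simulator record used by recovery tests."""

    site_baselines: pd.Series  # per site key, at age 0 (intercept of the trend)
    site_slopes: pd.Series  # methylation-fraction per month; nonzero only for age sites
    reference_ages: pd.Series  # months per sample
    affected_gene_table: pd.DataFrame  # organ, gene_id, effect, direction

    @property
    def age_site_ids(self) -> list[str]:
        return list(self.site_slopes.index[self.site_slopes != 0])


@dataclass
class SimulatedCohort:
    methylation: pd.DataFrame  # samples x sites, observed fractions, NaN missing
    coverage: pd.DataFrame  # samples x sites, integer read counts
    samples: pd.DataFrame  # sample_id, age_months, group, organ, individual_id
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

def _true_methylation(
    baselines: np.ndarray, slopes: np.ndarray, ages: np.ndarray, drift: float
) -> np.ndarray:
    """Expected methylation per (sample, site): clamp(baseline + slope*age),
    then entropy drift shrinks |m - 0.5| by a factor (1 - drift*age)."""
    m = np.clip(baselines[None, :] + slopes[None, :] * ages[:, None], 0.0, 1.0)
    if drift > 0:
        shrink = np.clip(1.0 - drift * ages, 0.0, 1.0)[:, None]
        m = 0.5 + (m - 0.5) * shrink
    return m


def _observe(m_true: np.ndarray, config: SimulationConfig, rng: np.random.Generator):
    """Apply biological noise, coverage draw, censoring and binomial reads."""
    noisy = m_true
    if config.noise_sd > 0:
        noisy = np.clip(m_true + rng.normal(0.0, config.noise_sd, m_true.shape), 0.0, 1.0)
    r = config.coverage_dispersion
    p = r / (r + config.coverage_mean)
    coverage = rng.negative_binomial(r, p, m_true.shape)
    if config.low_coverage_rate > 0:
        low = rng.random(m_true.shape) < config.low_coverage_rate
        coverage = np.where(low, rng.integers(0, 5, m_true.shape), coverage)
    meth_reads = rng.binomial(coverage, noisy)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(coverage > 0, meth_reads / np.maximum(coverage, 1), np.nan)
    return observed, coverage


def _draw_age_site_parameters(
    rng: np.random.Generator, n_age: int, slope_scale: float, age_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Slopes with magnitude Uniform(0.5, 1.5)*scale and random sign;
    baselines chosen so the linear trend stays inside [0, 1] over the age
    range (the clamp in the observation model then never bites)."""
    magnitude = rng.uniform(0.5, 1.5, n_age) * slope_scale
    sign = rng.choice([-1.0, 1.0], n_age)
    slopes = magnitude * sign
    mid = 0.5 * (age_range[0] + age_range[1])
    half_span = 0.5 * (age_range[1] - age_range[0])
    centers = rng.uniform(0.2, 0.8, n_age)
    # keep center +/- slope*half_span within (0.02, 0.98) where possible
    reach = np.minimum(np.abs(slopes) * half_span, 0.47)
    centers = np.clip(centers, 0.02 + reach, 0.98 - reach)
    baselines = centers - slopes * mid
    return baselines, slopes


# ---------------------------------------------------------------------------
# Training cohort
# ---------------------------------------------------------------------------

def simulate_training_cohort(
    config: SimulationConfig,
    baselines: np.ndarray | None = None,
    slopes: np.ndarray | None = None,
    chrom: str = "chr1",
    site_keys: Sequence[str] | None = None,
) -> SimulatedCohort:
    """Simulate a blood-like training cohort.

    Ages are uniform over ``config.age_range``.  Site baselines come from
    the configured Beta distribution except for the age-associated minority,
    whose baseline/slope pairs keep the trend inside the unit interval.
    Explicit ``baselines``/``slopes`` arrays (length ``n_sites``) and/or
    ``site_keys`` override the random draw, which lets tests pin site
    trajectories and simulate further cohorts over the same site set.
    """
    rng = np.random.default_rng(config.seed)
    ages = rng.uniform(config.age_range[0], config.age_range[1], config.n_samples)
    if site_keys is None:
        positions = np.cumsum(rng.integers(50, 150, config.n_sites)) + 1000
        keys = [site_key(chrom, int(p)) for p in positions]
    else:
        keys = list(site_keys)
        if len(keys) != config.n_sites:
            raise ValueError("site_keys must have length n_sites")

    if baselines is None or slopes is None:
        drawn_baselines = rng.beta(*config.baseline_shape, config.n_sites)
        drawn_slopes = np.zeros(config.n_sites)
        n_age = int(round(config.frac_age_associated * config.n_sites))
        if n_age > 0:
            age_idx = rng.choice(config.n_sites, n_age, replace=False)
            b, s = _draw_age_site_parameters(rng, n_age, config.slope_scale, config.age_range)
            drawn_baselines[age_idx] = b
            drawn_slopes[age_idx] = s
        baselines = drawn_baselines if baselines is None else np.asarray(baselines, float)
        slopes = drawn_slopes if slopes is None else np.asarray(slopes, float)
    else:
        baselines = np.asarray(baselines, dtype=float)
        slopes = np.asarray(slopes, dtype=float)
    if len(baselines) != config.n_sites or len(slopes) != config.n_sites:
        raise ValueError("baselines/slopes must have length n_sites")

    m_true = _true_methylation(baselines, slopes, ages, config.entropy_drift)
    observed, coverage = _observe(m_true, config, rng)

    sample_ids = [f"blood{i + 1:03d}" for i in range(config.n_samples)]
    methylation = pd.DataFrame(observed, index=sample_ids, columns=keys)
    cov = pd.DataFrame(coverage, index=sample_ids, columns=keys)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age_months": ages,
            "group": "other",
            "organ": "blood",
            "individual_id": sample_ids,
        }
    )
    truth = GroundTruth(
        site_baselines=pd.Series(baselines, index=keys),
        site_slopes=pd.Series(slopes, index=keys),
        reference_ages=pd.Series(ages, index=sample_ids),
        affected_gene_table=pd.DataFrame(columns=["organ", "gene_id", "effect", "direction"]),
    )
    return SimulatedCohort(methylation=methylation, coverage=cov, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# Multi-organ cohort
# ---------------------------------------------------------------------------

def simulate_multiorgan_cohort(
    config: SimulationConfig,
    design: MultiOrganDesign,
    annotation: Sequence[GeneRecord],
    shared_truth: GroundTruth | None = None,
) -> SimulatedCohort:
    """Simulate the two-group, four-organ application cohort.

    CpGs are placed inside each annotated gene's promoter window
    (``design.cpg_per_promoter`` per gene), plus background sites up to
    ``config.n_sites``.  When ``shared_truth`` (from a training cohort) is
    given, its sites — baselines, slopes and keys — are appended, so clocks
    trained on the training cohort can be applied to this one; per-organ
    apparent-age offsets act through those age-associated sites.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = {r.gene_id: r for r in annotation}
    effect_table = design.effect_table()
    unknown = set(effect_table["gene_id"]) - set(genes)
    if unknown:
        raise ValueError(f"affected genes absent from annotation: {sorted(unknown)}")

    # --- site layout -------------------------------------------------------
    keys: list[str] = []
    baselines: list[float] = []
    slopes: list[float] = []
    promoter_sites: dict[str, list[int]] = {}
    for record in annotation:
        window = promoter_window(record)
        span = window.end - window.start
        n_cpg = min(design.cpg_per_promoter, span + 1)
        offsets = np.sort(rng.choice(span + 1, n_cpg, replace=False))
        positions = (window.start + offsets).astype(int)
        start_idx = len(keys)
        for pos in positions:
            keys.append(site_key(window.chrom, int(pos)))
        promoter_sites[record.gene_id] = list(range(start_idx, start_idx + n_cpg))
        baselines.extend(rng.uniform(0.25, 0.75, n_cpg))
        slopes.extend([0.0] * n_cpg)
    n_background = max(0, config.n_sites - len(keys))
    if n_background:
        positions = np.cumsum(rng.integers(50, 150, n_background)) + 1000
        keys.extend(site_key("chrBG", int(p)) for p in positions)
        baselines.extend(rng.beta(*config.baseline_shape, n_background))
        slopes.extend([0.0] * n_background)
    n_own = len(keys)
    if shared_truth is not None:
        keys.extend(shared_truth.site_baselines.index)
        baselines.extend(shared_truth.site_baselines.to_numpy())
        slopes.extend(shared_truth.site_slopes.to_numpy())
    if len(set(keys)) != len(keys):
        raise ValueError(
            "site key collision between promoter/background and shared training sites; "
            "use distinct chromosome labels for the annotation and the training cohort"
        )
    baselines_arr = np.asarray(baselines)
    slopes_arr = np.asarray(slopes)

    # --- samples -----------------------------------------------------------
    n_individuals = 2 * design.n_per_group
    individual_ids = [
        f"{group}{i + 1:02d}" for group in design.groups for i in range(design.n_per_group)
    ]
    individual_groups = {
        ind: design.groups[0] if ind.startswith(design.groups[0]) else design.groups[1]
        for ind in individual_ids
    }
    individual_ages = dict(
        zip(individual_ids, rng.uniform(config.age_range[0], config.age_range[1], n_individuals))
    )

    rows_meth, rows_cov, sample_rows = [], [], []
    for organ in design.organs:
        gmm_shift, accel = design.organ_offsets.get(organ, (0.0, 0.0))
        organ_effects = effect_table[effect_table["organ"] == organ]
        for ind in individual_ids:
            age = individual_ages[ind]
            group = individual_groups[ind]
            base = baselines_arr.copy()
            if group == design.groups[1]:
                for _, row in organ_effects.iterrows():
                    idx = promoter_sites[row["gene_id"]]
                    base[idx] = np.clip(base[idx] + row["effect"], 0.0, 1.0)
            apparent_age = np.full(len(keys), age)
            apparent_age[slopes_arr != 0] += accel
            m_true = np.clip(base + slopes_arr * apparent_age + gmm_shift, 0.0, 1.0)
            if config.entropy_drift > 0:
                shrink = max(0.0, 1.0 - config.entropy_drift * age)
                m_true = 0.5 + (m_true - 0.5) * shrink
            observed, coverage = _observe(m_true[None, :], config, rng)
            rows_meth.append(observed[0])
            rows_cov.append(coverage[0])
            sample_rows.append(
                {
                    "sample_id": f"{ind}_{organ}",
                    "age_months": age,
                    "group": group,
                    "organ": organ,
                    "individual_id": ind,
                }
            )

    sample_ids = [r["sample_id"] for r in sample_rows]
    order = sort_site_keys(keys)
    methylation = pd.DataFrame(np.vstack(rows_meth), index=sample_ids, columns=keys)[order]
    cov = pd.DataFrame(np.vstack(rows_cov), index=sample_ids, columns=keys)[order]
    samples = pd.DataFrame(sample_rows)
    truth = GroundTruth(
        site_baselines=pd.Series(baselines_arr, index=keys),
        site_slopes=pd.Series(slopes_arr, index=keys),
        reference_ages=pd.Series([r["age_months"] for r in sample_rows], index=sample_ids),
        affected_gene_table=effect_table,
    )
    return SimulatedCohort(methylation=methylation, coverage=cov, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# Fixtures: annotation and file output
# ---------------------------------------------------------------------------

def make_gene_records(
    n_genes: int,
    chrom: str = "chr2",
    seed: int = 0,
    spacing: int = 10_000,
    length: int = 2_000,
) -> list[GeneRecord]:
    """Evenly spaced toy genes with alternating strands."""
    rng = np.random.default_rng(seed)
    records = []
    start = 5_000
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        records.append(
            GeneRecord(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + length + int(rng.integers(0, 500)),
            )
        )
        start += spacing
    return records


def make_toy_gtf(records: Sequence[GeneRecord], path: str | Path) -> Path:
    """Write gene records as a standard GTF file (1-based, closed, tabbed).

    ``parse_gtf(make_toy_gtf(x))`` round-trips the records.
    """
    path = Path(path)
    lines = []
    for record in records:
        if record.strand not in {"+", "-"}:  # GeneRecord validates, but be explicit
            raise ValueError(f"invalid strand {record.strand!r}")
        lines.append(
            "\t".join(
                [
                    record.chrom,
                    "methaging",
                    "gene",
                    str(record.start),
                    str(record.end),
                    ".",
                    record.strand,
                    ".",
                    f'gene_id "{record.gene_id}";',
                ]
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as Bismark .cov files + sample sheet + truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample_id in cohort.methylation.index:
        meth = cohort.methylation.loc[sample_id]
        cov = cohort.coverage.loc[sample_id]
        observed = meth.notna()
        chroms, positions = zip(
            *[(c, p) for c, p in (key.rsplit(":", 1) for key in meth.index[observed])]
        ) if observed.any() else ((), ())
        table = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": [int(p) for p in positions],
                "meth_frac": meth[observed].to_numpy(),
                "coverage": cov[observed].to_numpy().astype(int),
            }
        )
        paths[sample_id] = write_bismark_cov(table, outdir / f"{sample_id}.cov")
    sheet = outdir / "samples.tsv"
    cohort.samples.to_csv(sheet, sep="\t", index=False)
    paths["sample_sheet"] = sheet
    truth_path = outdir / "truth_sites.tsv"
    pd.DataFrame(
        {
            "site_key": cohort.truth.site_baselines.index,
            "baseline": cohort.truth.site_baselines.to_numpy(),
            "slope": cohort.truth.site_slopes.to_numpy(),
        }
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth_sites"] = truth_path
    effects_path = outdir / "truth_effects.tsv"
    cohort.truth.affected_gene_table.to_csv(effects_path, sep="\t", index=False)
    paths["truth_effects"] = effects_path
    return paths
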