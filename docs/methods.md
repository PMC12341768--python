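# Methods

This note documents the models, conventions and numerical choices behind
`methaging`, the assumptions of its synthetic-data generator, and the
limits of what the test suite demonstrates.

## Data model and coverage rules

The central substrate is a pair of aligned sample × CpG matrices: observed
methylation fractions m = methylated reads / total reads (exactly; the
percent columns of Bismark coverage files are validated against the
counts, not trusted), and integer read coverage.  Missingness is explicit
(`NaN`), never a sentinel value, because imputation semantics must be
testable.  CpG sites are keyed `"chrom:pos"` (1-based) and never
strand-merged: a site is what the source file reported.  Two coverage
rules apply in sequence:

* **masking** — an entry observed with fewer than `min_depth` reads
  (default 5, *inclusive*: exactly 5 reads is kept) becomes missing;
* **site filtering** — a site is retained when at least
  `min_sample_fraction` (default 90%) of samples cover it at
  `min_depth`+.  The filter is idempotent and never reorders sites.

Both thresholds are configurable; the ≥5 convention is applied uniformly.

## Elastic-net clocks

`train_elastic_net_clock` fits age (months) on methylation fractions with
an elastic net at mixing α = 0.5 (configurable in [0, 1]; pure ridge is
approximated at mixing 1e-3 because the coordinate-descent path requires
an L1 component).  The penalty strength is chosen as the minimum of the
k-fold (default 10) cross-validated error over a log-spaced path of 100
candidates.  Features are standardised internally during fitting and the
coefficients are returned on the original scale, so weights read as
months per methylation-fraction unit.  Only nonzero-weight sites are kept
in the model.

The cohort is split 80/20 before training; the test size is
`round(0.2·n)`, so 134 samples give 107 train / 27 test.  The held-out
samples provide the evaluation (MAE, median AE, Pearson r with two-sided
p) and the *reference regression* — the least-squares line of predicted
on chronological age — stored with the model.  **Age acceleration** of a
later sample is `predicted − (slope·age + intercept)`; over the set the
line was fitted on, accelerations sum to zero by the least-squares
identity, which the tests assert.

Missing clock sites at application time are filled in two stages: a
missing value takes the mean of that site over the application-cohort
samples that cover it; a site covered in no sample falls back to the
sample's own mean over its covered clock sites.  The orientation
(site-mean first, sample-mean fallback) is a design choice; training-set
site means are also stored on the model for serialization and reference.

## Intersection clock

RRBS covers a partly random site subset per library, so a fixed-site
clock may find few of its CpGs in a new sample.  The intersection clock
maximises site use per test sample: intersect the training site set with
the sample's covered sites, restrict both sides, partition the training
samples into five seed-deterministic folds (fixed once per cohort run,
not resampled per sample — this makes cohort runs reproducible and
cacheable), fit one elastic net per fold on the other four folds (each
with its own nested penalty cross-validation, so no fold prediction sees
its own data), and report the arithmetic mean of the five predictions
(MeanPred).  A cohort run therefore fits five models per sample (5 × 64
for a 64-sample cohort); identical covered-site sets reuse cached fold
fits, which leaves every prediction bit-identical to the uncached
computation.  "Covered" means non-missing after depth masking.  Samples
sharing no site with the training set are reported, never silently
dropped.

## rDNA clock

The multi-copy rDNA repeat accumulates read depth, so an rDNA-restricted
predictor transfers well across datasets.  Per-sample coverage files on a
single rDNA reference are merged into a sample × position table of
methylation percentages (0–100, the scale the upstream extraction emits).
Four imputers complete it — column mean; k-nearest-neighbour (scikit-learn's
`KNNImputer`: nan-Euclidean distance over mutually observed features
scaled by feature count, donors restricted to rows observing the cell,
column-mean fallback when none does); SoftImpute (EM-style iterative SVD
with singular values soft-thresholded by a shrinkage λ, default 0, i.e.
plain hard-rank completion — the λ > 0 variant's objective, observed-entry
reconstruction error plus the nuclear-norm surrogate, decreases
monotonically and is tested); and iterative PCA (the same EM loop with
column centring).  Default rank is min(10, n−1), tolerance 1e-4 on the
relative RMS update, at most 200 iterations; imputed values are clipped
to [0, 100] and observed entries are never modified.

`run_model_grid` evaluates every imputer × {elastic net, gradient
boosting, random forest} combination on an 80/20 split.  Imputers are
fitted on training rows only and applied to test rows using training
statistics (for the SVD imputers, test rows are completed by iterative
projection onto the training row-space); the order of operations is a
deliberate leakage-free choice.  Tree models use fixed documented
defaults (100 trees; boosting depth 3; forest depth unlimited) with
seeds.  The best row minimises test MAE, ties broken by higher r, then a
fixed method order.

## Global statistics and group tests

GMM is a sample's mean methylation over its observed sites; MME is the
mean of the per-site binary Shannon entropy (base 2, `0·log 0 ≡ 0`, so
entropy is 0 at the endpoints and exactly 1 at m = 0.5).  Both are
computed over each sample's own observed sites — not a common-complete
subset — with the site count reported, so the choice is auditable.

Two-group comparisons use a two-sided Welch t-test (unequal variances);
the test suite cross-checks it against a permutation oracle on separated
groups.  Pearson correlations report two-sided p-values.  Significance
stars: ns for p > 0.05, `*` for 0.01 < p ≤ 0.05, `**` for
0.001 < p ≤ 0.01, `***` for p ≤ 0.001, `****` for p ≤ 1e-4 (the most
significant band is checked first where the bands overlap).

## Promoter analysis

Promoters are [−1500, +500] bp around the TSS along the direction of
transcription — closed interval, 2001 bp unless clipped at position 1.
The TSS comes from the GTF *gene* feature (start on +, end on −);
multi-transcript resolution is out of scope.  Per-gene per-sample
promoter methylation is the mean of observed CpGs in the window; genes
with no covered CpG are excluded, and a gene is testable in an organ when
both groups have ≥2 non-missing promoter means.  Bonferroni's G is the
number of genes actually tested in that organ, not the annotation size.
Best hits are the k genes with smallest uncorrected p (ties by gene id);
cross-organ common genes require p strictly below α in *every* organ,
with per-organ directions reported but consistency only flagged, not
required.  A Benjamini–Hochberg step-up utility is provided for FDR-style
corrections.

## Multi-organ comparisons

Per-individual metrics (epigenetic age, acceleration, GMM, MME) measured
in several organs are compared with paired t-tests on within-individual
differences for each organ pair; zero-variance differences are flagged
degenerate instead of being assigned a p-value.  Raw p-values carry
stars; a BH-adjusted column is emitted alongside rather than replacing
them.  Cross-organ consistency of aging rate is probed by Pearson
correlation of age accelerations between organ pairs.

## The synthetic-data generator

The generator emulates the *structure* of a multi-organ RRBS aging study,
not any particular dataset:

* **Training cohort** — default 134 samples with ages uniform over 1–27
  months (a lifespan-wide range; the real training-age distribution is
  unpublished, so uniform is the declared choice), 5,000 CpGs of which 4%
  drift linearly with age.  Expected methylation is
  `clamp(baseline + slope·age, 0, 1)`; age-site slopes have magnitude
  Uniform(0.5, 1.5) × `slope_scale` (default 0.01 fraction/month) with
  random sign, and their baselines are placed so the trend stays inside
  the unit interval over the age range (the clamp never distorts the
  injected linearity).  Non-drifting baselines come from a bimodal
  Beta(0.4, 0.2) (mean ≈ 2/3), like a real methylome.
* **Observation model** — per-entry Gaussian biological noise (sd 0.05),
  negative-binomial coverage (mean 30, dispersion 5; overdispersion
  mimics RRBS depth variability), a configurable fraction of entries
  (default 5%) forced below the 5-read threshold, and binomially sampled
  methylated reads, so observed fractions are exactly reads/coverage and
  zero-coverage entries are missing.
* **Entropy drift** — |m − 0.5| shrinks by a factor (1 − rate·age); this
  directly produces a positive MME–age correlation, and a negative
  GMM–age correlation whenever the site average sits above ½, without
  dictating either a priori.
* **Multi-organ cohort** — two groups × four organs × n per group (8 by
  default, 64 samples), ages ~23.5–27 months, CpGs placed inside toy-gene
  promoter windows plus background sites.  Group effects are additive
  methylation shifts on the promoter CpGs of affected genes in the HCR
  group; per-organ offsets shift global methylation and apparent age.
  Every injected effect is recorded in a ground-truth table used by the
  recovery tests.

What the simulator does **not** emulate: read-level sequence context,
bisulfite conversion error, sample-level correlated noise (noise is
independent per entry, so promoter averaging is more powerful than in
real tissue), CpG-island structure, sex effects, or the exact variance
structure of any published dataset.  Passing recovery tests therefore
demonstrate correctness of the machinery under the stated generative
model — they do not certify effect sizes or error rates on real RRBS.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately scaled designs: the clock
recovery study at the full 134 × 5,000 design; the intersection-clock
cohort study at 100 training samples × 600 sites with a 64-sample
application cohort (5 × 64 = 320 fold models) and a shorter penalty path
(5-fold CV, 20 candidates); the rDNA grid at 134 × 200 positions; null
calibration at 1,000 genes / 1,000 replicates; effect recovery over 50
simulation seeds.  Degenerate inputs are errors, not silent results:
constant ages, all-missing samples or features, empty intersections and
zero-variance paired differences all raise or flag explicitly.  Ties are
broken deterministically everywhere (documented per operation), and every
stochastic step takes an explicit seed, so reruns are bit-identical.

## Known limitations

* The clocks are linear; no pan-tissue normalisation or nonlinear age
  transforms are provided.
* The promoter unit is the gene, not the transcript, and enrichment
  analysis beyond BH correction is out of scope.
* The rDNA workflow consumes coverage files; alignment to the rDNA
  reference happens upstream.
* Genome-build liftover is assumed done: site keys must already be on a
  shared coordinate system before matrices are intersected.
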