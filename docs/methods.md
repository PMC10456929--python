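# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the design decisions behind `dimet`, in the order
a cohort flows through the pipeline.

## Data model

All stages operate on a samples × features abundance matrix of non-negative
intensities with NaN as the single missing marker, a per-sample metadata
table (sex, genotype, zygosity, role, batch, body weight), a per-feature
annotation (platform, chemical cluster, internal-standard flag) and an
optional samples × phenotypes matrix. Only `role == study` samples enter
statistics; QC rows feed technical metrics only, and `WT` is the reserved
wildtype genotype label. Statistics run on natural-scale abundances —
fold-changes are ratios of arithmetic means, matching how such screens
report effect sizes — while the generator plants effects additively on the
log2 scale so planted fold-changes are exact.

## QC and processing

Per feature: QC relative standard deviation RSD = sd/mean × 100 over the
pooled-plasma QC injections (sample sd, n−1; undefined with fewer than two
QC values, and an undefined RSD never removes a feature), and missingness /
prevalence over study samples. The filter boundaries follow the protocol
wording literally and are deliberately asymmetric:

* RSD **>** 50% removed (50.0% exactly is kept);
* missing fraction **≥** 0.70 removed ("at least 70%");
* prevalence must be **>** 0.30 (0.30 exactly is removed);
* internal standards removed by annotation flag (the package has no
  chemistry engine, so deuterated standards are a supplied flag).

The three rules commute, so the retained set is order-independent (tested).
Whether the missingness thresholds should apply per sex group instead of
overall is not fixed by the protocol wording for metabolites; the package
follows the wording (overall for metabolites, per sex group for phenotypes)
and exposes the thresholds as configuration.

**Imputation.** A missing metabolite value becomes 0.5 × the minimum
observed value of that feature within the sample's genotype group —
the below-detection reading of missingness, which the generator's MNAR
mechanism realises. A group with no observed value falls back to 0.5 × the
feature's global minimum; a feature observed nowhere is an error (the
prevalence filter should have removed it). Missing phenotype values use the
full group minimum (not half), after discarding phenotypes with > 70%
missing in either sex group — phenotypes are assumed less variable than
abundances, with missingness at the low end. An optional `gc_noise_floor`
switch replaces the half-minimum on the GC platform with a seeded
Uniform(0.3, 0.7) × group-minimum draw, approximating peak-detection noise
floors; the default stays half-minimum for uniformity.

**Batch normalisation.** "Median scaling per batch" is applied per feature:
x / median_batch(f) × median_all(f), preserving units and reducing to the
identity for a single batch. Per-feature correction is the standard intent
of median batch scaling; when a feature has fewer than 3 observed values in
a batch the batch's global median ratio substitutes. Only platforms listed
in the configuration are touched (default: HILIC, the platform acquired in
multiple batches in the emulated design). Reference-material-based drift
correction for the GC platform is out of scope; GC data flow through
untouched by default or via the same median scaling by config.

## Wildtype sex effects

Per feature, `Y ~ Sex` (optionally `+ Weight` as a covariate; the adjusted
analysis is reported alongside, never instead). `variance_mode="per-sex"`
(default) is two-step feasible GLS: an OLS fit, per-sex residual variances,
then weighted least squares with weights 1/σ²_sex — the natural
heteroskedasticity for a two-group sex model. No correlation structure is
modelled: the design has no repeated measures. Pooled mode is plain OLS and
is exactly the pooled-variance t-test (tested against scipy); per-sex mode
coincides with pooled when the two sample variances agree. A zero-variance
response returns p = 1 with a warning; features that cannot be fit at all
(e.g. on an un-imputed matrix) yield NaN rows with a warning rather than
aborting a scan. Benjamini–Hochberg q-values are computed across features by
a from-scratch step-up implementation (property-tested against statsmodels).
Tests are two-sided, α = 0.05 by default.

## Knockout dimorphism

Each KO line (6 mice) is compared against the full shared WT pool (40 mice)
— shared controls match the screen design; per-line control subsetting is a
config option. Two nested OLS comparisons give the p-values:

* genotype: full model `Y ~ G + S + G:S` vs `Y ~ S`, F on (2, n−4) df;
* interaction: same full model vs `Y ~ G + S`, F on (1, n−4) df;

computed as F = ((RSS₀ − RSS₁)/Δdf)/(RSS₁/df₁) from vectorised least
squares over the whole feature matrix at once (one design factorisation per
line, not per feature). Degrees of freedom come from design-matrix ranks, so
a line missing one sex is detected as rank-deficient and skipped with a
warning. Per-sex KO-vs-WT contrasts use the pooled two-group t-test
(equivalently two-group OLS); Welch is a config option. Direction is the
sign of (KO mean − WT mean) per sex on the natural scale.

**Classification.** With significance at α per test:

1. neither genotype nor interaction significant → `ns`;
2. genotype significant, interaction not → `genotype-no-sex-difference`;
3. interaction significant → by the per-sex contrasts: one sex significant →
   `female-only` / `male-only`; both significant → `opposite-direction` if
   the signs differ else `different-effect-size`; neither →
   `interaction-only`.

`interaction-only` is this package's addition for the case the four-way
wording does not cover; it is always reported separately, never merged.
Whether sub-classification should additionally require the genotype test
(the wording "by the genotype effect and by genotype–sex interaction" reads
either way) is exposed as `gate_on_genotype`; the default gates on the
interaction only and reports the genotype p alongside. No FDR is applied
across (line, metabolite) tests by default — the screen's stated posture is
hypothesis generation with multiplicity control at the cluster level — and a
`fdr` flag adds BH q-values per test family for users who want them.

**Effect sizes.** The standardised fold-change is the KO arithmetic mean
over the sex-matched WT arithmetic mean; its spread is the first-order
delta-method sd of a ratio of independent means,
fc × sqrt(se²_KO/m²_KO + se²_WT/m²_WT), which matches a bootstrap sd of the
ratio within the tolerance tested.

## Chemical-cluster enrichment

Clusters are a supplied non-overlapping labelling of features (deriving them
from structural similarity or ontology terms is out of scope). Per cluster,
the member p-values from any upstream test are compared to Uniform(0,1) by
the one-sided Kolmogorov–Smirnov statistic D⁺ = sup(ECDF − x) — one-sided
because only an excess of small p-values is of interest. BH FDR runs across
tested clusters; clusters below `min_size` (default 3 — the smallest size at
which a KS test is meaningful; the published screen does not state its
minimum) are excluded and listed. Each cluster also reports its altered
fraction (members with p < α), the increased fraction among those, a median
direction score and the member with the smallest p, which together give the
coordinates of the usual impact plot (direction vs −log10 p, dot size =
cluster size) as a plain table.

## Metabolite–phenotype association

Computed in WT mice only (KO groups of three are too small for rank
correlations). Per sex, Spearman rho uses average ranks with the two-sided
t approximation for p; pairs need n ≥ 15 in both sexes ("more than 14 data
points", read strictly), counted on pairwise-complete observations. An exact
permutation p exists for n < 10 as a safety net but is unreachable under the
filter. Constant vectors make a pair undefined; such pairs are skipped and
counted. Categories: `both-same-direction` / `both-opposite-direction` when
both sexes are significant, `female-only` / `male-only` when exactly one is,
else `ns`; the significant total is the union over sexes, which the four
categories partition exactly. Cluster-level association maps run the KS
enrichment per (phenotype, sex) slice on that sex's correlation p-values,
signed by the median rho of significant members — a long-format table of
exactly |phenotypes| × |clusters ≥ min_size| × 2 rows.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the emulated
study conditions, not tuning knobs.

* **Design**: 20 WT per sex; 30 KO lines × 3 per sex (zygosity assigned
  het/hom in the screen's 17:13 proportion); 22 pooled-plasma QC replicates;
  800 features split across the five platforms in the screen's per-platform
  compound proportions (GC 13.1%, HILIC 22.0%, CSH lipidomics 54.5%,
  bile acids/steroids 4.1%, oxylipins 6.3%), plus 5 flagged internal
  standards.
* **Abundances**: lognormal; per-feature baseline log2-mean ~ N(16, 2)
  (intensities around 10³–10⁷, the dynamic range of MS peak heights) and
  within-group log2-sd ~ U(0.3, 0.8) (biological CV roughly 20–75%, typical
  of plasma metabolites). The protocol does not state abundance
  distributions; lognormality is a modelling choice recorded in the config,
  chosen because plasma intensities are right-skewed and because
  log-additive effects make planted fold-changes exact.
* **Sex effects**: 55% of features carry a WT sex effect of U(0.2, 2.0) log2
  units (up to 4-fold), 75% of them higher in males — the direction split
  the screen reports. Effects are planted cluster-coherently (whole chemical
  clusters chosen until the target fraction is met, one dominant direction
  per cluster) so that enrichment has structure to find; a flag reverts to
  feature-independent planting.
* **KO effects**: per line, 30% of features are affected, one third of them
  dimorphic (split evenly over female-only, male-only, opposite-direction,
  different-effect-size; the rest both-sexes-equal), with magnitudes
  U(1, 2) log2 units and random sign. An explicit per-line archetype map can
  replace the random assignment; referencing an unknown line is an error.
  The planted truth — archetype and exact per-sex log2 effect per (feature,
  line) — is returned for recovery testing.
* **Missingness**: missing-not-at-random. Cells below the per-feature 30%
  quantile are 4× as likely to be blanked; sampling is without replacement
  via exponential races, so the realised missing count is exact at
  round(rate × cells) (rate 5% by default). Ten features get ~85%
  missingness and ten get 80% QC RSD to exercise the filters.
* **QC replicates**: drawn around the grand feature mean with lognormal
  noise set to a 10% RSD target (the protocol reports median QC RSD below
  20%).
* **Batches**: two; HILIC batch 2 is multiplied by 1.3 so batch
  normalisation has a real effect to undo.
* **Phenotypes**: 208 continuous phenotypes, each a linear readout of two
  driver features' log2 abundances plus Gaussian noise at signal-sd (so
  driver correlations are ≈ 0.7), with sex-specific coefficient patterns
  (40% female-only, 40% male-only, 12% both-same, 8% both-opposite) to plant
  correlation dimorphism; 3% scattered missingness plus two phenotypes
  mostly missing in females to exercise the drop rule.
* **Reproducibility**: one seed; per-stage RNGs are spawned deterministically
  from it, so any sub-stage is stable under changes elsewhere.

What the generator does **not** emulate: chromatographic drift within a
batch, realistic inter-metabolite correlation networks (only the
cluster-level coherence knob above), platform-specific noise shapes, and
litter/cage structure. Passing recovery tests therefore show that the
statistics recover the effects this model plants — not that they are robust
to every artefact of real acquisitions.

## Numerical choices and degenerate inputs

* BH step-up: q_(i) = min over j ≥ i of p_(j)·n/j, clipped to [0,1]; NaN
  p-values propagate as NaN and do not count toward n.
* Nested F: a perfect full-model fit (RSS₁ ≈ 0 at relative tolerance 1e-12)
  returns p = 0 when the null fits worse and p = 1 when both fit perfectly;
  rank-deficient designs raise rather than return a misleading p.
* Two-group tests: zero pooled variance with equal means → p = 1.
* Spearman: |rho| clipped to 1 before the t transform; p = 0 at |rho| = 1.
* Ties in sorting: all result tables are written with a stable sort on
  (feature, line/phenotype) keys, so identical inputs give byte-identical
  files.

## Problem sizes used in validation

The test suite validates on reduced cohorts (120–400 features, 3–25
phenotypes) and calibrates null error rates on a 2000-feature null cohort;
oracle-equivalence checks run 1000 random instances per primitive. The
acceptance script runs the full study-shaped preset (805 features, 220
study mice, 208 phenotypes, 30 lines). These sizes were chosen so the whole
validation cycle completes in minutes while keeping every binomial
tolerance band tight enough to detect real miscalibration.

## Known limitations

* The per-sex FGLS uses n−2 degrees of freedom rather than a Satterthwaite
  approximation; with 20 mice per sex the difference is negligible, with
  very small groups pooled OLS is the safer mode.
* Half-minimum imputation underestimates variance for heavily-missing
  features; the 70%/30% filters bound how much imputation any retained
  feature receives.
* The KS enrichment treats member p-values as independent; correlated
  members (e.g. co-regulated lipids) make it anti-conservative at the
  cluster level, which the FDR across clusters only partially absorbs.
* Phenotype association is WT-only by design; extending it to KO lines
  would need more than three animals per sex per line.
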