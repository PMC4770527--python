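# Methods

`epityper` re-implements, as a tested reusable pipeline, a genome-wide
DNA-methylation subtyping ("epityping") analysis of breast tumors measured on
Illumina 450K arrays, together with the downstream integrative steps that
characterize the resulting subtypes.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic cohorts
used for testing do and do not establish.

## Beta values, masking, and peak normalization

Methylation is summarized per CpG and sample as the beta value
`beta = M / (M + U)` from the methylated and unmethylated signal intensities.
A measurement is set missing when its detection p value exceeds 0.05
(strictly) or fewer than 3 beads support a channel; when bead counts are
absent from the input dialect (as in TCGA level-2 tables) only the p rule
applies.  A zero total intensity yields a missing value rather than an error.
Samples with more than 10,000 missing values are flagged in the QC report,
not rejected.

The two Infinium probe chemistries have different dynamic ranges (type II is
compressed toward 0.5), so each sample is normalized per assay type: the beta
density is smoothed with an Epanechnikov kernel, the unmethylated peak
(density argmax below 0.5) is moved to 0 and the methylated peak (argmax
above 0.5) to 1 by a linear stretch, and values outside [0, 1] are clamped.

Numerical choices:

- **Bandwidth 0.04, 1001-point grid over [0, 1], midpoint 0.5** — resolves
  peaks at least 0.1 apart without splitting noise modes; all configurable.
- **Boundary reflection.** The kernel estimate is boundary-corrected by
  reflection at 0 and 1.  Without it, mass clamped onto a boundary by a
  previous normalization pulls the estimated mode a few grid steps inward,
  and renormalization would drift by ~0.005; with reflection the procedure is
  idempotent to well under one grid step.
- **Minimum peak separation 0.2** — a sample/assay stratum whose two modes
  are closer (effectively unimodal) raises an error naming the stratum,
  protecting the linear map from a degenerate denominator.
- The map is strictly monotone between the clamping bounds, so within-sample
  ranks are preserved.

The hypermethylation score is the per-sample mean beta over a contributing
probe set, excluding missing values — computed globally (all probes) and for
promoter CpG-island probes (region annotation TSS1500 or TSS200 *and* island
relation "Island").  The source analysis cites an external score definition
without reproducing it; mean beta is used here as it preserves the intended
ordering semantics, and the contributing-site counts are returned alongside.

## Tumor-specific CpG selection

A probe is constitutively **methylated** in the normal cohort when every
non-missing normal beta is strictly greater than 0.7, allowing at most 2
missing values; **unmethylated** symmetrically below 0.3.  Any non-missing
value inside [0.3, 0.7] excludes the probe.  "Allowing for 2 missing values"
is read as `<= 2`.

Among constitutive probes, a CpG is **cancer-methylated** when it is
unmethylated in normals and exceeds beta 0.7 in at least
`ceil(min_fraction * n_tumors)` tumors (5% by default; 5% of 188 gives
n = 10), and **cancer-unmethylated** in mirror image.  Missing tumor values
never count as switched and the denominator stays the full tumor count
(conservative).  The two sets are disjoint by construction (opposite normal
states).

## Epitype discovery and classification

Bootstrap consensus clustering over the selected CpGs:

1. Each of `n_boot` (default 2000) iterations draws n samples with
   replacement; the *unique* resampled samples are clustered by Ward
   agglomeration on Pearson-correlation distance `d = 1 - r` and cut at each
   k in 3..10 (the inner clustering).
2. Co-clustering frequencies, normalized by per-pair co-presence counts,
   form the consensus matrix; its rows are clustered the same way (Ward on
   1 - Pearson between rows; `1 - frequency` is available behind a flag) to
   give the outer labels.

Dialect notes: the bootstrap recipe (resample-to-n, cluster unique samples,
normalize by co-presence) is one of several defensible readings and is
documented and seedable; inner and outer clusterings share the same k.  R's
`ward.D` on a dissimilarity d is reproduced with scipy by passing `sqrt(d)`
to `linkage(method="ward")`, since scipy treats its input as Euclidean and
works internally with squares.  Correlations are pairwise-complete with a
minimum overlap of 100 sites.  A sample never drawn in any resample is an
error by default (advising more iterations).

**Choosing k.**  For each k, every outer cluster gets a consensus margin:
mean within-cluster consensus minus the largest mean consensus to any other
cluster.  A k is admissible when no cluster has fewer than 5 samples and the
smallest margin is at least 0.6 (both configurable; the stability statistic
is a design choice — the admissibility wording in the source analysis names
none).  The largest admissible k is selected, i.e. the solution with the
largest number of robust clusters.  On the default synthetic cohort this
flags k = 8..10 (fragment clusters with low margins) and selects the planted
k = 7.

**Centroids and classification.**  An epitype centroid is the per-CpG mean
beta over its members (missing excluded).  Epitypes are ordered by
descending correlation of their centroid with the normal-cohort mean
profile, so the most normal-like cluster is named ET1; this is a naming
convention, not a biological claim, and on synthetic or new cohorts the
ordinal names need not coincide with any particular biological role.  For
that reason the *roles* consumed by pattern extraction (which cluster is
basal-like, hypermethylated luminal, globally hypomethylated luminal) are
declared in configuration rather than inferred.  New samples are assigned to
the centroid with the largest Pearson correlation (pairwise-complete,
minimum 100 overlapping sites); exact ties break to the first epitype in the
order; a zero-variance sample is an error, not a default call.

## Epitype-specific methylation patterns

Five pattern sets are conjunctions of strict per-epitype mean-beta bounds
applied to the two tumor-specific universes (basal = basal-like role,
hyperL = hypermethylated luminal, hypoL = globally hypomethylated luminal):

| set | universe | constraints |
|---|---|---|
| basal_methylated | cancer-methylated | mean(basal) > 0.5 |
| luminal_methylated | cancer-methylated | mean(hyperL) > 0.5 and mean(basal) < 0.1 |
| global_hypo | cancer-unmethylated | mean(hypoL) < 0.5 and mean(hyperL) > 0.7 and mean(basal) > 0.7 |
| luminal_hypo | cancer-unmethylated | mean(hyperL) < 0.5 and mean(basal) > 0.7 |
| basal_hypo | cancer-unmethylated | mean(basal) < 0.5 and mean(hypoL) > 0.7 |

Means are over non-missing members; a probe with no observation in a
constrained epitype fails that constraint.  Tightening any threshold can
only shrink a set, and luminal_methylated is disjoint from basal_methylated
by construction.

## Expression integration and promoter calling

Relative expression is `log2(x + 1)` mean-centered per gene; absolute
expression is `log2(TPM + 1)` with TPM obtained by column normalization of
scaled estimates.  When several probes map to one gene, the probe with the
largest variance across samples is kept.  Methylation-expression screening
uses pairwise-complete Pearson correlation for CpGs mapped to a unique gene,
with strict class thresholds r > 0.2 (positive) and r < -0.2 (negative);
constant CpGs or genes, missing mappings, and overlaps under 10 pairs are
reported as unmapped with a reason.  Module scores are per-sample means of
the module genes found, with the matched count reported.

Promoter methylation for a candidate driver is called in two steps: (1)
screen every CpG within the gene's transcripts or 1 kb upstream (strand
aware, 0-based half-open, windows of multiple transcripts unioned) for
r < -0.2 against the gene's expression in a declared screening cohort; (2)
average beta over the informative CpGs per sample and call by a preset —
methylated if mean > 0.2 (BRCA1-style) or unmethylated if mean < 0.8
(HORMAD1-style), strictly.  Zero informative CpGs yields "uncallable" for
every sample, never a default call.

## Genomic context, copy number, mutations, statistics

Interval arithmetic is 0-based half-open throughout; strand is ignored
(CpG methylation is strand-symmetric); a probe covered by overlapping repeat
intervals counts once.  Repeat enrichment is a two-sided Fisher exact test
on the 2x2 (target vs non-target background) x (in LINE/LTR vs not) table.
Chromosome-end proximity uses `min(pos, length - pos)` and a two-sided Welch
t test; the subtelomere window defaults to 5 Mb.

FGA is the fraction of platform probes called gained or lost; thresholds of
±0.2 on log-ratio-like estimates produce calls when the input carries none.
A catalogue region is amplified when the mean probe estimate is strictly
greater than 0.8; regions without probes are reported uncallable.  Mutation
tables (MAF-minimal) may contain several experiments per tumor: a gene is
mutated when nonsilent in at least one experiment, and the substitution
count is the mean over experiments (SNP rows when a Variant_Type column is
present).  Nonsilent excludes Silent, Intron, UTRs, IGR, flanks and RNA
(configurable).

Categorical associations use the chi-square test without continuity
correction (df = k - 1 for a k x 2 table), switching to Fisher's exact test
for 2x2 tables with any expected count below 5 (scipy's exact test only
covers 2x2; larger sparse tables fall back to chi-square with a warning).
Feature screens adjust p values by Benjamini-Hochberg over the tested
features only, after any minimum-count filter (e.g. genes mutated in at
least 5 tumors).  Survival uses Kaplan-Meier estimates and the k-group
log-rank test with the standard hypergeometric variance for ties; patients
with several samples are reduced to the first record (first primary) before
testing; an optional horizon (e.g. 10 years) administratively censors later
events.  Overall-survival events are deaths of any cause.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes, so
that every stage is testable without downloads.  Default conditions: 120
tumors, 96 normals, 5000 probes, 7 epitypes with proportions
(0.20, 0.08, 0.14, 0.12, 0.10, 0.08, 0.28), beta peaks 0.05/0.95, beta-scale
noise 0.05, 70% type-II probes with peak compression to 0.10/0.85, and a
0.5% detection-censoring rate — sizes chosen to exercise the pipeline at
desk scale while keeping every planted epitype above the 5-sample
admissibility floor.

Beta noise is drawn on the logit scale (sd = 4 x noise_sd, the factor
matching the logistic slope at 0.5) and mapped back, which keeps values in
[0, 1] without clipping and concentrates noise away from the peaks, as in
real beta data.  Type-II bias is a linear peak shrinkage toward 0.5 —
exactly the dialect the peak normalizer corrects, so normalization restores
both assay types to a common scale by construction.

Planted probe classes: constitutive unmethylated/methylated backgrounds, an
intermediate "variable" class (excluded by the normal-status rules), two
graded-switching classes whose per-epitype *switch rates* follow a gradient
while their per-epitype means stay strictly outside every pattern-rule bound
(members of the tumor-specific universes but of no pattern set), and five
mean-target classes realizing the pattern sets, with per-epitype means
placed at least 0.05 beyond each rule threshold.  Switch counts per probe
and epitype are deterministic (`round(rate x n)`), so rule recovery on a
low-noise cohort (noise 0.01, no missingness) is exact by design.  The
graded promoter hypermethylation rises across the luminal epitypes toward
the hypermethylated-luminal epitype, one epitype is globally hypomethylated
(its specific probes are placed within 5 Mb of chromosome ends), the
luminal-shared hypomethylation probes are placed inside LINE/LTR repeats,
and a near-normal epitype is included.  Exact means are configuration
values, not claims about real tumors.  Two driver genes are planted: a
BRCA1-like gene (a quarter of basal-epitype tumors silenced: promoter beta
0.6, suppressed expression; normals near 0.02) and a HORMAD1-like gene
(30% of basal tumors demethylated to 0.25, elevated expression; normals
0.95), each with informative and non-informative window CpGs.

Expression is linear in the planted beta with configurable per-class slopes
(negative for luminal-specific methylation, positive for the hypomethylation
classes, zero for the basal constitutive class) plus Gaussian noise (sd
0.1); copy-number profiles are contiguous ±0.6 segments with per-epitype
altered fractions rising from 5% to 40% plus named amplicon regions, one of
which (the ERBB2-like region) is amplified in 80% of the HER2-like epitype;
mutation tables plant three driver genes with epitype-dependent rates plus
Poisson background substitutions, and a few tumors carry a second
sequencing experiment; survival is exponential with per-epitype yearly
hazards (0.03, 0.015, 0.025, 0.05, 0.07, 0.08, 0.06) and uniform censoring
on 4–15 years — a minimal model supporting log-rank tests, with hazard
contrasts detectable at n in the hundreds (the survival check therefore
runs on a 600-tumor cohort).

All randomness flows from one PCG64 generator (`numpy.random.default_rng`)
seeded from the configuration, so identical configurations reproduce every
table bit-for-bit; fixtures round-trip through TSV at 17 significant digits.

**What passing tests do not show.**  The generator draws independent noise
per probe and sample: it has no probe-probe correlation beyond the planted
class structure, no tumor purity gradient, no batch or chip effects, no
genuine genomic background for repeats and chromatin states (tracks are
random segmentations with the planted placements), and clusters far better
separated than real tumor heterogeneity.  Recovery results therefore
validate the *implementation* of the rules and algorithms, not their power
on real cohorts.

## Problem sizes used in the shipped checks

The default test and acceptance conditions are 120 tumors x 5000 probes with
200 bootstrap iterations, a low-noise replicate of the same size, a held-out
cohort of the same size for classifier concordance, and a 600-tumor cohort
for the survival comparison.  These sizes make every stage's behavior
observable in minutes on one CPU; the algorithms themselves are vectorized
over probes and precompute the sample-distance matrix once per consensus
run, so full-scale 450K cohorts (hundreds of samples x 485k probes) remain
tractable.

## Known limitations

- The consensus-bootstrap dialect and the cluster-stability statistic are
  documented choices among several defensible readings.
- Fisher's exact test is available for 2x2 tables only; larger sparse tables
  use chi-square with a warning.
- The hypermethylation score is a mean-beta summary, not the externally
  defined score it stands in for semantically.
- No background/dye-bias correction (noob, SWAN, BMIQ), IDAT decoding,
  segmentation, external subtype classifiers, or enrichment databases:
  those are out of scope; the pipeline consumes their outputs as inputs
  where relevant.
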