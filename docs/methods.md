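# Methods

## Scope and design

`lymphgerm` re-implements, as a tested library, the desk-scale machinery of
a rare germline-variant analysis of B-cell neoplasm cohorts: consensus
calling over four variant callers' outputs, a rarity/impact prioritization
cascade, clonal-hematopoiesis (CHIP) filtering, double-hit detection, a
carrier-collapsing burden test against public-control allele counts, and
per-gene Cox survival screens. Upstream read alignment and the callers
themselves are out of scope — the pipeline consumes their VCFs. Annotation
resources (population frequencies, CADD-like scores, consequence calls,
known-variant and pathogenicity tables, gene lists, mappability tracks) are
consumed as plain tables, never queried live.

## Variant identity and consensus

Callers disagree on indel spelling, so cross-caller matching operates on a
canonical key: multi-allelic records are split (with per-allele depth
apportionment), then each allele pair is made parsimonious and left-aligned
against the reference by the standard algorithm (repeatedly trim the shared
trailing base, extending left with the preceding reference base when an
allele would empty; finally trim shared leading bases). Normalization is
idempotent and maps every equivalent representation of an indel to one key;
records whose REF disagrees with the reference are rejected with a warning.

A consensus call requires ≥ 2 supporting callers. Merge rules the source
protocol leaves open, fixed here: GQ and DP are medians across supporting
callers; VAF is recomputed from summed allele depths when all callers
report them (median of per-caller VAFs otherwise); a het/hom-alt genotype
tie resolves to het — conservative for downstream homozygote calling — and
is flagged. QC thresholds (GQ ≥ 30, DP ≥ 10, VAF ≥ 0.30) apply to the merged
values, i.e. after caller merging. Excluded regions arrive as one merged BED
(0-based half-open at the interface; VCF coordinates are 1-based inclusive
everywhere else); a variant at 1-based position p is removed iff p−1 lies in
an interval.

## Prioritization

popmax is the maximum allele frequency over non-excluded populations, with a
strict `< threshold` comparison (default 0.5%). Two exclusion conventions
coexist: the cohort-characterization filter uses no exclusions; the burden
configuration excludes Finnish, Ashkenazi Jewish and "Other". A variant
absent from the frequency table — or observed only in excluded populations —
counts as unobserved (popmax 0, passes). Impact classes: PTV consequences
qualify regardless of score; missense requires CADD Phred strictly > 20;
inframe/other consequences qualify only through the extended high-impact
flag (protein-interaction, structural-interaction, rare-amino-acid
annotations) used by the extended burden model. One consequence per variant:
the most severe across transcripts (PTV terms > missense > inframe >
synonymous/other). Novelty is absence from the supplied known-variant table.
The cascade's filters are pure per-variant predicates, so their application
order is irrelevant, and panel restriction partitions the qualifying set
exhaustively into panel and background streams.

## CHIP and hit structure

Variants in the supplied CHIP gene list with a germline-like blood VAF but a
tumor-compartment VAF below 0.05 (configurable; the source protocol gives no
number) are classified as likely myeloid mosaics and removed from all
downstream analyses; missing tumor data yields "germline, not assessable".
Homozygotes are per (patient, variant) events; germline double hits are per
(patient, gene) events requiring ≥ 2 distinct heterozygous qualifying
variants, with phase taken from an optional phase table (cis candidates are
retained but flagged, enabling a stricter trans-only analysis). A somatic
mutation in the same gene and patient yields a germline–somatic event; a
germline variant whose position falls inside a patient's LOH segment
(1-based inclusive) yields an LOH second hit.

## Burden test

Dominant collapsing: a patient with ≥ 1 qualifying allele in a gene is one
carrier. Public controls are site-frequency data without genotypes, so
control carriers are approximated by the summed allele count over the gene's
qualifying variants, capped at the control sample size (each rare allele
assumed to sit in a distinct control — standard for public-control burden
testing). The test is the one-sided upper hypergeometric tail of the 2×2
carrier table, in the enrichment direction only. BH FDR is applied within
model (PTV-only vs PTV + high-impact; the two models are corrected
separately), with gene discovery at q < 0.1. The genomic inflation factor is
λ = median(χ²₁-quantile of 1 − p) / 0.4549.

A calibration caveat measured by the evaluation suite: with realistic
qualifying-carrier rates (~1%/gene in a 500-case cohort, i.e. ~5 expected
carriers per gene), the exact test's discreteness makes its null
p-distribution super-uniform — median p ≈ 0.57 rather than 0.5 — so λ sits
near 0.7 and the fraction of genes with p < 0.05 near 0.03. This is
conservatism, not miscalibration: under the null the suite observes zero
q < 0.1 discoveries across 2,000 genes, and type-I error never exceeds its
nominal level. λ approaches 1 only as per-gene carrier counts grow.

## Survival

Analysis is restricted to CLL-subgroup patients and to genes carried by
strictly more than 1% of them. One Cox proportional-hazards model per gene
and outcome (lifelines; Efron tie handling; Wald tests; normal-approximation
95% CIs): time to first treatment adjusted for IGHV mutation status and
stage, overall survival for IGHV status and age at diagnosis; an alternative
age + CLL/MBL adjustment set is selectable. Patients with missing covariates
are dropped per model with logged counts. Degenerate designs (no carrier
contrast, < 2 events) raise; non-converged fits are returned flagged and
excluded from the BH correction, which is applied across genes within each
outcome.

## Synthetic cohort generator

The generator emulates the full study input surface: per-patient,
per-caller VCFs (FORMAT GT/GQ/DP/AD), population AF / CADD / consequence /
known-variant / pathogenicity tables, an excluded-region BED, control
allele counts, somatic mutation and LOH segment tables, tumor-compartment
VAFs for CHIP-gene variants, and a clinical table with two
exponential-model outcome pairs — plus a ground-truth JSON of everything
planted.

Model and defaults (chosen once, to mirror the emulated study's structure
at reduced scale):

- **Cohort.** Two diagnosis subgroups mixed 504:222 (CLL-dominated); age ~
  N(65, 10) years; ordinal stage 1–4; IGHV unmutated with probability 0.45
  among CLL (2% missing); MBL precursor status at 54/504.
- **Carriers.** Each patient independently carries a qualifying variant per
  gene with probability `background_qualifying_rate` (default 0.01) times a
  per-gene enrichment multiplier, drawn from a pool of 4 recurrent
  segregating variants per gene. The Bernoulli carrier model means a
  background carrier has exactly one variant per gene; multi-variant
  structure is planted explicitly, which makes exact-recovery oracles
  sharp but understates accidental co-occurrence relative to real cohorts.
- **Variant types.** Pool variants follow a configurable mix dominated by
  missense (93.5%), with stop-gain, frameshift, splice, inframe, stop/start
  loss making up the rest; missense CADD ~ U(20.5, 45); inframe events carry
  the extended high-impact flag. Population AFs use a point-mass-at-zero
  (novel, 44.75%) + uniform(0, 0.004) mixture — no claim of realism for the
  AF spectrum. Per gene, five "noise" variants exercise each filter: a
  common variant, a low-CADD missense, a synonymous variant, a
  Finnish/Ashkenazi-only common variant, and a rare damaging variant inside
  the excluded BED region.
- **Planted events.** Per-patient rates for compound hets (15/726),
  homozygotes (12/726), CHIP mosaics (10/726), somatic second hits (17/726)
  and LOH second hits (1/726) match the emulated study's observed
  per-patient frequencies; second hits pair with panel-gene germline
  variants. CHIP mosaics have blood VAF ~ U(0.35, 0.45) and tumor VAF ~
  U(0, 0.02); true germline calls in CHIP genes get concordant tumor VAFs.
  Background somatic mutations and LOH segments are placed only in genes
  where the patient has no qualifying germline variant, so planted events
  are exactly the true-positive set.
- **Observations.** Het VAF ~ Beta(60, 60), hom-alt ~ Beta(95, 5), DP ~
  12 + Poisson(35), GQ ~ U(40, 99); a configurable 5% of true calls fail one
  QC threshold. Each of four pseudo-callers detects each true variant
  independently with probability `caller_sensitivity` (0.95 default; at
  least one caller always emits the record so ground truth is observable).
  One caller writes indels non-parsimoniously (suffix-padded anchors) to
  exercise normalization.
- **Survival.** Exponential times with log-hazard = planted per-gene carrier
  effects + 0.8·IGHV-unmutated + 0.3·(stage − 2.5) for TTFT (baseline rate
  0.15/yr) and + 0.05·(age − 65) for OS (baseline 0.05/yr); independent
  uniform censoring (1–8 and 3–12 years). Proportional hazards holds by
  construction, so Cox recovery is a clean parameter-recovery test.

What passing tests on this generator do **not** show: robustness to allele-
frequency spectra, linkage disequilibrium, sequencing batch effects between
cohort and controls, caller-specific error modes beyond representation
differences, ancestry structure, or informative censoring. The statistical
suites validate the machinery's calibration under its stated assumptions,
not the published cohort findings, which require the controlled-access data.

## Problem sizes used by the evaluation suites

Null burden calibration: 2,000 genes × 500 cases, control counts emulating
15,708 genomes. Power: 50 replicates of a 10×-enriched gene among 100 genes
× 500 cases. Cox: 20 replicates of an all-CLL 500-patient cohort with ~8%
carriers (planted OS hazard ratio 3 for coverage; hazard ratio 1 screened
against ~15 eligible genes for the null arm). Event recovery: a 40-patient
noise-free cohort with boosted event rates run through the file-based
pipeline end to end. Consensus confirmation: a 50-sample cohort scanned
brute-force at the VCF text level. These sizes keep every suite within
seconds to tens of seconds while leaving the measured proportions'
confidence intervals well inside the asserted bounds.

## Numerical and degenerate-input conventions

Percentages round half-up to 2 decimals. Fold enrichment against a zero
reference frequency is reported "novel", not infinite. Zero-margin 2×2
tables give p = 1; all-p = 1 inputs give λ = 0 with a warning. BH on an
empty vector returns an empty vector. Fisher p-values are clamped to (0, 1].
Control-count rows with missing AN contribute zero carriers with a warning;
malformed LOH segments (start ≥ end) are rejected with a warning. The
pipeline is deterministic: identical inputs and configuration produce
byte-identical reports, verified by checksum.

## Known limitations

- Control carriers from summed allele counts ignore the (negligible at
  these frequencies) chance of two rare alleles in one control, and cap at
  the control sample size.
- Phasing is table-driven only; no read-backed phasing.
- The recessive/compound-het burden model and covariate-adjusted (mixed
  model) burden tests are out of scope.
- The generator's variant-type mix applies to the qualifying pool, not to
  the full site spectrum; synonymous and common variation exist only as
  filter-exercising noise.
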