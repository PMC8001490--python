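# lymphgerm

Rare germline variant analysis for B-cell neoplasm cohorts: multi-caller
consensus calling, rarity/impact prioritization, double-hit and clonal
hematopoiesis (CHIP) classification, gene-level burden testing against
public controls, and per-gene survival association — with a synthetic
cohort generator so the whole pipeline can be exercised and calibrated
without controlled-access patient data.

## The problem

Rare germline variants (population allele frequency < 0.5%) in cancer genes
shape both predisposition and prognosis of B-cell lymphoid malignancies
(CLL, follicular lymphoma, DLBCL, Burkitt lymphoma), but individual variants
are too rare to analyze one at a time. The standard strategy is:

1. **Consensus calling.** Germline variants from several callers are
   normalized (multi-allelic split, indels left-aligned and made
   parsimonious) and accepted only when ≥ 2 callers agree and the merged
   call passes GQ ≥ 30, DP ≥ 10, VAF ≥ 30% and falls outside low-mappability
   or homopolymer regions.
2. **Prioritization.** Keep variants that are rare (popmax < 0.5%, optionally
   excluding the bottlenecked Finnish/Ashkenazi populations) and putatively
   dysfunctional: protein-truncating variants (PTVs: stop gained/lost, start
   lost, frameshift, splice donor/acceptor), missense with CADD Phred > 20,
   or other high-impact annotations. Restrict to a curated cancer-gene panel
   (the union of six literature gene lists), routing off-panel variants to a
   background stream for rate comparison.
3. **CHIP filtering.** Apparent germline calls in clonal-hematopoiesis genes
   that are absent from the tumor compartment are mosaic blood events, not
   inherited variants, and are removed.
4. **Hit structure.** Homozygotes, germline double hits (compound
   heterozygote candidates), germline–somatic double hits and LOH second
   hits are cataloged per patient and gene.
5. **Burden test.** Per gene, the number of carrier patients (dominant
   collapsing: ≥ 1 qualifying allele counts once) is compared against
   public-control allele counts with a one-sided Fisher exact test
   (hypergeometric upper tail); control carriers are approximated by the
   summed allele count capped at the control sample size. Benjamini–Hochberg
   FDR within model, with the genomic inflation factor
   λ = median(χ²₁(1 − p)) / 0.4549 as a calibration diagnostic.
6. **Survival.** For genes carried by > 1% of CLL cases, Cox
   proportional-hazards models (Efron ties) of carrier status on time to
   first treatment (adjusted for IGHV status and stage) and overall survival
   (adjusted for IGHV status and age), BH-corrected within outcome.

## Worked example

Generate a 200-patient synthetic study with one 12×-enriched gene and run
every stage:

```python
from lymphgerm.synthetic_cohort import CohortSpec, generate_cohort
from lymphgerm.pipeline import RunConfig, run_pipeline

spec = CohortSpec(n_patients=200, n_genes=60, panel_size=40, seed=42,
                  enriched_genes=[("G0005", 12.0)])
bundle = generate_cohort(spec, "demo/cohort")
manifest = run_pipeline(RunConfig(
    vcf_dir=str(bundle.vcf_dir), reference_fasta=str(bundle.reference_fasta),
    popaf_table=str(bundle.popaf_table), cadd_table=str(bundle.cadd_table),
    consequence_table=str(bundle.consequence_table),
    clinical_table=str(bundle.clinical_table),
    panel_files={"panel": str(bundle.panel_file)},
    chip_gene_file=str(bundle.chip_gene_file),
    tumor_vaf_table=str(bundle.tumor_vaf_table),
    somatic_table=str(bundle.somatic_table), loh_table=str(bundle.loh_table),
    control_counts=str(bundle.control_counts),
    excluded_bed=str(bundle.excluded_bed), out_dir="demo/run"))
print(manifest["stages"])
```

prints the per-stage filter funnel:

```
{
 "caller_observations": 1859,
 "consensus_variants": 412,
 "qualifying_panel": 115,
 "qualifying_background": 46,
 "chip_flagged": 2,
 "qualifying_after_chip": 113,
 "double_hit_events": 11,
 "burden_ptv_only_genes": 2,
 "burden_ptv_plus_high_impact_genes": 2,
 "survival_os_genes": 25,
 "survival_ttft_genes": 25
}
```

1,859 raw caller records collapse to 412 consensus variants (≥ 2 callers, QC
pass); 115 qualify in panel genes and 46 in background genes; two apparent
germline calls in CHIP genes were absent from the tumor compartment and
removed. `demo/run/double_hits.tsv` lists the per-patient event catalog,
e.g.:

```
patient  gene                kind                      variants   phase
  P0057 G0023          homozygote                chr1:44221:C>G unknown
  P0025 G0014 germline_double_hit chr1:26101:A>C;chr1:26161:T>A unknown
  P0045 G0005    germline_somatic                 chr1:8221:C>A unknown
```

and `demo/run/survival_os.tsv` holds per-gene hazard ratios with 95% CIs and
BH q-values. The same run is available from the shell:

```bash
lymphgerm simulate --out-dir demo/cohort --n-patients 200 --seed 42
lymphgerm run-all --config config.yaml
```

## Layout

- `lymphgerm.consensus` — normalization, BED exclusion, multi-caller merge
- `lymphgerm.prioritization` — popmax, impact classes, gene panel
- `lymphgerm.hit_structure` — homozygote/double-hit/second-hit/CHIP calls
- `lymphgerm.burden` — collapsing burden test, FDR, inflation factor
- `lymphgerm.cohort_stats` — carrier percentages, rates, fold enrichment,
  subgroup Fisher tests, annotation joins
- `lymphgerm.survival` — per-gene Cox screens
- `lymphgerm.synthetic_cohort` — study generator with planted ground truth
- `lymphgerm.evaluation` — calibration/power/recovery suites
- `lymphgerm.pipeline`, `lymphgerm.cli` — orchestration and `lymphgerm` CLI

See `docs/methods.md` for the statistical model, generator assumptions and
known limitations.
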