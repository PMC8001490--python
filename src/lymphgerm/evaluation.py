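"""Statistical evaluation suites over synthetic studies.

Each function simulates studies with a known planted structure and measures
how the analysis behaves: null calibration of the burden test (type-I error
and genomic inflation), power against a planted enriched gene, Cox
parameter recovery and null false-discovery behavior, exact recovery of
planted second-hit/CHIP events through the full file-based pipeline, and a
brute-force confirmation of the consensus caller.  The same entry points
back both the test suite and the reproduction script.
"""

from __future__ import annotations

import statistics as pystats
import tempfile
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd

from lymphgerm.burden import burden_test, genomic_lambda
from lymphgerm.consensus import load_excluded_regions, normalize_variant
from lymphgerm.pipeline import RunConfig, run_pipeline
from lymphgerm.survival import cox_association, screen_genes
from lymphgerm.burden import collapse_carriers
from lymphgerm.synthetic_cohort import (
    CohortSpec,
    control_counts_frame,
    generate_cohort,
    qualifying_from_simulation,
    simulate_cohort,
)


def _null_spec(seed: int, n_genes: int, n_cases: int) -> CohortSpec:
    return CohortSpec(
        n_patients=n_cases, n_genes=n_genes, panel_size=n_genes, seed=seed,
        compound_het_rate=0, homozygote_rate=0, chip_rate=0,
        somatic_second_hit_rate=0, loh_second_hit_rate=0,
        caller_sensitivity=1.0, qc_fail_rate=0.0, noise_rate=0.0,
    )


def null_burden_calibration(
    seed: int, n_genes: int = 2000, n_cases: int = 500
) -> dict:
    """Type-I error and inflation of the burden test under the global null."""
    sim = simulate_cohort(_null_spec(seed, n_genes, n_cases))
    qualifying = qualifying_from_simulation(sim)
    controls = control_counts_frame(sim)
    result = burden_test(
        qualifying, controls, n_cases=n_cases,
        n_controls=sim.spec.n_controls, model=None,
    )
    p = result["p"].to_numpy()
    return {
        "n_genes_tested": int(len(p)),
        "frac_p_lt_05": float((p < 0.05).mean()),
        "lambda": float(genomic_lambda(p)),
        "n_discoveries_q_lt_10": int((result["q"] < 0.1).sum()),
    }


def burden_power(
    seed: int,
    n_replicates: int = 50,
    n_cases: int = 500,
    n_genes: int = 100,
    enrichment: float = 10.0,
) -> dict:
    """Fraction of replicates in which a planted enriched gene reaches
    q < 0.1 against emulated public-control counts."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = _null_spec(rep_seed, n_genes, n_cases)
        spec.enriched_genes = [("G0001", enrichment)]
        sim = simulate_cohort(spec)
        qualifying = qualifying_from_simulation(sim)
        controls = control_counts_frame(sim)
        result = burden_test(
            qualifying, controls, n_cases=n_cases,
            n_controls=spec.n_controls, model=None,
        )
        row = result[result["gene"] == "G0001"]
        if len(row) and float(row["q"].iloc[0]) < 0.1:
            hits += 1
    return {"n_replicates": n_replicates, "power_q_lt_10": hits / n_replicates}


def cox_recovery(
    seed: int, n_replicates: int = 20, hr: float = 3.0, n_patients: int = 500
) -> dict:
    """Coverage of a planted carrier hazard ratio and null FDR behavior.

    Coverage arm: an all-CLL cohort with ~8% carriers of one gene and a
    planted OS hazard ratio; the fitted 95% CI should cover the truth in
    >= 90% of replicates.  Null arm: the same carrier structure with hazard
    ratio 1 screened against the cohort's other eligible genes; the gene's
    BH q should stay >= 0.1 in >= 90% of replicates.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    null_ok = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        spec = _null_spec(rep_seed, 40, n_patients)
        spec.subgroup_fractions = {"CLL": 1.0}
        spec.enriched_genes = [("G0001", 8.0)]
        spec.survival_genes = [("G0001", hr)]
        sim = simulate_cohort(spec)
        carriers = set(sim.truth.carriers.get("G0001", []))
        res = cox_association(sim.clinical, carriers, "OS")
        if res.ci95[0] <= hr <= res.ci95[1]:
            covered += 1

        null_seed = int(rng.integers(0, 2**31 - 1))
        null = _null_spec(null_seed, 40, n_patients)
        null.subgroup_fractions = {"CLL": 1.0}
        null.enriched_genes = [("G0001", 8.0)]  # frequent carrier, HR = 1
        nsim = simulate_cohort(null)
        gene_carriers = collapse_carriers(qualifying_from_simulation(nsim))
        results = screen_genes(
            nsim.clinical, gene_carriers, "OS", n_cll=n_patients
        )
        target = [r for r in results if r.gene == "G0001"]
        if not target or target[0].q is None or target[0].q >= 0.1:
            null_ok += 1
    return {
        "n_replicates": n_replicates,
        "coverage_frac": covered / n_replicates,
        "null_q_ge_10_frac": null_ok / n_replicates,
    }


def _event_sets(truth) -> dict[str, set]:
    return {
        "homozygote": {(t["patient"], t["gene"]) for t in truth.homozygotes},
        "germline_double_hit": {
            (t["patient"], t["gene"]) for t in truth.compound_hets
        },
        "germline_somatic": {
            (t["patient"], t["gene"]) for t in truth.germline_somatic
        },
        "loh_second_hit": {
            (t["patient"], t["gene"]) for t in truth.loh_second_hits
        },
        "chip": {(t["patient"], t["gene"]) for t in truth.chip},
    }


def event_recovery(seed: int, work_dir: str | Path | None = None) -> dict:
    """Precision and recall of planted events through the full file pipeline
    under noise-free generator settings (perfect caller sensitivity, no QC
    failures)."""
    spec = CohortSpec(
        n_patients=40, n_genes=30, panel_size=20, seed=seed,
        compound_het_rate=0.15, homozygote_rate=0.15, chip_rate=0.15,
        somatic_second_hit_rate=0.20, loh_second_hit_rate=0.10,
        caller_sensitivity=1.0, qc_fail_rate=0.0,
    )
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        bundle = generate_cohort(spec, Path(tmp) / "cohort")
        out = Path(tmp) / "run"
        cfg = RunConfig(
            vcf_dir=str(bundle.vcf_dir),
            reference_fasta=str(bundle.reference_fasta),
            popaf_table=str(bundle.popaf_table),
            cadd_table=str(bundle.cadd_table),
            consequence_table=str(bundle.consequence_table),
            clinical_table=str(bundle.clinical_table),
            panel_files={"panel": str(bundle.panel_file)},
            chip_gene_file=str(bundle.chip_gene_file),
            tumor_vaf_table=str(bundle.tumor_vaf_table),
            somatic_table=str(bundle.somatic_table),
            loh_table=str(bundle.loh_table),
            control_counts=str(bundle.control_counts),
            excluded_bed=str(bundle.excluded_bed),
            known_variants=str(bundle.known_variants),
            out_dir=str(out),
        )
        run_pipeline(cfg)
        events = pd.read_csv(out / "double_hits.tsv", sep="\t")
        chip = pd.read_csv(out / "chip_assessments.tsv", sep="\t")
        detected: dict[str, set] = defaultdict(set)
        for r in events.itertuples(index=False):
            detected[r.kind].add((r.patient, r.gene))
        for r in chip.itertuples(index=False):
            if r.verdict == "likely_chip":
                detected["chip"].add((r.patient, r.gene))
        truth_sets = _event_sets(bundle.truth)
    out_stats: dict[str, dict] = {}
    tp = fp = fn = 0
    for kind, truth_set in truth_sets.items():
        found = detected.get(kind, set())
        tp_k = len(found & truth_set)
        fp_k = len(found - truth_set)
        fn_k = len(truth_set - found)
        tp, fp, fn = tp + tp_k, fp + fp_k, fn + fn_k
        out_stats[kind] = {
            "n_planted": len(truth_set),
            "precision": tp_k / len(found) if found else 1.0,
            "recall": tp_k / len(truth_set) if truth_set else 1.0,
        }
    return {
        "per_kind": out_stats,
        "n_planted_total": tp + fn,
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
    }


def _scan_raw_vcfs(vcf_dir: Path, reference) -> dict:
    """Brute-force text scan of the per-caller VCFs: per (sample, variant),
    the list of supporting caller observations."""
    support: dict[tuple, list[dict]] = defaultdict(list)
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        patient, caller = path.name.split(".")[:2]
        for line in path.read_text().splitlines():
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, pos, _, ref, alt = fields[:5]
            fmt = dict(zip(fields[8].split(":"), fields[9].split(":")))
            key = normalize_variant(chrom, int(pos), ref, alt, reference)
            ref_d, alt_d = (int(x) for x in fmt["AD"].split(","))
            support[(patient, key)].append(
                {
                    "caller": caller,
                    "gq": float(fmt["GQ"]),
                    "dp": float(fmt["DP"]),
                    "ad": (ref_d, alt_d),
                }
            )
    return support


def consensus_oracle_check(
    seed: int, n_samples: int = 50, work_dir: str | Path | None = None
) -> dict:
    """Confirm every emitted consensus variant against a brute-force scan of
    the raw caller VCFs, and check threshold monotonicity."""
    import pyfaidx

    from lymphgerm.consensus import build_consensus, read_caller_vcf

    spec = CohortSpec(n_patients=n_samples, n_genes=25, panel_size=15, seed=seed)
    with tempfile.TemporaryDirectory(dir=work_dir) as tmp:
        bundle = generate_cohort(spec, Path(tmp) / "cohort")
        reference = pyfaidx.Fasta(str(bundle.reference_fasta), as_raw=True)
        observations = []
        for path in sorted(Path(bundle.vcf_dir).glob("*.vcf")):
            patient, caller = path.name.split(".")[:2]
            observations.extend(
                read_caller_vcf(path, caller, reference, sample=patient)
            )
        consensus = build_consensus(
            observations, excluded_regions=str(bundle.excluded_bed)
        )
        support = _scan_raw_vcfs(Path(bundle.vcf_dir), reference)
        regions = load_excluded_regions(bundle.excluded_bed)

        confirmed = 0
        for v in consensus:
            raw = support.get((v.sample, v.key), [])
            if len(raw) < 2:
                continue
            gq = pystats.median(o["gq"] for o in raw)
            dp = pystats.median(o["dp"] for o in raw)
            ref_d = sum(o["ad"][0] for o in raw)
            alt_d = sum(o["ad"][1] for o in raw)
            vaf = alt_d / (ref_d + alt_d) if ref_d + alt_d else 0.0
            tree = regions.get(v.key.chrom)
            outside = not (tree and tree[v.key.pos - 1])
            if gq >= 30 and dp >= 10 and vaf >= 0.30 and outside:
                confirmed += 1

        monotone = True
        baseline_keys = {(v.sample, v.key) for v in consensus}
        for kwargs in (
            {"min_callers": 3}, {"min_gq": 50}, {"min_dp": 20}, {"min_vaf": 0.4}
        ):
            tight = build_consensus(
                observations, excluded_regions=str(bundle.excluded_bed), **kwargs
            )
            tight_keys = {(v.sample, v.key) for v in tight}
            if not tight_keys <= baseline_keys or len(tight) > len(consensus):
                monotone = False
    return {
        "n_consensus": len(consensus),
        "n_confirmed": confirmed,
        "confirmed_fraction": confirmed / len(consensus) if consensus else 1.0,
        "monotone": monotone,
    }
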