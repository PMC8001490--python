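"""End-to-end orchestration: consensus → prioritization → CHIP filter →
double-hit detection → burden test → cohort statistics → survival screen.

Every numeric threshold of the analysis lives in :class:`RunConfig` with the
published defaults (2 callers, GQ 30, DP 10, VAF 0.30, popmax 0.5%, CADD 20,
CHIP tumor VAF 0.05, carrier frequency 1%, FDR 0.1).  A run writes TSV/JSON
reports plus a machine-readable manifest with input checksums, thresholds and
a per-stage variant-count funnel; given identical inputs and config the
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx
import yaml

from lymphgerm import __version__
from lymphgerm.burden import burden_test
from lymphgerm.cohort_stats import cohort_summary
from lymphgerm.consensus import build_consensus, consensus_to_frame, read_caller_vcf
from lymphgerm.hit_structure import (
    assess_chip,
    detect_germline_double_hits,
    detect_homozygotes,
    detect_somatic_second_hits,
    events_to_frame,
    remove_chip,
)
from lymphgerm.prioritization import (
    build_gene_panel,
    prioritize,
    qualifying_to_frame,
    read_gene_list,
)
from lymphgerm.survival import results_to_frame, screen_genes
from lymphgerm.burden import collapse_carriers

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    vcf_dir: str
    reference_fasta: str
    popaf_table: str
    cadd_table: str
    consequence_table: str
    clinical_table: str
    panel_files: dict[str, str] = field(default_factory=dict)
    chip_gene_file: str | None = None
    tumor_vaf_table: str | None = None
    somatic_table: str | None = None
    loh_table: str | None = None
    control_counts: str | None = None
    excluded_bed: str | None = None
    known_variants: str | None = None
    out_dir: str = "lymphgerm_run"
    min_callers: int = 2
    min_gq: float = 30.0
    min_dp: float = 10.0
    min_vaf: float = 0.30
    popmax_max: float = 0.005
    cadd_min: float = 20.0
    popmax_exclusions: tuple[str, ...] = ()
    chip_tumor_vaf: float = 0.05
    min_carrier_freq: float = 0.01
    fdr_threshold: float = 0.1
    n_controls: int = 15708
    burden_models: tuple[str, ...] = ("ptv_only", "ptv_plus_high_impact")
    survival_model: str | None = None  # None = all qualifying categories
    seed: int = 0

    def __post_init__(self) -> None:
        for name, low, high in (
            ("min_callers", 1, 10), ("min_gq", 0, 99), ("min_dp", 0, 10000),
            ("min_vaf", 0.0, 1.0), ("popmax_max", 0.0, 1.0),
            ("cadd_min", 0.0, 99.0), ("chip_tumor_vaf", 0.0, 1.0),
            ("min_carrier_freq", 0.0, 1.0), ("fdr_threshold", 0.0, 1.0),
        ):
            value = getattr(self, name)
            if not low <= value <= high:
                raise ValueError(f"{name}={value} outside [{low}, {high}]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("popmax_exclusions", "burden_models"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_annotations(
    popaf_table: str | Path, cadd_table: str | Path, consequence_table: str | Path
) -> pd.DataFrame:
    """Merge population-AF, CADD and consequence tables on variant identity."""
    keys = ["chrom", "pos", "ref", "alt"]
    pop = pd.read_csv(popaf_table, sep="\t")
    cadd = pd.read_csv(cadd_table, sep="\t")
    cons = pd.read_csv(consequence_table, sep="\t")
    af_cols = [c for c in pop.columns if c.startswith("af_")]
    merged = cons.merge(cadd, on=keys, how="left").merge(
        pop[keys + af_cols], on=keys, how="left"
    )
    return merged


def discover_vcfs(vcf_dir: str | Path) -> dict[str, dict[str, Path]]:
    """Map patient → caller → VCF path for files named ``{patient}.{caller}.vcf``."""
    out: dict[str, dict[str, Path]] = {}
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        parts = path.name.split(".")
        if len(parts) < 3:
            continue
        patient, caller = parts[0], parts[1]
        out.setdefault(patient, {})[caller] = path
    if not out:
        raise FileNotFoundError(f"no per-caller VCFs found under {vcf_dir}")
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    funnel: dict[str, int] = {}
    notices: list[str] = []
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": funnel,
        "notices": notices,
        "complete": False,
    }

    # ---------------------------------------------------------- consensus
    try:
        reference = pyfaidx.Fasta(config.reference_fasta, as_raw=True)
        vcfs = discover_vcfs(config.vcf_dir)
        observations = []
        for patient in sorted(vcfs):
            for caller in sorted(vcfs[patient]):
                observations.extend(
                    read_caller_vcf(vcfs[patient][caller], caller, reference, sample=patient)
                )
        funnel["caller_observations"] = len(observations)
        consensus = build_consensus(
            observations,
            excluded_regions=config.excluded_bed,
            min_callers=config.min_callers,
            min_gq=config.min_gq,
            min_dp=config.min_dp,
            min_vaf=config.min_vaf,
        )
        funnel["consensus_variants"] = len(consensus)
        consensus_to_frame(consensus).to_csv(out / "consensus.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("consensus", exc) from exc

    # ------------------------------------------------------ prioritization
    try:
        annotations = load_annotations(
            config.popaf_table, config.cadd_table, config.consequence_table
        )
        panel = None
        if config.panel_files:
            panel = build_gene_panel(
                {label: read_gene_list(p) for label, p in config.panel_files.items()}
            )
        known = None
        if config.known_variants:
            kv = pd.read_csv(config.known_variants, sep="\t")
            known = {
                (r.chrom, r.pos, r.ref, r.alt) for r in kv.itertuples(index=False)
            }
        qualifying, background = prioritize(
            consensus,
            annotations,
            panel=panel,
            cadd_min=config.cadd_min,
            popmax_max=config.popmax_max,
            excluded_populations=config.popmax_exclusions,
            known_variants=known,
        )
        funnel["qualifying_panel"] = len(qualifying)
        funnel["qualifying_background"] = len(background)
    except Exception as exc:
        raise StageError("prioritization", exc) from exc

    # ------------------------------------------------------------ CHIP
    try:
        if config.chip_gene_file and config.tumor_vaf_table:
            chip_genes = read_gene_list(config.chip_gene_file)
            tumor = pd.read_csv(config.tumor_vaf_table, sep="\t")
            assessments = assess_chip(
                qualifying, chip_genes, tumor,
                tumor_absent_threshold=config.chip_tumor_vaf,
            )
            qualifying = remove_chip(qualifying, assessments)
            funnel["chip_flagged"] = sum(
                a.verdict == "likely_chip" for a in assessments
            )
            pd.DataFrame(
                [
                    {
                        "patient": a.patient, "gene": a.gene,
                        "chrom": a.key.chrom, "pos": a.key.pos,
                        "ref": a.key.ref, "alt": a.key.alt,
                        "tumor_vaf": a.tumor_vaf, "verdict": a.verdict,
                        "assessable": a.assessable,
                    }
                    for a in assessments
                ]
            ).to_csv(out / "chip_assessments.tsv", sep="\t", index=False)
        else:
            notices.append("CHIP stage skipped: no CHIP gene list / tumor VAF table")
        funnel["qualifying_after_chip"] = len(qualifying)
        qualifying_to_frame(qualifying).to_csv(
            out / "qualifying.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise StageError("chip", exc) from exc

    # ------------------------------------------------------- double hits
    try:
        events = list(detect_homozygotes(qualifying))
        events += detect_germline_double_hits(qualifying)
        somatic = (
            pd.read_csv(config.somatic_table, sep="\t")
            if config.somatic_table
            else None
        )
        loh = pd.read_csv(config.loh_table, sep="\t") if config.loh_table else None
        events += detect_somatic_second_hits(qualifying, somatic, loh)
        funnel["double_hit_events"] = len(events)
        events_to_frame(events).to_csv(out / "double_hits.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("doublehit", exc) from exc

    # ------------------------------------------------------------ burden
    clinical = pd.read_csv(config.clinical_table, sep="\t")
    n_cases = len(clinical)
    try:
        if config.control_counts and Path(config.control_counts).exists():
            controls = pd.read_csv(config.control_counts, sep="\t")
            for model in config.burden_models:
                result = burden_test(
                    qualifying, controls, n_cases=n_cases,
                    n_controls=config.n_controls, model=model,
                )
                result.to_csv(out / f"burden_{model}.tsv", sep="\t", index=False)
                funnel[f"burden_{model}_genes"] = len(result)
                manifest[f"lambda_{model}"] = result.attrs.get("lambda")
        else:
            notices.append("burden stage skipped: control-count table missing")
    except Exception as exc:
        raise StageError("burden", exc) from exc

    # ------------------------------------------------------- cohort stats
    try:
        n_panel = len(panel) if panel else len({v.gene for v in qualifying})
        summary = cohort_summary(
            qualifying, n_patients=n_cases,
            n_panel_genes=max(n_panel, 1),
        )
        (out / "cohort_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise StageError("stats", exc) from exc

    # ---------------------------------------------------------- survival
    try:
        cll = clinical[clinical["subgroup"] == "CLL"].reset_index(drop=True)
        if len(cll) >= 10 and cll["os_event"].sum() >= 2:
            carriers = collapse_carriers(qualifying, model=config.survival_model)
            for outcome in ("TTFT", "OS"):
                results = screen_genes(
                    cll, carriers, outcome,
                    min_frequency=config.min_carrier_freq, n_cll=len(cll),
                )
                results_to_frame(results).to_csv(
                    out / f"survival_{outcome.lower()}.tsv", sep="\t", index=False
                )
                funnel[f"survival_{outcome.lower()}_genes"] = len(results)
        else:
            notices.append("survival stage skipped: too few CLL cases or events")
    except Exception as exc:
        raise StageError("survival", exc) from exc

    # ---------------------------------------------------------- manifest
    inputs = {}
    for name in (
        "reference_fasta", "popaf_table", "cadd_table", "consequence_table",
        "clinical_table", "control_counts", "excluded_bed", "somatic_table",
        "loh_table", "tumor_vaf_table", "chip_gene_file", "known_variants",
    ):
        path = getattr(config, name)
        if path and Path(path).exists():
            inputs[name] = _sha256(path)
    manifest["input_checksums"] = inputs
    manifest["complete"] = True
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
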