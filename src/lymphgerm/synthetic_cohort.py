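"""Synthetic study generator.

Emulates everything the analysis consumes — per-caller germline VCFs,
population allele-frequency / CADD / consequence annotation tables, an
excluded-region BED, somatic mutation and LOH segment tables, tumor-
compartment VAFs for CHIP-gene variants, control site-frequency counts, and
a clinical table with two survival endpoints — together with a ground-truth
record of every planted signal, so each downstream stage can be tested for
exact recovery and statistical calibration without controlled-access data.

The cohort model: each patient carries, independently per gene, a qualifying
variant with probability ``background_qualifying_rate`` (times a per-gene
enrichment multiplier), drawn from a small pool of recurrent segregating
variants per gene.  On top of this background the generator plants compound
heterozygotes, homozygotes, CHIP mosaics (high blood VAF, near-zero tumor
VAF), somatic second hits, and LOH second hits at configured per-patient
rates, and exponential survival times whose log-hazard includes planted
per-gene carrier effects and clinical covariates.  Four pseudo-callers each
detect every true variant independently with probability
``caller_sensitivity``; one of them spells indels un-normalized (anchored
with extra reference bases) to exercise cross-caller normalization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from lymphgerm.consensus import VariantKey, normalize_variant

CALLERS = ("callerA", "callerB", "callerC", "callerD")
#: The caller that emits right-anchored, non-parsimonious indel records.
UNNORMALIZED_CALLER = "callerD"

POPULATIONS = ("NFE", "AFR", "AMR", "EAS", "SAS", "FIN", "ASJ", "OTH")

#: Default variant-type mix of the qualifying pool (percent).
DEFAULT_TYPE_MIX: dict[str, float] = {
    "missense": 93.50,
    "stop_gained": 2.40,
    "frameshift_deletion": 1.60,
    "frameshift_insertion": 0.80,
    "splice_donor": 0.80,
    "splice_acceptor": 0.40,
    "inframe_deletion": 0.20,
    "stop_lost": 0.10,
    "inframe_insertion": 0.10,
    "start_lost": 0.10,
}

#: Generator type → consequence term of the prioritization stage.
TYPE_TO_CONSEQUENCE = {
    "missense": "missense",
    "stop_gained": "stop_gained",
    "frameshift_deletion": "frameshift",
    "frameshift_insertion": "frameshift",
    "splice_donor": "splice_donor",
    "splice_acceptor": "splice_acceptor",
    "inframe_deletion": "inframe_deletion",
    "stop_lost": "stop_lost",
    "start_lost": "start_lost",
    "inframe_insertion": "inframe_insertion",
    "synonymous": "synonymous",
}

_GENE_WINDOW = 2000  # bp of reference per gene
_POOL_SIZE = 4  # recurrent qualifying variants per gene

_BASES = np.array(list("ACGT"))


@dataclass
class CohortSpec:
    """Configuration of one synthetic study.

    Defaults describe a scaled-down cohort with the study's structure: a
    CLL-dominated two-subgroup mix (504:222), a curated panel inside a larger
    gene space, ~1% per-gene qualifying carrier probability, and per-patient
    rates for compound hets / homozygotes / CHIP / somatic second hits chosen
    to match their observed per-patient frequencies (≈2.1%, 1.7%, 1.4%,
    2.3%).
    """

    n_patients: int = 50
    subgroup_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"CLL": 504 / 726, "lymphoma": 222 / 726}
    )
    n_genes: int = 100
    panel_size: int = 60
    background_qualifying_rate: float = 0.01
    enriched_genes: Sequence[tuple[str, float]] = ()
    survival_genes: Sequence[tuple[str, float]] = ()
    chip_rate: float = 10 / 726
    compound_het_rate: float = 15 / 726
    homozygote_rate: float = 12 / 726
    somatic_second_hit_rate: float = 17 / 726
    loh_second_hit_rate: float = 1 / 726
    caller_sensitivity: float = 0.95
    qc_fail_rate: float = 0.05
    noise_rate: float = 0.005
    novel_fraction: float = 0.4475
    variant_type_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    n_controls: int = 15708
    # Covariate log-hazards: (IGHV-unmutated, stage) for TTFT,
    # (IGHV-unmutated, per-year age) for OS.
    ttft_covariate_betas: tuple[float, float] = (0.8, 0.3)
    os_covariate_betas: tuple[float, float] = (0.8, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 < self.panel_size <= self.n_genes):
            raise ValueError("panel must be non-empty and within n_genes")
        total = sum(self.subgroup_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("subgroup fractions must sum to 1")
        for name in (
            "background_qualifying_rate", "chip_rate", "compound_het_rate",
            "homozygote_rate", "somatic_second_hit_rate", "loh_second_hit_rate",
            "caller_sensitivity", "qc_fail_rate", "noise_rate", "novel_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for gene, hr in self.survival_genes:
            if hr <= 0:
                raise ValueError(f"hazard ratio for {gene} must be > 0")
        for gene, mult in self.enriched_genes:
            if mult < 0:
                raise ValueError(f"enrichment multiplier for {gene} must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of planted structure, for parameter-recovery tests."""

    carriers: dict[str, list[str]]  # gene -> qualifying-variant carriers
    homozygotes: list[dict]  # {patient, gene, variant}
    compound_hets: list[dict]  # {patient, gene, variants}
    chip: list[dict]  # {patient, gene, variant}
    germline_somatic: list[dict]  # {patient, gene}
    loh_second_hits: list[dict]  # {patient, gene, variant}
    survival_log_hr: dict[str, float]  # gene -> planted log hazard ratio
    covariate_betas: dict[str, list[float]]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    """In-memory form of a generated study (files are written on demand)."""

    spec: CohortSpec
    reference: dict[str, str]
    genes: pd.DataFrame  # gene, chrom, start, is_panel, is_chip
    catalog: pd.DataFrame  # variant catalog (one row per distinct variant)
    occurrences: pd.DataFrame  # one row per patient x variant
    clinical: pd.DataFrame
    somatic: pd.DataFrame
    loh: pd.DataFrame
    excluded_bed: list[tuple[str, int, int]]
    panel_genes: list[str]
    chip_genes: list[str]
    truth: SyntheticTruth


@dataclass
class CohortBundle:
    """File layout of a written study."""

    root: Path
    reference_fasta: Path
    vcf_dir: Path
    popaf_table: Path
    cadd_table: Path
    consequence_table: Path
    known_variants: Path
    pathogenic_table: Path
    control_counts: Path
    excluded_bed: Path
    somatic_table: Path
    loh_table: Path
    tumor_vaf_table: Path
    clinical_table: Path
    panel_file: Path
    chip_gene_file: Path
    truth_json: Path
    truth: SyntheticTruth
    callers: tuple[str, ...] = CALLERS


def _key_str(key: VariantKey) -> str:
    return f"{key.chrom}:{key.pos}:{key.ref}>{key.alt}"


def _draw_snv_alt(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(0, 3)]


def _make_alleles(
    rng: np.random.Generator, seq: str, pos: int, vtype: str
) -> tuple[int, str, str]:
    """Raw (possibly non-normalized) alleles for a generator variant type."""
    base = seq[pos - 1]
    if vtype in ("frameshift_deletion", "inframe_deletion"):
        length = 3 if vtype == "inframe_deletion" else int(rng.integers(1, 3))
        ref = seq[pos - 1 : pos + length]
        return pos, ref, ref[0]
    if vtype in ("frameshift_insertion", "inframe_insertion"):
        length = 3 if vtype == "inframe_insertion" else int(rng.integers(1, 3))
        ins = "".join(_BASES[rng.integers(0, 4, size=length)])
        return pos, base, base + ins
    return pos, base, _draw_snv_alt(rng, base)


def _simulate_reference(rng: np.random.Generator, n_genes: int) -> dict[str, str]:
    length = n_genes * _GENE_WINDOW + 200
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return {"chr1": seq}


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the full study in memory (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    n_pat, n_genes = spec.n_patients, spec.n_genes
    patients = [f"P{i:04d}" for i in range(1, n_pat + 1)]
    gene_names = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    panel_genes = gene_names[: spec.panel_size]
    chip_genes = panel_genes[: min(22, spec.panel_size)]

    reference = _simulate_reference(rng, n_genes)
    seq = reference["chr1"]
    gene_start = {g: i * _GENE_WINDOW + 1 for i, g in enumerate(gene_names)}
    genes = pd.DataFrame(
        {
            "gene": gene_names,
            "chrom": "chr1",
            "start": [gene_start[g] for g in gene_names],
            "end": [gene_start[g] + _GENE_WINDOW - 1 for g in gene_names],
            "is_panel": [g in set(panel_genes) for g in gene_names],
            "is_chip": [g in set(chip_genes) for g in gene_names],
        }
    )

    # Excluded-region track: one interval per gene window (BED, 0-based).
    excluded_bed = [
        ("chr1", gene_start[g] - 1 + 1495, gene_start[g] - 1 + 1530)
        for g in gene_names
    ]

    # ------------------------------------------------------------------ catalog
    mix_terms = sorted(spec.variant_type_mix)
    mix_p = np.array([spec.variant_type_mix[t] for t in mix_terms], dtype=float)
    mix_p = mix_p / mix_p.sum()

    rows: list[dict] = []
    used_keys: set[VariantKey] = set()

    def _catalog_variant(
        gene: str, offset: int, vtype: str, role: str, cadd: float,
        rare: bool = True, fin_common: bool = False, common: bool = False,
    ) -> int:
        pos0 = gene_start[gene] + offset
        for attempt in range(8):
            raw_pos, ref, alt = _make_alleles(rng, seq, pos0 + attempt, vtype)
            key = normalize_variant("chr1", raw_pos, ref, alt, reference)
            if key not in used_keys:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place a unique variant")
        used_keys.add(key)
        novel = rare and bool(rng.random() < spec.novel_fraction)
        afs = {}
        if common:
            base_af = float(rng.uniform(0.01, 0.10))
        elif novel:
            base_af = 0.0
        elif rare:
            base_af = float(rng.uniform(1e-5, 0.004))
        else:
            base_af = float(rng.uniform(1e-5, 0.004))
        for pop in POPULATIONS:
            if pop in ("FIN", "ASJ") and fin_common:
                afs[f"af_{pop}"] = float(rng.uniform(0.006, 0.03))
            else:
                afs[f"af_{pop}"] = base_af * float(rng.uniform(0.0, 1.0)) if pop != "NFE" else base_af
        rows.append(
            {
                "var_id": len(rows),
                "gene": gene,
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "variant_type": vtype,
                "consequence": TYPE_TO_CONSEQUENCE[vtype],
                "high_impact_extra": vtype in ("inframe_deletion", "inframe_insertion"),
                "cadd_phred": cadd,
                "role": role,
                "novel": novel,
                "rsid": "" if novel else f"rs{900000 + len(rows)}",
                "pathogenic_flag": (
                    "cosmic_pathogenic" if (role == "pool" and rng.random() < 0.1) else ""
                ),
                **afs,
            }
        )
        return len(rows) - 1

    pool_ids: dict[str, list[int]] = {}
    chip_var: dict[str, int] = {}
    noise_ids: dict[str, list[int]] = {}
    for gene in gene_names:
        ids = []
        for j in range(_POOL_SIZE):
            vtype = mix_terms[int(rng.choice(len(mix_terms), p=mix_p))]
            cadd = float(rng.uniform(20.5, 45.0)) if vtype == "missense" else float(
                rng.uniform(15.0, 50.0)
            )
            ids.append(_catalog_variant(gene, 100 + 60 * j, vtype, "pool", cadd))
        pool_ids[gene] = ids
        if gene in set(chip_genes):
            chip_var[gene] = _catalog_variant(
                gene, 600, "missense", "chip", float(rng.uniform(22.0, 40.0))
            )
        nid = [
            _catalog_variant(gene, 800, "missense", "noise_common",
                             float(rng.uniform(21.0, 35.0)), rare=False, common=True),
            _catalog_variant(gene, 860, "missense", "noise_lowcadd",
                             float(rng.uniform(1.0, 15.0))),
            _catalog_variant(gene, 920, "synonymous", "noise_synonymous",
                             float(rng.uniform(0.5, 8.0))),
            _catalog_variant(gene, 980, "missense", "noise_fin_common",
                             float(rng.uniform(21.0, 35.0)), fin_common=True),
            _catalog_variant(gene, 1505, "missense", "noise_excluded",
                             float(rng.uniform(21.0, 35.0))),
        ]
        noise_ids[gene] = nid

    catalog = pd.DataFrame(rows)

    # Control site-frequency counts for qualifying-capable variants.
    control_an = 2 * spec.n_controls
    per_variant_rate = spec.background_qualifying_rate / 2.0 / _POOL_SIZE
    control_ac = np.zeros(len(catalog), dtype=int)
    qualifying_roles = catalog["role"].isin(["pool", "chip"]).to_numpy()
    n_q = int(qualifying_roles.sum())
    control_ac[qualifying_roles] = rng.binomial(control_an, per_variant_rate, size=n_q)
    catalog["control_ac"] = control_ac
    catalog["control_an"] = np.where(qualifying_roles, control_an, 0)

    # ------------------------------------------------------------- clinical
    sub_labels = sorted(spec.subgroup_fractions)
    sub_p = np.array([spec.subgroup_fractions[s] for s in sub_labels])
    subgroup = [sub_labels[i] for i in rng.choice(len(sub_labels), size=n_pat, p=sub_p)]
    age = np.clip(rng.normal(65.0, 10.0, size=n_pat), 25.0, 90.0)
    stage = rng.integers(1, 5, size=n_pat)
    is_cll = np.array([s == "CLL" for s in subgroup])
    ighv_roll = rng.random(n_pat)
    ighv_status = np.where(
        ~is_cll, "missing",
        np.where(ighv_roll < 0.02, "missing",
                 np.where(ighv_roll < 0.02 + 0.45, "unmutated", "mutated")),
    )
    is_mbl = np.where(is_cll, (rng.random(n_pat) < 54 / 504).astype(float), np.nan)

    # -------------------------------------------------- carriers & occurrences
    mult = {g: 1.0 for g in gene_names}
    for gene, m in spec.enriched_genes:
        if gene not in mult:
            raise ValueError(f"enriched gene {gene!r} not in gene space")
        mult[gene] = m
    p_gene = np.array(
        [min(1.0, spec.background_qualifying_rate * mult[g]) for g in gene_names]
    )
    carrier_matrix = rng.random((n_pat, n_genes)) < p_gene[None, :]

    occ_rows: list[dict] = []
    homozygotes: list[dict] = []
    compound_hets: list[dict] = []
    chip_truth: list[dict] = []

    def _add_occurrence(pi: int, var_id: int, zygosity: str, role: str,
                        tumor_vaf: float | None = None) -> None:
        occ_rows.append(
            {
                "patient": patients[pi],
                "var_id": var_id,
                "zygosity": zygosity,
                "role": role,
                "tumor_vaf": tumor_vaf,
            }
        )

    # Planted multi-hit structure (overrides the background matrix per gene).
    event_roll = rng.random((n_pat, 3))
    planted_gene_choice = rng.integers(0, len(panel_genes), size=(n_pat, 3))
    for pi in range(n_pat):
        if event_roll[pi, 0] < spec.compound_het_rate:
            gene = panel_genes[planted_gene_choice[pi, 0]]
            carrier_matrix[pi, gene_names.index(gene)] = False
            a, b = pool_ids[gene][0], pool_ids[gene][1]
            _add_occurrence(pi, a, "het", "compound_het")
            _add_occurrence(pi, b, "het", "compound_het")
            compound_hets.append(
                {"patient": patients[pi], "gene": gene,
                 "variants": [_key_str(_catalog_key(catalog, v)) for v in (a, b)]}
            )
        if event_roll[pi, 1] < spec.homozygote_rate:
            gene = panel_genes[planted_gene_choice[pi, 1]]
            gi = gene_names.index(gene)
            if any(
                r["patient"] == patients[pi] and catalog.at[r["var_id"], "gene"] == gene
                for r in occ_rows
            ):
                gene = panel_genes[(planted_gene_choice[pi, 1] + 1) % len(panel_genes)]
                gi = gene_names.index(gene)
            carrier_matrix[pi, gi] = False
            v = pool_ids[gene][2]
            _add_occurrence(pi, v, "hom_alt", "homozygote")
            homozygotes.append(
                {"patient": patients[pi], "gene": gene,
                 "variant": _key_str(_catalog_key(catalog, v))}
            )
        if event_roll[pi, 2] < spec.chip_rate and chip_genes:
            gene = chip_genes[int(rng.integers(0, len(chip_genes)))]
            v = chip_var[gene]
            _add_occurrence(pi, v, "het", "chip", tumor_vaf=float(rng.uniform(0.0, 0.02)))
            chip_truth.append(
                {"patient": patients[pi], "gene": gene,
                 "variant": _key_str(_catalog_key(catalog, v))}
            )

    # Background single-variant carriers.
    slot_choice = rng.integers(0, _POOL_SIZE, size=(n_pat, n_genes))
    planted_pairs = {
        (r["patient"], catalog.at[r["var_id"], "gene"]) for r in occ_rows
    }
    for pi in range(n_pat):
        for gi in np.nonzero(carrier_matrix[pi])[0]:
            gene = gene_names[gi]
            if (patients[pi], gene) in planted_pairs:
                continue
            _add_occurrence(pi, pool_ids[gene][slot_choice[pi, gi]], "het", "background")

    # Noise occurrences (filtered out by one rule or another downstream).
    if spec.noise_rate > 0:
        noise_roll = rng.random((n_pat, n_genes, 5))
        for pi in range(n_pat):
            for gi in range(n_genes):
                for si in range(5):
                    if noise_roll[pi, gi, si] < spec.noise_rate:
                        _add_occurrence(
                            pi, noise_ids[gene_names[gi]][si], "het", "noise"
                        )

    occurrences = pd.DataFrame(
        occ_rows,
        columns=["patient", "var_id", "zygosity", "role", "tumor_vaf"],
    )

    # Per-occurrence QC values and caller detection (vectorized).
    n_occ = len(occurrences)
    is_hom = (occurrences["zygosity"] == "hom_alt").to_numpy()
    is_chip_occ = (occurrences["role"] == "chip").to_numpy()
    vaf = rng.beta(60, 60, size=n_occ)
    vaf[is_hom] = rng.beta(95, 5, size=int(is_hom.sum()))
    vaf[is_chip_occ] = rng.uniform(0.35, 0.45, size=int(is_chip_occ.sum()))
    dp = rng.poisson(35, size=n_occ) + 12
    gq = rng.integers(40, 100, size=n_occ).astype(float)
    qc_fail = rng.random(n_occ) < spec.qc_fail_rate
    fail_mode = rng.integers(0, 3, size=n_occ)
    gq[qc_fail & (fail_mode == 0)] = rng.uniform(5, 25, size=int((qc_fail & (fail_mode == 0)).sum()))
    dp_fail = qc_fail & (fail_mode == 1)
    dp[dp_fail] = rng.integers(2, 9, size=int(dp_fail.sum()))
    vaf_fail = qc_fail & (fail_mode == 2)
    vaf[vaf_fail] = rng.uniform(0.05, 0.25, size=int(vaf_fail.sum()))
    detected = rng.random((n_occ, len(CALLERS))) < spec.caller_sensitivity
    none_det = ~detected.any(axis=1)
    if none_det.any():  # every true variant appears in >= 1 caller's output
        forced = rng.integers(0, len(CALLERS), size=int(none_det.sum()))
        detected[np.nonzero(none_det)[0], forced] = True

    occurrences["vaf"] = np.round(vaf, 4)
    occurrences["dp"] = dp
    occurrences["gq"] = np.round(gq, 1)
    occurrences["qc_fail"] = qc_fail
    for ci, caller in enumerate(CALLERS):
        occurrences[f"det_{caller}"] = detected[:, ci]
    # Tumor-compartment VAF for every call in a CHIP gene: mosaics near zero,
    # true germline concordant with the blood compartment.
    in_chip_gene = catalog.set_index("var_id").loc[
        occurrences["var_id"], "gene"
    ].isin(set(chip_genes)).to_numpy()
    tumor = np.full(n_occ, np.nan)
    tumor[in_chip_gene] = np.clip(
        vaf[in_chip_gene] + rng.normal(0.0, 0.03, size=int(in_chip_gene.sum())),
        0.05, 0.95,
    )
    planted_tumor = occurrences["tumor_vaf"].to_numpy(dtype=float)
    tumor = np.where(~np.isnan(planted_tumor), planted_tumor, tumor)
    occurrences["tumor_vaf"] = np.round(tumor, 4)

    # --------------------------------------- somatic second hits & LOH events
    occ_gene = catalog.set_index("var_id")["gene"]
    germline_by_patient: dict[str, set[str]] = {p: set() for p in patients}
    qualifying_occ = occurrences[occurrences["role"].isin(
        ["background", "compound_het", "homozygote"]
    )]
    for r in qualifying_occ.itertuples(index=False):
        germline_by_patient[r.patient].add(occ_gene[r.var_id])

    somatic_rows: list[dict] = []
    loh_rows: list[dict] = []
    germline_somatic: list[dict] = []
    loh_truth: list[dict] = []
    # Second hits pair with panel-gene germline variants only: the analysis
    # joins somatic/LOH evidence against the panel qualifying stream.
    panel_set = set(panel_genes)
    second_roll = rng.random((n_pat, 2))
    for pi, patient in enumerate(patients):
        hit_genes = sorted(germline_by_patient[patient] & panel_set)
        if second_roll[pi, 0] < spec.somatic_second_hit_rate:
            if not hit_genes:  # plant a germline variant to pair with
                gene = panel_genes[int(rng.integers(0, len(panel_genes)))]
                _plant_background(occurrences, pool_ids, rng, patient, gene)
                hit_genes = [gene]
                germline_by_patient[patient].add(gene)
            gene = hit_genes[int(rng.integers(0, len(hit_genes)))]
            pos = gene_start[gene] + int(rng.integers(200, 1400))
            somatic_rows.append(
                {"patient": patient, "gene": gene, "chrom": "chr1", "pos": pos,
                 "ref": seq[pos - 1], "alt": _draw_snv_alt(rng, seq[pos - 1])}
            )
            germline_somatic.append({"patient": patient, "gene": gene})
        loh_candidates = sorted(germline_by_patient[patient] & panel_set)
        if second_roll[pi, 1] < spec.loh_second_hit_rate and loh_candidates:
            gene = loh_candidates[int(rng.integers(0, len(loh_candidates)))]
            loh_rows.append(
                {"patient": patient, "chrom": "chr1",
                 "start": gene_start[gene], "end": gene_start[gene] + _GENE_WINDOW - 1,
                 "type": "copy_neutral_loh"}
            )
            keys = [
                _key_str(_catalog_key(catalog, r.var_id))
                for r in occurrences.itertuples(index=False)
                if r.patient == patient and occ_gene[r.var_id] == gene
                and r.role in ("background", "compound_het", "homozygote")
            ]
            loh_truth.append({"patient": patient, "gene": gene, "variant": keys[0]})

    # Background somatic mutations / LOH segments unrelated to germline hits:
    # placed only in genes where the patient carries no qualifying variant so
    # they never create an unplanned second-hit event.
    bg_somatic_roll = rng.random(n_pat)
    for pi, patient in enumerate(patients):
        if bg_somatic_roll[pi] < 0.08:
            free = [g for g in gene_names if g not in germline_by_patient[patient]]
            if free:
                gene = free[int(rng.integers(0, len(free)))]
                pos = gene_start[gene] + int(rng.integers(200, 1400))
                somatic_rows.append(
                    {"patient": patient, "gene": gene, "chrom": "chr1", "pos": pos,
                     "ref": seq[pos - 1], "alt": _draw_snv_alt(rng, seq[pos - 1])}
                )

    somatic = pd.DataFrame(
        somatic_rows, columns=["patient", "gene", "chrom", "pos", "ref", "alt"]
    )
    loh = pd.DataFrame(loh_rows, columns=["patient", "chrom", "start", "end", "type"])

    # ------------------------------------------------------------- survival
    log_hr = {g: 0.0 for g in gene_names}
    for gene, hr in spec.survival_genes:
        if gene not in log_hr:
            raise ValueError(f"survival gene {gene!r} not in gene space")
        log_hr[gene] = math.log(hr)
    carrier_sets: dict[str, set[str]] = {g: set() for g in gene_names}
    for r in occurrences.itertuples(index=False):
        if r.role in ("background", "compound_het", "homozygote"):
            carrier_sets[occ_gene[r.var_id]].add(r.patient)

    ighv_unmut = np.where(
        ighv_status == "missing", np.nan, (ighv_status == "unmutated").astype(float)
    )
    gene_effect = np.zeros(n_pat)
    for gene, lhr in log_hr.items():
        if lhr != 0.0 and carrier_sets[gene]:
            idx = [patients.index(p) for p in carrier_sets[gene]]
            gene_effect[idx] += lhr
    ighv_for_hazard = np.nan_to_num(ighv_unmut, nan=0.5)
    b_ighv_t, b_stage = spec.ttft_covariate_betas
    b_ighv_o, b_age = spec.os_covariate_betas
    lp_ttft = b_ighv_t * ighv_for_hazard + b_stage * (stage - 2.5) + gene_effect
    lp_os = b_ighv_o * ighv_for_hazard + b_age * (age - 65.0) + gene_effect
    t_ttft = rng.exponential(1.0 / (0.15 * np.exp(lp_ttft)))
    t_os = rng.exponential(1.0 / (0.05 * np.exp(lp_os)))
    c_ttft = rng.uniform(1.0, 8.0, size=n_pat)
    c_os = rng.uniform(3.0, 12.0, size=n_pat)
    ttft_event = (t_ttft <= c_ttft).astype(int)
    os_event = (t_os <= c_os).astype(int)

    clinical = pd.DataFrame(
        {
            "patient": patients,
            "subgroup": subgroup,
            "cll_mbl": np.where(
                is_cll, np.where(np.nan_to_num(is_mbl, nan=0.0) > 0, "MBL", "CLL"), ""
            ),
            "is_mbl": is_mbl,
            "ighv_status": ighv_status,
            "ighv_unmutated": ighv_unmut,
            "stage": stage,
            "age_dx": np.round(age, 1),
            "ttft_time": np.round(np.minimum(t_ttft, c_ttft), 4),
            "ttft_event": ttft_event,
            "os_time": np.round(np.minimum(t_os, c_os), 4),
            "os_event": os_event,
        }
    )

    truth = SyntheticTruth(
        carriers={g: sorted(s) for g, s in carrier_sets.items() if s},
        homozygotes=homozygotes,
        compound_hets=compound_hets,
        chip=chip_truth,
        germline_somatic=germline_somatic,
        loh_second_hits=loh_truth,
        survival_log_hr={g: v for g, v in log_hr.items() if v != 0.0},
        covariate_betas={
            "ttft": list(spec.ttft_covariate_betas),
            "os": list(spec.os_covariate_betas),
        },
    )
    return SimulatedCohort(
        spec=spec,
        reference=reference,
        genes=genes,
        catalog=catalog,
        occurrences=occurrences,
        clinical=clinical,
        somatic=somatic,
        loh=loh,
        excluded_bed=excluded_bed,
        panel_genes=panel_genes,
        chip_genes=chip_genes,
        truth=truth,
    )


def _catalog_key(catalog: pd.DataFrame, var_id: int) -> VariantKey:
    row = catalog.iloc[var_id] if catalog.index.name != "var_id" else catalog.loc[var_id]
    return VariantKey(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


def _plant_background(occurrences, pool_ids, rng, patient, gene):
    """Append one het background occurrence to a built occurrence frame."""
    var_id = pool_ids[gene][int(rng.integers(0, _POOL_SIZE))]
    new = {
        "patient": patient, "var_id": var_id, "zygosity": "het",
        "role": "background", "tumor_vaf": np.nan,
        "vaf": float(np.round(rng.beta(60, 60), 4)),
        "dp": int(rng.poisson(35) + 12),
        "gq": float(rng.integers(40, 100)),
        "qc_fail": False,
    }
    for caller in CALLERS:
        new[f"det_{caller}"] = True
    occurrences.loc[len(occurrences)] = {
        c: new.get(c, np.nan) for c in occurrences.columns
    }


def qualifying_from_simulation(sim: SimulatedCohort) -> list:
    """Qualifying variants an ideal pipeline run would produce.

    Materializes the cohort's true qualifying calls (pool, compound-het and
    homozygote occurrences that pass QC) directly from the in-memory
    simulation, bypassing file round-trips.  Used by the statistical
    calibration suites, where thousands of genes are simulated; equivalence
    with the file-based pipeline is established separately on small cohorts.
    """
    from lymphgerm.prioritization import QualifyingVariant

    catalog = sim.catalog.set_index("var_id")
    out = []
    for r in sim.occurrences.itertuples(index=False):
        if r.role not in ("background", "compound_het", "homozygote"):
            continue
        if r.qc_fail:
            continue
        var = catalog.loc[r.var_id]
        consequence = str(var["consequence"])
        if consequence in ("missense",) and float(var["cadd_phred"]) <= 20:
            continue
        if consequence == "missense":
            category = "missense_high_cadd"
        elif consequence in (
            "stop_gained", "frameshift", "splice_donor", "splice_acceptor",
            "stop_lost", "start_lost",
        ):
            category = "PTV"
        else:
            category = "high_impact_other"
        out.append(
            QualifyingVariant(
                key=VariantKey(
                    str(var["chrom"]), int(var["pos"]), str(var["ref"]), str(var["alt"])
                ),
                sample=str(r.patient),
                gene=str(var["gene"]),
                category=category,
                cadd_phred=float(var["cadd_phred"]),
                popmax=float(var["af_NFE"]),
                zygosity=str(r.zygosity),
                consequence=consequence,
            )
        )
    return out


def control_counts_frame(sim: SimulatedCohort) -> pd.DataFrame:
    """Control site-frequency table (gene, chrom, pos, ref, alt, ac, an)."""
    cat = sim.catalog[sim.catalog["control_an"] > 0]
    return cat[["gene", "chrom", "pos", "ref", "alt", "control_ac", "control_an"]].rename(
        columns={"control_ac": "ac", "control_an": "an"}
    ).reset_index(drop=True)


# --------------------------------------------------------------------- writer

def _write_fasta(reference: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _vcf_header(reference: Mapping[str, str], sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(reference):
        header.contigs.add(chrom, length=len(reference[chrom]))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (Phred)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.add_sample(sample)
    return header


def _unnormalized_representation(
    key_pos: int, ref: str, alt: str, seq: str
) -> tuple[int, str, str]:
    """Equivalent non-parsimonious spelling (suffix-padded, right-anchored)."""
    tail_start = key_pos - 1 + len(ref)
    suffix = seq[tail_start : tail_start + 2]
    if not suffix:
        return key_pos, ref, alt
    return key_pos, ref + suffix, alt + suffix


def write_cohort(sim: SimulatedCohort, out_dir: str | Path) -> CohortBundle:
    """Write a simulated study to disk (per-caller VCFs + TSV/BED/JSON)."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    vcf_dir = root / "vcf"
    vcf_dir.mkdir(exist_ok=True)

    fasta = root / "reference.fa"
    _write_fasta(sim.reference, fasta)

    catalog = sim.catalog.set_index("var_id")
    seq = sim.reference["chr1"]
    all_patients = sorted(sim.clinical["patient"])

    for patient in all_patients:
        occ = sim.occurrences[sim.occurrences["patient"] == patient]
        for caller in CALLERS:
            path = vcf_dir / f"{patient}.{caller}.vcf"
            header = _vcf_header(sim.reference, patient)
            records = []
            for r in occ.itertuples(index=False):
                if not getattr(r, f"det_{caller}"):
                    continue
                var = catalog.loc[r.var_id]
                pos, ref, alt = int(var["pos"]), str(var["ref"]), str(var["alt"])
                if caller == UNNORMALIZED_CALLER and (len(ref) > 1 or len(alt) > 1):
                    pos, ref, alt = _unnormalized_representation(pos, ref, alt, seq)
                dp = int(r.dp)
                alt_d = int(round(r.vaf * dp))
                records.append(
                    (pos, ref, alt, r.zygosity, int(r.gq), dp, dp - alt_d, alt_d)
                )
            records.sort()
            with pysam.VariantFile(str(path), "w", header=header) as vcf:
                for pos, ref, alt, zyg, gq, dp, ref_d, alt_d in records:
                    rec = vcf.new_record(
                        contig="chr1", start=pos - 1, alleles=(ref, alt)
                    )
                    rec.samples[patient]["GT"] = (1, 1) if zyg == "hom_alt" else (0, 1)
                    rec.samples[patient]["GQ"] = gq
                    rec.samples[patient]["DP"] = dp
                    rec.samples[patient]["AD"] = (ref_d, alt_d)
                    vcf.write(rec)

    site_cols = ["chrom", "pos", "ref", "alt"]
    cat = sim.catalog.sort_values(["chrom", "pos", "ref", "alt"])

    popaf = root / "population_af.tsv"
    af_cols = [f"af_{p}" for p in POPULATIONS]
    pop_frame = cat[site_cols + af_cols].copy()
    for pop in POPULATIONS:
        pop_frame[f"an_{pop}"] = 10000
        pop_frame[f"ac_{pop}"] = (pop_frame[f"af_{pop}"] * 10000).round().astype(int)
    pop_frame.to_csv(popaf, sep="\t", index=False)

    cadd = root / "cadd.tsv"
    cat[site_cols + ["cadd_phred"]].to_csv(cadd, sep="\t", index=False)

    cons = root / "consequences.tsv"
    cat[site_cols + ["gene", "consequence", "high_impact_extra"]].to_csv(
        cons, sep="\t", index=False
    )

    known = root / "known_variants.tsv"
    cat.loc[cat["rsid"] != "", site_cols + ["rsid"]].to_csv(known, sep="\t", index=False)

    pathogenic = root / "pathogenic_flags.tsv"
    cat.loc[cat["pathogenic_flag"] != "", site_cols + ["pathogenic_flag"]].to_csv(
        pathogenic, sep="\t", index=False
    )

    controls = root / "control_counts.tsv"
    ctrl = cat[cat["control_an"] > 0]
    ctrl[["gene"] + site_cols + ["control_ac", "control_an"]].rename(
        columns={"control_ac": "ac", "control_an": "an"}
    ).to_csv(controls, sep="\t", index=False)

    bed = root / "excluded_regions.bed"
    with open(bed, "w") as fh:
        for chrom, start, end in sorted(sim.excluded_bed):
            fh.write(f"{chrom}\t{start}\t{end}\n")

    somatic_path = root / "somatic_mutations.tsv"
    sim.somatic.sort_values(["patient", "gene", "pos"]).to_csv(
        somatic_path, sep="\t", index=False
    )
    loh_path = root / "loh_segments.tsv"
    sim.loh.sort_values(["patient", "chrom", "start"]).to_csv(
        loh_path, sep="\t", index=False
    )

    tumor_path = root / "tumor_vaf.tsv"
    catalog_idx = sim.catalog.set_index("var_id")
    chip_gene_set = set(sim.chip_genes)
    tv_rows = []
    for r in sim.occurrences.itertuples(index=False):
        var = catalog_idx.loc[r.var_id]
        if var["gene"] in chip_gene_set and not np.isnan(r.tumor_vaf):
            tv_rows.append(
                {"patient": r.patient, "chrom": var["chrom"], "pos": var["pos"],
                 "ref": var["ref"], "alt": var["alt"], "tumor_vaf": r.tumor_vaf}
            )
    pd.DataFrame(
        tv_rows, columns=["patient", "chrom", "pos", "ref", "alt", "tumor_vaf"]
    ).sort_values(["patient", "pos"]).to_csv(tumor_path, sep="\t", index=False)

    clinical_path = root / "clinical.tsv"
    sim.clinical.to_csv(clinical_path, sep="\t", index=False)

    panel_path = root / "panel_genes.txt"
    panel_path.write_text("\n".join(sim.panel_genes) + "\n")
    chip_path = root / "chip_genes.txt"
    chip_path.write_text("\n".join(sim.chip_genes) + "\n")

    truth_path = root / "truth.json"
    truth_path.write_text(sim.truth.to_json() + "\n")

    return CohortBundle(
        root=root,
        reference_fasta=fasta,
        vcf_dir=vcf_dir,
        popaf_table=popaf,
        cadd_table=cadd,
        consequence_table=cons,
        known_variants=known,
        pathogenic_table=pathogenic,
        control_counts=controls,
        excluded_bed=bed,
        somatic_table=somatic_path,
        loh_table=loh_path,
        tumor_vaf_table=tumor_path,
        clinical_table=clinical_path,
        panel_file=panel_path,
        chip_gene_file=chip_path,
        truth_json=truth_path,
        truth=sim.truth,
    )


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> CohortBundle:
    """Simulate a study and write it to ``out_dir``; returns the file bundle."""
    return write_cohort(simulate_cohort(spec), out_dir)
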