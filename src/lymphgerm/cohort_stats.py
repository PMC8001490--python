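"""Cohort-level descriptive statistics and reports.

Carrier percentages, mutations-per-gene-per-patient rates, variant-type
distributions, fold-enrichment of cohort allele frequencies over a reference
population, subgroup Fisher enrichment (e.g. lymphoma vs CLL) with FDR, and
gene-report annotation joins (FLAGS membership, pLoF observed/expected).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from lymphgerm.burden import fdr_adjust
from lymphgerm.prioritization import QualifyingVariant


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (0.125 → 0.13 at 2 decimals), as tables print."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def carrier_percentage(carrier_count: int, n_patients: int, decimals: int = 2) -> float:
    """Percentage of patients carrying >= 1 qualifying variant, half-up rounded."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    if not 0 <= carrier_count <= n_patients:
        raise ValueError("carrier_count must lie in [0, n_patients]")
    return round_half_up(100.0 * carrier_count / n_patients, decimals)


def mutation_rate(n_mutations: int, n_genes: int, n_patients: int) -> float:
    """Mutations per gene per patient."""
    if n_genes <= 0 or n_patients <= 0:
        raise ValueError("n_genes and n_patients must be positive")
    return n_mutations / (n_genes * n_patients)


@dataclass(frozen=True)
class FoldEnrichment:
    cohort_ac: int
    cohort_an: int
    reference_af: float
    fold: float | None  # None when reference_af == 0 (novel)

    @property
    def novel(self) -> bool:
        return self.fold is None


def fold_enrichment(cohort_ac: int, cohort_an: int, reference_af: float) -> FoldEnrichment:
    """Cohort allele frequency over a reference population's frequency.

    A reference frequency of zero marks the variant novel (fold undefined)
    rather than dividing by zero.
    """
    if cohort_an <= 0:
        raise ValueError("cohort_an must be positive")
    if reference_af == 0:
        return FoldEnrichment(cohort_ac, cohort_an, reference_af, None)
    return FoldEnrichment(
        cohort_ac, cohort_an, reference_af, (cohort_ac / cohort_an) / reference_af
    )


def variant_type_distribution(
    variants: Sequence[QualifyingVariant], decimals: int = 2
) -> dict[str, float]:
    """Percentage of qualifying events per consequence term (sums to ~100)."""
    if not variants:
        return {}
    counts = pd.Series([v.consequence for v in variants]).value_counts()
    total = counts.sum()
    return {
        term: round_half_up(100.0 * n / total, decimals)
        for term, n in counts.items()
    }


def subgroup_fisher(tables: Mapping[str, Sequence[Sequence[int]]]) -> pd.DataFrame:
    """Two-sided Fisher exact tests per gene with BH correction across genes.

    ``tables`` maps gene → 2×2 table
    [[carriers_in_A, noncarriers_in_A], [carriers_in_B, noncarriers_in_B]].
    Uses the point-probability rule for two-sidedness.  Zero-margin tables
    give p = 1.
    """
    records = []
    for gene in sorted(tables):
        table = tables[gene]
        (a, b), (c, d) = table
        if min(a, b, c, d) < 0:
            raise ValueError(f"negative count in table for {gene}")
        if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
            p = 1.0
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        records.append({"gene": gene, "a": a, "b": b, "c": c, "d": d, "p": p})
    df = pd.DataFrame(records, columns=["gene", "a", "b", "c", "d", "p"])
    if len(df):
        df["q"] = fdr_adjust(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df


def annotate_genes(
    gene_counts: Mapping[str, int],
    flags_table: pd.DataFrame | None = None,
    plof_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recurrently-affected-gene report with FLAGS and pLoF o/e annotations.

    ``flags_table``: column ``gene`` listing genes in the top of the FLAGS
    (frequently mutated in public exomes) ranking.  ``plof_table``: columns
    ``gene`` and ``oe`` (formatted observed/expected string or number).
    Missing annotations are left absent ("No" / NA), never fabricated.
    """
    df = pd.DataFrame(
        sorted(gene_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "n_cases"],
    )
    flags = (
        set(flags_table["gene"].astype(str).str.upper())
        if flags_table is not None and len(flags_table)
        else set()
    )
    df["flags_top"] = df["gene"].str.upper().map(lambda g: "Yes" if g in flags else "No")
    if plof_table is not None and len(plof_table):
        oe = plof_table.set_index(plof_table["gene"].astype(str).str.upper())["oe"]
        df["plof_oe"] = df["gene"].str.upper().map(oe)
    else:
        df["plof_oe"] = pd.NA
    return df


def cohort_summary(
    variants: Sequence[QualifyingVariant],
    n_patients: int,
    n_panel_genes: int,
    n_background_genes: int | None = None,
    background_variants: Sequence[QualifyingVariant] = (),
) -> dict:
    """Headline cohort numbers with explicit denominators."""
    carriers = {v.sample for v in variants}
    ptv_carriers = {v.sample for v in variants if v.category == "PTV"}
    genes_hit = {v.gene for v in variants if v.gene}
    out = {
        "n_patients": n_patients,
        "n_qualifying_variants": len(variants),
        "n_genes_hit": len(genes_hit),
        "carrier_percent": carrier_percentage(len(carriers), n_patients),
        "ptv_carrier_percent": carrier_percentage(len(ptv_carriers), n_patients),
        "variant_type_distribution": variant_type_distribution(variants),
        "rate_panel": mutation_rate(len(variants), n_panel_genes, n_patients),
    }
    if n_background_genes:
        out["rate_background"] = mutation_rate(
            len(background_variants), n_background_genes, n_patients
        )
    return out
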