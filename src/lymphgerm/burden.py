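"""Gene-level carrier-collapsing burden test against public controls.

Cases contribute carriers — patients with at least one qualifying allele in a
gene (dominant collapsing).  Controls are a site-frequency resource (per-
variant allele counts; no per-sample genotypes), so control carriers are
approximated by the summed allele count over the gene's qualifying variants,
capped at the control sample size: at such low frequencies each rare allele
almost surely sits in a distinct control.  Enrichment is a one-sided Fisher
exact test (hypergeometric upper tail) per gene, Benjamini–Hochberg corrected
within model, with the genomic inflation factor λ as a calibration diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lymphgerm.prioritization import QualifyingVariant

logger = logging.getLogger(__name__)

MODELS = ("ptv_only", "ptv_plus_high_impact")

#: Median of the 1-df chi-square distribution.
_CHI2_1DF_MEDIAN = float(stats.chi2.median(df=1))


@dataclass(frozen=True)
class BurdenResult:
    gene: str
    model: str
    case_carriers: int
    n_cases: int
    control_carriers: int
    n_controls: int
    p: float
    q: float | None = None


def model_categories(model: str) -> frozenset[str]:
    if model == "ptv_only":
        return frozenset({"PTV"})
    if model == "ptv_plus_high_impact":
        return frozenset({"PTV", "high_impact_other"})
    raise ValueError(f"unknown burden model {model!r}")


def collapse_carriers(
    variants: Sequence[QualifyingVariant], model: str | None = None
) -> dict[str, set[str]]:
    """Per-gene carrier sets under dominant collapsing.

    A patient with any number of qualifying alleles in a gene counts once.
    ``model`` restricts the variant categories (``ptv_only`` keeps PTVs;
    ``ptv_plus_high_impact`` adds extended high-impact variants; None keeps
    every qualifying category).
    """
    categories = model_categories(model) if model else None
    carriers: dict[str, set[str]] = {}
    for v in variants:
        if not v.gene:
            continue
        if categories is not None and v.category not in categories:
            continue
        carriers.setdefault(v.gene, set()).add(v.sample)
    return carriers


def control_carrier_estimate(
    control_counts: pd.DataFrame | Iterable[Mapping], n_controls: int
) -> int:
    """Estimated control carriers for one gene from site-frequency data.

    Sums allele counts (``ac``) over the gene's qualifying variants and caps
    at ``n_controls``.  Variants with a missing allele number contribute 0
    with a warning (their ``ac`` cannot be trusted).
    """
    if isinstance(control_counts, pd.DataFrame):
        rows = control_counts.to_dict("records")
    else:
        rows = list(control_counts)
    total = 0
    for row in rows:
        an = row.get("an")
        if an is None or (isinstance(an, float) and np.isnan(an)):
            logger.warning("variant with missing AN contributes 0 control carriers")
            continue
        total += int(row.get("ac", 0))
    return min(total, n_controls)


def fisher_burden(
    case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
) -> float:
    """One-sided enrichment p-value for the 2×2 carrier table.

    Upper tail of the hypergeometric distribution: drawing ``n_cases`` samples
    from a pool of ``n_cases + n_controls`` containing
    ``case_carriers + control_carriers`` carriers, the probability of at least
    ``case_carriers`` carriers among cases.  Zero margins give p = 1.
    """
    if not (0 <= case_carriers <= n_cases and 0 <= control_carriers <= n_controls):
        raise ValueError("inconsistent 2x2 counts")
    total = n_cases + n_controls
    k_total = case_carriers + control_carriers
    if case_carriers == 0 or k_total == 0 or n_cases == 0:
        return 1.0
    # P(X >= case_carriers), X ~ Hypergeom(M=total, n=k_total, N=n_cases)
    p = float(stats.hypergeom.sf(case_carriers - 1, total, k_total, n_cases))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def genomic_lambda(p_values: Sequence[float]) -> float:
    """Genomic inflation factor over a set of test p-values.

    Converts each p to its 1-df chi-square quantile and divides the median by
    the null median (≈ 0.4549).  λ ≈ 1 indicates a calibrated null; λ > 1,
    inflation.  Degenerate input (all p = 1) gives λ = 0 with a warning.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("genomic_lambda requires at least one p-value")
    chi2 = stats.chi2.isf(p, df=1)
    med = float(np.median(chi2))
    if med == 0.0:
        logger.warning("all p-values at 1; lambda reported as 0")
        return 0.0
    return med / _CHI2_1DF_MEDIAN


def burden_test(
    variants: Sequence[QualifyingVariant],
    control_counts: pd.DataFrame,
    n_cases: int,
    n_controls: int = 15708,
    model: str | None = "ptv_only",
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene one-sided burden test with within-model BH correction.

    ``control_counts`` columns: gene, ac, an (one row per control-qualifying
    variant; the same popmax filter as cases is assumed applied upstream).
    Genes with zero case carriers are skipped.  Returns a DataFrame sorted by
    p with columns gene, model, case_carriers, n_cases, control_carriers,
    n_controls, p, q and attribute ``df.attrs["lambda"]``.
    """
    carriers = collapse_carriers(variants, model=model)
    if genes is not None:
        carriers = {g: s for g, s in carriers.items() if g in set(genes)}
    by_gene_controls = (
        dict(tuple(control_counts.groupby("gene")))
        if len(control_counts)
        else {}
    )
    records = []
    for gene in sorted(carriers):
        case_n = len(carriers[gene])
        if case_n == 0:
            continue
        ctrl = by_gene_controls.get(gene)
        ctrl_carriers = (
            control_carrier_estimate(ctrl, n_controls) if ctrl is not None else 0
        )
        p = fisher_burden(case_n, n_cases, ctrl_carriers, n_controls)
        records.append(
            {
                "gene": gene,
                "model": model or "all_qualifying",
                "case_carriers": case_n,
                "n_cases": n_cases,
                "control_carriers": ctrl_carriers,
                "n_controls": n_controls,
                "p": p,
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "gene", "model", "case_carriers", "n_cases",
            "control_carriers", "n_controls", "p",
        ],
    )
    if len(df):
        df["q"] = fdr_adjust(df["p"].to_numpy())
        df.attrs["lambda"] = genomic_lambda(df["p"].to_numpy())
        df = df.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df.attrs["lambda"] = float("nan")
    return df
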