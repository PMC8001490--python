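"""Rarity/impact prioritization of consensus variants.

The cascade keeps a variant when it is (1) rare — maximum allele frequency
across reference populations (popmax) strictly below 0.5%, optionally
excluding bottlenecked populations (Finnish, Ashkenazi Jewish, "Other") —
and (2) putatively dysfunctional: a protein-truncating consequence, a
missense with CADD Phred > 20, or (for the extended burden model) another
high-impact annotation.  Qualifying variants are finally restricted to a
curated cancer-gene panel; off-panel variants are routed to a background
stream so panel vs background mutation rates can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lymphgerm.consensus import ConsensusVariant, VariantKey

logger = logging.getLogger(__name__)

#: Consequence terms counted as protein-truncating.
PTV_TERMS = frozenset(
    {
        "start_lost",
        "stop_lost",
        "stop_gained",
        "frameshift",
        "splice_acceptor",
        "splice_donor",
    }
)

CONSEQUENCE_TERMS = PTV_TERMS | {
    "missense",
    "inframe_deletion",
    "inframe_insertion",
    "synonymous",
    "other",
}

#: Severity order used to pick one consequence per variant across transcripts.
_SEVERITY = {
    term: rank
    for rank, term in enumerate(
        [
            "stop_gained",
            "frameshift",
            "splice_acceptor",
            "splice_donor",
            "start_lost",
            "stop_lost",
            "missense",
            "inframe_deletion",
            "inframe_insertion",
            "synonymous",
            "other",
        ]
    )
}

#: Populations excluded from popmax by default for burden testing
#: (bottlenecked/heterogeneous populations).
DEFAULT_POPMAX_EXCLUSIONS = frozenset({"FIN", "ASJ", "OTH"})

CATEGORIES = ("PTV", "missense_high_cadd", "high_impact_other")


@dataclass(frozen=True)
class ConsequenceClass:
    term: str
    high_impact_extra: bool = False

    def __post_init__(self) -> None:
        if self.term not in CONSEQUENCE_TERMS:
            raise ValueError(f"unknown consequence term {self.term!r}")

    @property
    def is_ptv(self) -> bool:
        return self.term in PTV_TERMS


@dataclass(frozen=True)
class GenePanel:
    """Non-redundant union of curated gene lists with per-gene provenance."""

    genes: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class QualifyingVariant:
    """A variant surviving the rarity/impact cascade."""

    key: VariantKey
    sample: str
    gene: str
    category: str  # PTV | missense_high_cadd | high_impact_other
    cadd_phred: float | None
    popmax: float
    zygosity: str
    novel: bool = False
    pathogenic_flags: frozenset[str] = frozenset()
    consequence: str = "other"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def build_gene_panel(source_lists: Mapping[str, Iterable[str]]) -> GenePanel:
    """Union curated gene lists into a non-redundant panel with provenance.

    Gene symbols are upper-cased; a gene present in several source lists is
    kept once and tagged with every source label.
    """
    provenance: dict[str, set[str]] = {}
    for label, genes in source_lists.items():
        for gene in genes:
            sym = str(gene).strip().upper()
            if not sym:
                continue
            provenance.setdefault(sym, set()).add(label)
    if not provenance:
        raise ValueError("gene panel union is empty")
    return GenePanel(
        genes=frozenset(provenance),
        provenance={g: frozenset(s) for g, s in provenance.items()},
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def popmax(
    af_by_population: Mapping[str, float] | None,
    threshold: float = 0.005,
    excluded_populations: Iterable[str] = (),
) -> tuple[float, bool]:
    """Maximum allele frequency across non-excluded populations.

    Returns ``(popmax_value, passes)`` where ``passes`` is strict
    (``popmax < threshold``).  A variant absent from the table — or one
    observed only in excluded populations — is treated as unobserved
    (popmax 0, passes).
    """
    excluded = {p.upper() for p in excluded_populations}
    if not af_by_population:
        return 0.0, True
    considered = {
        pop: af for pop, af in af_by_population.items() if pop.upper() not in excluded
    }
    if not considered:
        logger.warning("all populations excluded; variant treated as unobserved")
        return 0.0, True
    value = max(considered.values())
    return value, value < threshold


def classify_variant(
    consequence: ConsequenceClass, cadd_phred: float | None, cadd_min: float = 20.0
) -> str | None:
    """Assign an impact category, or None when the variant does not qualify.

    PTV consequences qualify regardless of CADD; missense requires
    CADD Phred strictly above ``cadd_min``; other consequences qualify only
    via the extended high-impact flag (protein-interaction / structural /
    rare-amino-acid annotations), used by the extended burden model.
    """
    if consequence.is_ptv:
        return "PTV"
    if consequence.term == "missense":
        if cadd_phred is None:
            logger.warning("missense variant without CADD score rejected")
        elif cadd_phred > cadd_min:
            return "missense_high_cadd"
        if consequence.high_impact_extra:
            return "high_impact_other"
        return None
    if consequence.high_impact_extra:
        return "high_impact_other"
    return None


def most_severe(terms: Iterable[str]) -> str:
    """Pick one consequence per variant: the most severe across transcripts."""
    terms = list(terms)
    if not terms:
        return "other"
    return min(terms, key=lambda t: _SEVERITY.get(t, len(_SEVERITY)))


def prioritize(
    variants: Sequence[ConsensusVariant],
    annotations: pd.DataFrame,
    panel: GenePanel | None = None,
    cadd_min: float = 20.0,
    popmax_max: float = 0.005,
    excluded_populations: Iterable[str] = (),
    known_variants: set[tuple] | None = None,
    pathogenic_flags: Mapping[tuple, Iterable[str]] | None = None,
) -> tuple[list[QualifyingVariant], list[QualifyingVariant]]:
    """Run the full cascade; return (panel_stream, background_stream).

    ``annotations`` must carry one row per variant with columns
    ``chrom, pos, ref, alt, gene, consequence, high_impact_extra, cadd_phred``
    plus one ``af_<POP>`` column per population.  The cascade is
    order-independent: each filter is a pure predicate on the variant.
    """
    ann = annotations.set_index(["chrom", "pos", "ref", "alt"])
    af_cols = [c for c in annotations.columns if c.startswith("af_")]
    qualifying: list[QualifyingVariant] = []
    for v in variants:
        idx = (v.key.chrom, v.key.pos, v.key.ref, v.key.alt)
        if idx not in ann.index:
            continue  # unannotated: cannot qualify
        row = ann.loc[idx]
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        af_table = {
            c[3:]: float(row[c]) for c in af_cols if pd.notna(row[c])
        }
        pm_value, pm_pass = popmax(
            af_table, threshold=popmax_max, excluded_populations=excluded_populations
        )
        if not pm_pass:
            continue
        cadd = row.get("cadd_phred")
        cadd = float(cadd) if pd.notna(cadd) else None
        cons = ConsequenceClass(
            term=str(row["consequence"]),
            high_impact_extra=bool(row.get("high_impact_extra", False)),
        )
        category = classify_variant(cons, cadd, cadd_min=cadd_min)
        if category is None:
            continue
        gene = row.get("gene")
        gene = str(gene).upper() if pd.notna(gene) and str(gene) else ""
        qualifying.append(
            QualifyingVariant(
                key=v.key,
                sample=v.sample,
                gene=gene,
                category=category,
                cadd_phred=cadd,
                popmax=pm_value,
                zygosity=v.zygosity,
                novel=(known_variants is not None and idx not in known_variants),
                pathogenic_flags=frozenset(
                    (pathogenic_flags or {}).get(idx, ())
                ),
                consequence=cons.term,
            )
        )
    return restrict_to_panel(qualifying, panel)


def restrict_to_panel(
    variants: Sequence[QualifyingVariant], panel: GenePanel | None
) -> tuple[list[QualifyingVariant], list[QualifyingVariant]]:
    """Partition qualifying variants into (panel, background) streams.

    Variants without a gene annotation go to the background stream; the
    partition is exhaustive and disjoint.
    """
    if panel is None:
        return list(variants), []
    in_panel: list[QualifyingVariant] = []
    background: list[QualifyingVariant] = []
    for v in variants:
        (in_panel if v.gene and v.gene in panel else background).append(v)
    return in_panel, background


def qualifying_to_frame(variants: Sequence[QualifyingVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": v.sample,
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "gene": v.gene,
                "category": v.category,
                "consequence": v.consequence,
                "cadd_phred": v.cadd_phred,
                "popmax": v.popmax,
                "zygosity": v.zygosity,
                "novel": v.novel,
            }
            for v in variants
        ],
        columns=[
            "sample", "chrom", "pos", "ref", "alt", "gene", "category",
            "consequence", "cadd_phred", "popmax", "zygosity", "novel",
        ],
    )
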