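"""Second-hit structure of qualifying variants.

Detects, per patient and gene: homozygous qualifying variants, germline
double hits (two or more distinct heterozygous qualifying variants in the
same gene — compound heterozygotes when in trans), germline–somatic double
hits (a somatic mutation in the same gene and patient), and germline variants
whose reference allele is lost through LOH.  Also classifies likely clonal
hematopoiesis (CHIP): a "germline" call in a known CHIP gene that is absent
(or nearly absent) from the tumor compartment is most parsimoniously a
myeloid somatic mosaic in the blood control, and is removed downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lymphgerm.consensus import VariantKey
from lymphgerm.prioritization import QualifyingVariant

logger = logging.getLogger(__name__)

EVENT_KINDS = ("homozygote", "germline_double_hit", "germline_somatic", "loh_second_hit")


@dataclass(frozen=True)
class DoubleHitEvent:
    patient: str
    gene: str
    kind: str
    keys: tuple[VariantKey, ...]
    phase: str = "unknown"  # cis | trans | unknown

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.phase not in ("cis", "trans", "unknown"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class ChipAssessment:
    key: VariantKey
    patient: str
    gene: str
    control_vaf: float
    tumor_vaf: float | None
    verdict: str  # likely_chip | germline
    assessable: bool = True


def _sorted_keys(keys: Iterable[VariantKey]) -> tuple[VariantKey, ...]:
    return tuple(sorted(set(keys)))


def detect_homozygotes(variants: Sequence[QualifyingVariant]) -> list[DoubleHitEvent]:
    """One event per (patient, variant) with hom_alt zygosity."""
    events = [
        DoubleHitEvent(
            patient=v.sample, gene=v.gene, kind="homozygote", keys=(v.key,)
        )
        for v in variants
        if v.zygosity == "hom_alt"
    ]
    events.sort(key=lambda e: (e.patient, e.gene, e.keys))
    return events


def detect_germline_double_hits(
    variants: Sequence[QualifyingVariant],
    phase_table: Mapping[tuple[str, VariantKey, VariantKey], str] | None = None,
) -> list[DoubleHitEvent]:
    """Patients with >= 2 distinct heterozygous qualifying variants in a gene.

    One event per (patient, gene) listing every involved variant.  Phase is
    looked up in ``phase_table`` keyed by (patient, key_a, key_b) with keys in
    sorted order; pairs not covered get phase "unknown".  Candidates in cis
    are retained (flagged) rather than dropped, so a stricter trans-only
    analysis remains possible.
    """
    by_patient_gene: dict[tuple[str, str], set[VariantKey]] = defaultdict(set)
    for v in variants:
        if v.zygosity == "het" and v.gene:
            by_patient_gene[(v.sample, v.gene)].add(v.key)
    events = []
    for (patient, gene), keys in by_patient_gene.items():
        if len(keys) < 2:
            continue
        ordered = _sorted_keys(keys)
        phase = "unknown"
        if phase_table and len(ordered) == 2:
            phase = phase_table.get((patient, ordered[0], ordered[1]), "unknown")
        events.append(
            DoubleHitEvent(
                patient=patient,
                gene=gene,
                kind="germline_double_hit",
                keys=ordered,
                phase=phase,
            )
        )
    events.sort(key=lambda e: (e.patient, e.gene))
    return events


def detect_somatic_second_hits(
    variants: Sequence[QualifyingVariant],
    somatic_table: pd.DataFrame | None = None,
    loh_segments: pd.DataFrame | None = None,
) -> list[DoubleHitEvent]:
    """Germline–somatic double hits and LOH second hits.

    ``somatic_table`` columns: patient, gene (others ignored).  ``loh_segments``
    columns: patient, chrom, start, end (1-based inclusive).  A germline
    qualifying variant yields a ``germline_somatic`` event when the same
    patient carries a somatic mutation in the same gene, and an
    ``loh_second_hit`` event when its normalized position falls inside an LOH
    segment of that patient.  Malformed segments (start >= end) are rejected
    with a warning.
    """
    events: list[DoubleHitEvent] = []

    if somatic_table is not None and len(somatic_table):
        somatic_pairs = {
            (str(r.patient), str(r.gene).upper())
            for r in somatic_table.itertuples(index=False)
        }
        seen: set[tuple[str, str]] = set()
        by_pair: dict[tuple[str, str], list[VariantKey]] = defaultdict(list)
        for v in variants:
            pair = (v.sample, v.gene)
            if v.gene and pair in somatic_pairs:
                by_pair[pair].append(v.key)
        for (patient, gene), keys in by_pair.items():
            if (patient, gene) in seen:
                continue
            seen.add((patient, gene))
            events.append(
                DoubleHitEvent(
                    patient=patient,
                    gene=gene,
                    kind="germline_somatic",
                    keys=_sorted_keys(keys),
                )
            )

    if loh_segments is not None and len(loh_segments):
        segs: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
        for r in loh_segments.itertuples(index=False):
            start, end = int(r.start), int(r.end)
            if start >= end:
                logger.warning(
                    "rejecting malformed LOH segment %s:%s-%s for patient %s",
                    r.chrom, start, end, r.patient,
                )
                continue
            segs[str(r.patient)].append((str(r.chrom), start, end))
        for v in variants:
            for chrom, start, end in segs.get(v.sample, ()):
                if v.key.chrom == chrom and start <= v.key.pos <= end:
                    events.append(
                        DoubleHitEvent(
                            patient=v.sample,
                            gene=v.gene,
                            kind="loh_second_hit",
                            keys=(v.key,),
                        )
                    )
                    break

    events.sort(key=lambda e: (e.kind, e.patient, e.gene))
    return events


def assess_chip(
    variants: Sequence[QualifyingVariant],
    chip_genes: Iterable[str],
    tumor_vaf: Mapping[tuple[str, VariantKey], float] | pd.DataFrame,
    tumor_absent_threshold: float = 0.05,
) -> list[ChipAssessment]:
    """Classify calls in CHIP genes as likely mosaic or true germline.

    Only variants whose gene is in ``chip_genes`` are assessed.  ``tumor_vaf``
    maps (patient, key) to the variant's allele fraction in the tumor
    (lymphoid) compartment, or is a DataFrame with columns
    patient, chrom, pos, ref, alt, tumor_vaf.  Verdict is ``likely_chip`` when
    the tumor VAF is below ``tumor_absent_threshold`` (or the variant is
    absent from the tumor compartment entirely); missing tumor data yields
    ``germline`` flagged not assessable.
    """
    chip = {g.upper() for g in chip_genes}
    if isinstance(tumor_vaf, pd.DataFrame):
        lookup: dict[tuple[str, VariantKey], float] = {}
        for r in tumor_vaf.itertuples(index=False):
            key = VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            lookup[(str(r.patient), key)] = float(r.tumor_vaf)
        tumor_vaf = lookup

    out: list[ChipAssessment] = []
    for v in variants:
        if v.gene not in chip:
            continue
        tv = tumor_vaf.get((v.sample, v.key))
        if tv is None:
            out.append(
                ChipAssessment(
                    key=v.key, patient=v.sample, gene=v.gene,
                    control_vaf=_control_vaf(v), tumor_vaf=None,
                    verdict="germline", assessable=False,
                )
            )
            continue
        verdict = "likely_chip" if tv < tumor_absent_threshold else "germline"
        out.append(
            ChipAssessment(
                key=v.key, patient=v.sample, gene=v.gene,
                control_vaf=_control_vaf(v), tumor_vaf=tv, verdict=verdict,
            )
        )
    return out


def _control_vaf(v: QualifyingVariant) -> float:
    return float(getattr(v, "control_vaf", 0.0) or 0.0)


def remove_chip(
    variants: Sequence[QualifyingVariant], assessments: Sequence[ChipAssessment]
) -> list[QualifyingVariant]:
    """Drop variants judged likely CHIP from the qualifying set."""
    flagged = {
        (a.patient, a.key) for a in assessments if a.verdict == "likely_chip"
    }
    return [v for v in variants if (v.sample, v.key) not in flagged]


def events_to_frame(events: Sequence[DoubleHitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient": e.patient,
                "gene": e.gene,
                "kind": e.kind,
                "variants": ";".join(
                    f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k in e.keys
                ),
                "phase": e.phase,
            }
            for e in events
        ],
        columns=["patient", "gene", "kind", "variants", "phase"],
    )
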