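"""Multi-caller consensus germline calling.

Individual variant callers disagree both on which sites they call and on how
they spell indels (left- vs right-aligned, padded vs parsimonious).  This
module normalizes every record to a canonical key — parsimonious alleles,
left-aligned against the reference — and then merges per-caller observations
into a single per-sample call set.  A variant is accepted when at least
``min_callers`` callers report it and the merged call passes genotype-quality,
depth and allele-fraction thresholds (defaults GQ ≥ 30, DP ≥ 10, VAF ≥ 0.30)
and falls outside an excluded-region track (low mappability, homopolymers,
abnormal coverage — supplied as a merged BED).
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

GENOTYPES = ("het", "hom_alt", "hom_ref", "missing")


class ReferenceMismatchError(ValueError):
    """REF allele of a record disagrees with the reference sequence."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a bi-allelic variant (1-based, normalized)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) is not a variant")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class CallerObservation:
    """One caller's view of one variant in one sample."""

    key: VariantKey
    sample: str
    caller: str
    genotype: str  # het | hom_alt | hom_ref | missing
    gq: float
    dp: int
    vaf: float
    ad: tuple[int, int] | None = None  # (ref_depth, alt_depth) when available

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.gq < 0 or self.dp < 0:
            raise ValueError("gq and dp must be non-negative")


@dataclass(frozen=True)
class ConsensusVariant:
    """A merged call supported by >= min_callers callers."""

    key: VariantKey
    sample: str
    n_callers: int
    gq: float
    dp: float
    vaf: float
    zygosity: str  # het | hom_alt
    genotype_conflict: bool = False


def _ref_base(reference, chrom: str, pos: int) -> str:
    """1-based single-base lookup supporting pyfaidx.Fasta or a plain mapping."""
    seq = reference[chrom]
    base = seq[pos - 1 : pos]
    return str(base).upper()


def normalize_variant(chrom: str, pos: int, ref: str, alt: str, reference) -> VariantKey:
    """Return the parsimonious, left-aligned representation of a variant.

    Implements the standard normalization algorithm: repeatedly trim a shared
    trailing base (extending left with the preceding reference base whenever an
    allele would become empty) and finally trim shared leading bases.  SNVs pass
    through unchanged.  ``reference`` is a per-contig sequence accessor
    (e.g. ``pyfaidx.Fasta``); multi-allelic records must be split beforehand.

    Raises
    ------
    ValueError
        If ``ref == alt`` or alleles are empty/invalid.
    ReferenceMismatchError
        If ``ref`` does not match the reference sequence at ``pos``.
    """
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError(f"degenerate record at {chrom}:{pos} (ref == alt)")
    if not (set(ref) <= _VALID_BASES and set(alt) <= _VALID_BASES):
        raise ValueError(f"non-ACGT allele at {chrom}:{pos}: {ref}>{alt}")

    seq = reference[chrom]
    observed = str(seq[pos - 1 : pos - 1 + len(ref)]).upper()
    if observed != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} record REF {ref!r} != reference {observed!r}"
        )

    # SNV fast path: nothing to align.
    if len(ref) == 1 and len(alt) == 1:
        return VariantKey(chrom, pos, ref, alt)

    while True:
        # Trim identical trailing base.
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError(
                        f"cannot left-extend past contig start at {chrom}:{pos}"
                    )
                pos -= 1
                pad = _ref_base(reference, chrom, pos)
                ref, alt = pad + ref, pad + alt
            continue
        break
    # Trim identical leading bases while both alleles keep >= 1 base.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def load_excluded_regions(bed_path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-contig interval trees.

    Unsorted input is accepted; intervals are stored as given.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end > start:
                trees[chrom][start:end] = True
    return dict(trees)


def _in_excluded(key: VariantKey, regions: Mapping[str, IntervalTree] | None) -> bool:
    if not regions:
        return False
    tree = regions.get(key.chrom)
    if tree is None:
        return False
    # VCF 1-based position p maps to 0-based coordinate p-1.
    return bool(tree[key.pos - 1])


def filter_excluded_regions(
    variants: Sequence, regions: Mapping[str, IntervalTree] | str | Path | None
):
    """Drop variants whose (1-based) position falls inside an excluded region.

    ``regions`` may be a BED path or the output of :func:`load_excluded_regions`.
    Works on anything carrying a ``.key`` attribute or on bare VariantKeys.
    """
    if isinstance(regions, (str, Path)):
        regions = load_excluded_regions(regions)
    kept = []
    for v in variants:
        key = v.key if hasattr(v, "key") else v
        if not _in_excluded(key, regions):
            kept.append(v)
    return kept


def _genotype_from_gt(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "missing"
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a != 0 for a in alleles) and len(alleles) > 1:
        return "hom_alt"
    return "het"


def read_caller_vcf(
    vcf_path: str | Path,
    caller: str,
    reference,
    sample: str | None = None,
) -> list[CallerObservation]:
    """Read one caller's VCF into normalized observations.

    Multi-allelic records are split into bi-allelic ones with per-allele depth
    apportionment before normalization.  Records whose REF disagrees with the
    reference are rejected with a logged warning.
    """
    observations: list[CallerObservation] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample is None:
            if len(vcf_samples) != 1:
                raise ValueError(f"{vcf_path}: expected a single-sample VCF")
            sample = vcf_samples[0]
        for rec in vcf:
            fmt = rec.samples[sample]
            gt = fmt.get("GT", (None,))
            gq = fmt.get("GQ")
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                if alt is None or alt in (".", "*", "<NON_REF>"):
                    continue
                # Restrict the genotype to this allele for split records.
                sub_gt = tuple(
                    (1 if a == alt_index else (0 if a == 0 else None)) if a is not None else None
                    for a in gt
                )
                genotype = _genotype_from_gt(sub_gt)
                if genotype in ("hom_ref", "missing"):
                    continue
                try:
                    key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt, reference)
                except ReferenceMismatchError as exc:
                    logger.warning("rejecting record: %s", exc)
                    continue
                except ValueError as exc:
                    logger.warning("rejecting malformed record at %s:%s: %s", rec.chrom, rec.pos, exc)
                    continue
                ad_pair = None
                vaf = 0.0
                if ad is not None and len(ad) > alt_index and ad[0] is not None:
                    ref_d = int(ad[0])
                    alt_d = int(ad[alt_index]) if ad[alt_index] is not None else 0
                    ad_pair = (ref_d, alt_d)
                    if ref_d + alt_d > 0:
                        vaf = alt_d / (ref_d + alt_d)
                observations.append(
                    CallerObservation(
                        key=key,
                        sample=sample,
                        caller=caller,
                        genotype=genotype,
                        gq=float(gq) if gq is not None else 0.0,
                        dp=int(dp) if dp is not None else 0,
                        vaf=vaf,
                        ad=ad_pair,
                    )
                )
    return observations


def build_consensus(
    observations: Iterable[CallerObservation],
    excluded_regions: Mapping[str, IntervalTree] | str | Path | None = None,
    min_callers: int = 2,
    min_gq: float = 30.0,
    min_dp: float = 10.0,
    min_vaf: float = 0.30,
) -> list[ConsensusVariant]:
    """Merge per-caller observations into consensus calls.

    A (sample, variant) pair is emitted when supported by ``min_callers``
    callers (het or hom_alt) and the merged QC values pass all thresholds:
    GQ and DP are medians across supporting callers; VAF is recomputed from
    summed allele depths when every supporting caller reports them, else the
    median of per-caller VAFs.  Zygosity is the majority genotype; a 1–1 tie
    resolves to het and is flagged ``genotype_conflict``.
    """
    if isinstance(excluded_regions, (str, Path)):
        excluded_regions = load_excluded_regions(excluded_regions)

    grouped: dict[tuple[str, VariantKey], dict[str, CallerObservation]] = defaultdict(dict)
    for obs in observations:
        if obs.genotype in ("hom_ref", "missing"):
            continue
        slot = grouped[(obs.sample, obs.key)]
        if obs.caller in slot:
            raise ValueError(
                f"duplicate observation for caller {obs.caller!r} at "
                f"{obs.key.chrom}:{obs.key.pos} sample {obs.sample!r}"
            )
        slot[obs.caller] = obs

    out: list[ConsensusVariant] = []
    for (sample, key), by_caller in grouped.items():
        support = list(by_caller.values())
        if len(support) < min_callers:
            continue
        gq = statistics.median(o.gq for o in support)
        dp = statistics.median(o.dp for o in support)
        if all(o.ad is not None for o in support):
            ref_d = sum(o.ad[0] for o in support)
            alt_d = sum(o.ad[1] for o in support)
            vaf = alt_d / (ref_d + alt_d) if ref_d + alt_d > 0 else 0.0
        else:
            vaf = statistics.median(o.vaf for o in support)
        if gq < min_gq or dp < min_dp or vaf < min_vaf:
            continue
        if _in_excluded(key, excluded_regions):
            continue
        n_hom = sum(o.genotype == "hom_alt" for o in support)
        n_het = sum(o.genotype == "het" for o in support)
        conflict = n_hom > 0 and n_het > 0
        if n_hom > n_het:
            zygosity = "hom_alt"
        else:
            zygosity = "het"  # majority het, or tie resolved conservatively to het
        out.append(
            ConsensusVariant(
                key=key,
                sample=sample,
                n_callers=len(support),
                gq=gq,
                dp=dp,
                vaf=vaf,
                zygosity=zygosity,
                genotype_conflict=conflict,
            )
        )
    out.sort(key=lambda v: (v.key.chrom, v.key.pos, v.key.ref, v.key.alt, v.sample))
    return out


def consensus_to_frame(variants: Sequence[ConsensusVariant]) -> pd.DataFrame:
    """Tabular view of consensus calls (one row per sample × variant)."""
    return pd.DataFrame(
        [
            {
                "sample": v.sample,
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "n_callers": v.n_callers,
                "gq": v.gq,
                "dp": v.dp,
                "vaf": v.vaf,
                "zygosity": v.zygosity,
                "genotype_conflict": v.genotype_conflict,
            }
            for v in variants
        ],
        columns=[
            "sample", "chrom", "pos", "ref", "alt", "n_callers",
            "gq", "dp", "vaf", "zygosity", "genotype_conflict",
        ],
    )
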