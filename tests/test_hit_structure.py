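"""Homozygotes, compound candidates, somatic second hits, CHIP calls."""

import logging
import random

import pandas as pd
import pytest

from lymphgerm.consensus import VariantKey
from lymphgerm.hit_structure import (
    assess_chip,
    detect_germline_double_hits,
    detect_homozygotes,
    detect_somatic_second_hits,
    remove_chip,
)
from lymphgerm.prioritization import QualifyingVariant


def qv(pos, sample="P1", gene="ATM", zygosity="het", category="missense_high_cadd"):
    return QualifyingVariant(
        key=VariantKey("chr1", pos, "A", "T"), sample=sample, gene=gene,
        category=category, cadd_phred=25.0, popmax=0.0, zygosity=zygosity,
        consequence="missense",
    )


def test_homozygote_detection():
    events = detect_homozygotes([qv(10, zygosity="hom_alt"), qv(20)])
    assert len(events) == 1 and events[0].kind == "homozygote"
    # same variant homozygous in two patients -> two events with the same key
    events = detect_homozygotes(
        [qv(10, sample="P1", zygosity="hom_alt"), qv(10, sample="P2", zygosity="hom_alt")]
    )
    assert len(events) == 2 and events[0].keys == events[1].keys


def test_double_hit_requires_two_distinct_het_variants():
    events = detect_germline_double_hits([qv(10), qv(20)])
    assert len(events) == 1
    assert set(k.pos for k in events[0].keys) == {10, 20}
    assert detect_germline_double_hits([qv(10)]) == []
    # variants in different genes do not pair
    assert detect_germline_double_hits([qv(10), qv(20, gene="WRN")]) == []


def test_het_plus_homozygote_yields_both_event_kinds():
    variants = [qv(10), qv(20, zygosity="hom_alt")]
    homs = detect_homozygotes(variants)
    doubles = detect_germline_double_hits(variants)
    assert len(homs) == 1
    # the hom_alt variant is not a *heterozygous* partner, so a germline
    # double hit additionally requires two het variants
    assert doubles == []
    variants.append(qv(30))
    assert len(detect_germline_double_hits(variants)) == 1
    assert len(detect_homozygotes(variants)) == 1


def test_phase_table_sets_cis():
    a, b = qv(10), qv(20)
    key_pair = tuple(sorted([a.key, b.key]))
    events = detect_germline_double_hits(
        [a, b], phase_table={("P1", *key_pair): "cis"}
    )
    assert events[0].phase == "cis"


def test_somatic_second_hits_and_loh():
    somatic = pd.DataFrame(
        [{"patient": "P1", "gene": "KMT2D", "chrom": "chr1", "pos": 99,
          "ref": "G", "alt": "C"},
         {"patient": "P2", "gene": "MYC", "chrom": "chr1", "pos": 5,
          "ref": "G", "alt": "C"}]
    )
    loh = pd.DataFrame(
        [{"patient": "P1", "chrom": "chr1", "start": 5, "end": 50,
          "type": "copy_neutral_loh"}]
    )
    variants = [qv(10, gene="KMT2D"), qv(10, sample="P3", gene="MYC")]
    events = detect_somatic_second_hits(variants, somatic, loh)
    kinds = {(e.kind, e.patient, e.gene) for e in events}
    # P1: somatic KMT2D + germline KMT2D; the variant also sits in P1's LOH segment
    assert ("germline_somatic", "P1", "KMT2D") in kinds
    assert ("loh_second_hit", "P1", "KMT2D") in kinds
    # P2's somatic MYC has no germline counterpart in P2
    assert not any(e.patient == "P2" for e in events)


def test_malformed_loh_segment_rejected_with_warning(caplog):
    loh = pd.DataFrame(
        [{"patient": "P1", "chrom": "chr1", "start": 50, "end": 50, "type": "x"}]
    )
    with caplog.at_level(logging.WARNING):
        events = detect_somatic_second_hits([qv(50)], None, loh)
    assert events == [] and "malformed" in caplog.text


def test_event_detection_stable_under_row_permutation():
    variants = [qv(10), qv(20), qv(30, gene="WRN"), qv(40, gene="WRN", sample="P2")]
    rng = random.Random(3)
    baseline = detect_germline_double_hits(variants)
    for _ in range(5):
        shuffled = variants[:]
        rng.shuffle(shuffled)
        assert detect_germline_double_hits(shuffled) == baseline


def _chip_variant(pos, gene, sample="P1"):
    return qv(pos, sample=sample, gene=gene)


def test_chip_verdicts():
    chip_genes = ["DNMT3A", "TET2"]
    variants = [
        _chip_variant(10, "DNMT3A"),
        _chip_variant(20, "TET2"),
        _chip_variant(30, "ATM"),  # not a CHIP gene: not assessed
    ]
    tumor = {
        ("P1", variants[0].key): 0.0,
        ("P1", variants[1].key): 0.47,
    }
    out = assess_chip(variants, chip_genes, tumor)
    verdicts = {(a.gene): a.verdict for a in out}
    assert verdicts == {"DNMT3A": "likely_chip", "TET2": "germline"}
    assert len(out) == 2


def test_missing_tumor_data_is_not_assessable():
    v = _chip_variant(10, "DNMT3A")
    (a,) = assess_chip([v], ["DNMT3A"], {})
    assert a.verdict == "germline" and not a.assessable


def test_removing_chip_does_not_touch_non_chip_genes():
    variants = [
        _chip_variant(10, "DNMT3A"),
        qv(20, gene="ATM"),
        qv(30, gene="WRN"),
    ]
    assessments = assess_chip(variants, ["DNMT3A"], {("P1", variants[0].key): 0.0})
    kept = remove_chip(variants, assessments)
    assert {v.gene for v in kept} == {"ATM", "WRN"}


def test_planted_events_recovered_exactly_in_memory(recovery_spec):
    """Noise-free simulation: every planted event kind is recovered with
    precision and recall 1.0 from the generator's own qualifying calls."""
    from lymphgerm.synthetic_cohort import simulate_cohort, qualifying_from_simulation

    sim = simulate_cohort(recovery_spec)
    qualifying = qualifying_from_simulation(sim)

    homs = {(e.patient, e.gene) for e in detect_homozygotes(qualifying)}
    truth_homs = {(t["patient"], t["gene"]) for t in sim.truth.homozygotes}
    assert homs == truth_homs and len(homs) > 0

    doubles = {(e.patient, e.gene) for e in detect_germline_double_hits(qualifying)}
    truth_doubles = {(t["patient"], t["gene"]) for t in sim.truth.compound_hets}
    assert doubles == truth_doubles and len(doubles) > 0

    events = detect_somatic_second_hits(qualifying, sim.somatic, sim.loh)
    gs = {(e.patient, e.gene) for e in events if e.kind == "germline_somatic"}
    truth_gs = {(t["patient"], t["gene"]) for t in sim.truth.germline_somatic}
    assert gs == truth_gs and len(gs) > 0

    loh = {(e.patient, e.gene) for e in events if e.kind == "loh_second_hit"}
    truth_loh = {(t["patient"], t["gene"]) for t in sim.truth.loh_second_hits}
    assert loh == truth_loh
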