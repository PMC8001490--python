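"""Variant normalization and multi-caller consensus merging."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lymphgerm.consensus import (
    CallerObservation,
    ReferenceMismatchError,
    VariantKey,
    build_consensus,
    filter_excluded_regions,
    normalize_variant,
)
from intervaltree import IntervalTree

REF = {"chr1": "GGACAAAGCTTACGTACGTTTTTACGATCGATCG"}
#                1234567890123456789012345678901234


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Independent haplotype oracle: splice alt into the sequence."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def test_snv_passes_through_unchanged():
    assert normalize_variant("chr1", 3, "A", "T", REF) == VariantKey("chr1", 3, "A", "T")


def test_all_representations_of_a_deletion_normalize_identically():
    # Delete one A from the A-run at positions 5-7: enumerate every (pos, ref,
    # alt) spelling in a 10 bp window that yields the same haplotype and
    # require a single normalized key.
    seq = REF["chr1"]
    canonical = normalize_variant("chr1", 4, "CA", "C", REF)
    target = apply_variant(seq, 4, "CA", "C")
    matched = []
    for pos in range(1, 12):
        for ref_len in range(1, 6):
            ref = seq[pos - 1 : pos - 1 + ref_len]
            if len(ref) < ref_len:
                continue
            for alt_len in range(1, ref_len):
                for alt in {ref[:alt_len], ref[ref_len - alt_len :]}:
                    if ref == alt:
                        continue
                    if apply_variant(seq, pos, ref, alt) == target:
                        matched.append((pos, ref, alt))
    assert len(matched) >= 3  # the representation class is non-trivial
    for pos, ref, alt in matched:
        assert normalize_variant("chr1", pos, ref, alt, REF) == canonical


def test_degenerate_and_mismatching_records_rejected():
    with pytest.raises(ValueError):
        normalize_variant("chr1", 3, "AC", "AC", REF)
    with pytest.raises(ReferenceMismatchError):
        normalize_variant("chr1", 3, "T", "G", REF)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pos=st.integers(min_value=5, max_value=25),
    ref_len=st.integers(min_value=1, max_value=4),
    alt=st.text(alphabet="ACGT", min_size=1, max_size=4),
)
def test_normalization_is_idempotent(pos, ref_len, alt):
    seq = REF["chr1"]
    ref = seq[pos - 1 : pos - 1 + ref_len]
    if ref == alt:
        return
    key = normalize_variant("chr1", pos, ref, alt, REF)
    again = normalize_variant(key.chrom, key.pos, key.ref, key.alt, REF)
    assert again == key


def _obs(caller, gq=40.0, dp=20, vaf=0.45, genotype="het", pos=3, sample="S1"):
    ad = (round(dp * (1 - vaf)), round(dp * vaf))
    return CallerObservation(
        key=VariantKey("chr1", pos, "A", "T"),
        sample=sample,
        caller=caller,
        genotype=genotype,
        gq=gq,
        dp=dp,
        vaf=vaf,
        ad=ad,
    )


def test_two_caller_support_with_passing_qc_is_emitted():
    out = build_consensus([_obs("a", gq=35, dp=12, vaf=0.45), _obs("b", gq=35, dp=12, vaf=0.45)])
    assert len(out) == 1
    v = out[0]
    assert v.n_callers == 2 and v.zygosity == "het"


def test_single_caller_is_dropped_regardless_of_quality():
    assert build_consensus([_obs("a", gq=99, dp=100)]) == []


def test_low_vaf_consensus_is_dropped():
    obs = [_obs(c, vaf=0.29, dp=100) for c in "abc"]
    assert build_consensus(obs) == []


def test_genotype_tie_resolves_to_het_and_is_flagged():
    out = build_consensus([_obs("a", genotype="het"), _obs("b", genotype="hom_alt")])
    assert out[0].zygosity == "het" and out[0].genotype_conflict


def test_consensus_invariant_to_caller_order():
    obs = [
        _obs("a", gq=31, dp=11),
        _obs("b", gq=45, dp=30),
        _obs("c", gq=60, dp=25),
        _obs("a", pos=5, gq=50, dp=40),
        _obs("b", pos=5, gq=50, dp=40),
    ]
    baseline = build_consensus(obs)
    for perm in itertools.permutations(obs):
        assert build_consensus(list(perm)) == baseline


@pytest.mark.parametrize(
    "kwargs",
    [
        {"min_callers": 3},
        {"min_gq": 50},
        {"min_dp": 25},
        {"min_vaf": 0.46},
    ],
)
def test_tightening_any_threshold_is_monotone(kwargs):
    obs = [
        _obs("a", gq=31, dp=11, vaf=0.45),
        _obs("b", gq=45, dp=30, vaf=0.5),
        _obs("c", gq=60, dp=25, vaf=0.4),
        _obs("a", pos=5, gq=99, dp=40),
        _obs("b", pos=5, gq=20, dp=40),
    ]
    loose = build_consensus(obs)
    tight = build_consensus(obs, **kwargs)
    assert len(tight) <= len(loose)
    loose_keys = {(v.sample, v.key) for v in loose}
    assert {(v.sample, v.key) for v in tight} <= loose_keys


def test_excluded_region_boundaries():
    tree = IntervalTree()
    tree[100:101] = True
    regions = {"chr1": tree}
    inside = VariantKey("chr1", 101, "A", "T")  # 0-based 100 in [100,101)
    assert filter_excluded_regions([inside], regions) == []
    tree2 = IntervalTree()
    tree2[101:200] = True
    assert filter_excluded_regions([inside], {"chr1": tree2}) == [inside]
    assert filter_excluded_regions([inside], None) == [inside]
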