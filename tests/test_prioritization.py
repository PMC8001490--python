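"""Rarity/impact cascade, popmax, and gene-panel restriction."""

import itertools

import pandas as pd
import pytest

from lymphgerm.consensus import ConsensusVariant, VariantKey
from lymphgerm.prioritization import (
    ConsequenceClass,
    build_gene_panel,
    classify_variant,
    popmax,
    prioritize,
    restrict_to_panel,
)


def test_panel_union_with_provenance():
    panel = build_gene_panel({"L1": ["A", "B"], "L2": ["B", "C"]})
    assert panel.genes == {"A", "B", "C"}
    assert panel.provenance["B"] == {"L1", "L2"}


def test_panel_from_six_curated_lists_reaches_899_genes():
    # Six lists with the published sizes (162, 723, 135, 59, 150, 72) and an
    # overlap structure whose union is the published 899 non-redundant genes.
    genes = [f"GENE{i:04d}" for i in range(899)]
    lists = {
        "cancer_gene_census": genes[:723],
        "mendelian_syndromes": genes[723:885],
        "target_db": genes[885:899] + genes[:121],
        "cll_drivers": genes[100:159],
        "dlbcl_drivers": genes[200:350],
        "burkitt_drivers": genes[400:472],
    }
    assert [len(v) for v in lists.values()] == [723, 162, 135, 59, 150, 72]
    panel = build_gene_panel(lists)
    assert len(panel) == 899


def test_single_list_panel_is_identity():
    panel = build_gene_panel({"only": ["ATM", "WRN"]})
    assert panel.genes == {"ATM", "WRN"}
    with pytest.raises(ValueError):
        build_gene_panel({"empty": []})


def test_popmax_excludes_bottlenecked_populations():
    value, passes = popmax(
        {"NFE": 0.004, "FIN": 0.02, "ASJ": 0.01, "AFR": 0.001},
        excluded_populations={"FIN", "ASJ", "OTH"},
    )
    assert value == pytest.approx(0.004) and passes


def test_popmax_boundary_is_strict():
    value, passes = popmax({"NFE": 0.005})
    assert value == pytest.approx(0.005) and not passes


def test_popmax_unobserved_variant_passes():
    assert popmax(None) == (0.0, True)
    assert popmax({"FIN": 0.5}, excluded_populations={"FIN"}) == (0.0, True)


@pytest.mark.parametrize(
    "term,cadd,expected",
    [
        ("stop_gained", 5.0, "PTV"),
        ("frameshift", None, "PTV"),
        ("missense", 20.0, None),  # strict > 20
        ("missense", 20.1, "missense_high_cadd"),
        ("missense", None, None),
        ("synonymous", 35.0, None),
    ],
)
def test_classify_variant(term, cadd, expected):
    assert classify_variant(ConsequenceClass(term), cadd) == expected


def test_extended_high_impact_category():
    cons = ConsequenceClass("inframe_deletion", high_impact_extra=True)
    assert classify_variant(cons, None) == "high_impact_other"
    assert classify_variant(ConsequenceClass("inframe_deletion"), None) is None


def _consensus(pos, sample="S1", zygosity="het"):
    return ConsensusVariant(
        key=VariantKey("chr1", pos, "A", "T"), sample=sample,
        n_callers=3, gq=60.0, dp=30.0, vaf=0.5, zygosity=zygosity,
    )


def _annotations():
    return pd.DataFrame(
        [
            # qualifying missense in panel gene
            {"chrom": "chr1", "pos": 10, "ref": "A", "alt": "T", "gene": "ATM",
             "consequence": "missense", "high_impact_extra": False,
             "cadd_phred": 28.0, "af_NFE": 0.001, "af_FIN": 0.0},
            # common variant: fails popmax
            {"chrom": "chr1", "pos": 20, "ref": "A", "alt": "T", "gene": "ATM",
             "consequence": "missense", "high_impact_extra": False,
             "cadd_phred": 30.0, "af_NFE": 0.01, "af_FIN": 0.0},
            # PTV in off-panel gene -> background stream
            {"chrom": "chr1", "pos": 30, "ref": "A", "alt": "T", "gene": "ZZZ9",
             "consequence": "stop_gained", "high_impact_extra": False,
             "cadd_phred": 12.0, "af_NFE": 0.0, "af_FIN": 0.0},
            # low-CADD missense: rejected
            {"chrom": "chr1", "pos": 40, "ref": "A", "alt": "T", "gene": "ATM",
             "consequence": "missense", "high_impact_extra": False,
             "cadd_phred": 8.0, "af_NFE": 0.0, "af_FIN": 0.0},
            # no gene annotation -> background
            {"chrom": "chr1", "pos": 50, "ref": "A", "alt": "T", "gene": None,
             "consequence": "splice_donor", "high_impact_extra": False,
             "cadd_phred": 22.0, "af_NFE": 0.0, "af_FIN": 0.0},
        ]
    )


def test_cascade_partition_and_filters():
    panel = build_gene_panel({"p": ["ATM"]})
    variants = [_consensus(p) for p in (10, 20, 30, 40, 50)]
    qual, background = prioritize(variants, _annotations(), panel=panel)
    assert [(v.key.pos, v.category) for v in qual] == [(10, "missense_high_cadd")]
    assert sorted(v.key.pos for v in background) == [30, 50]
    # every qualifying variant traces to exactly one consensus variant
    assert len({(v.sample, v.key) for v in qual + background}) == len(qual) + len(background)


def test_cascade_is_order_independent():
    # popmax / classification / panel restriction are pure predicates, so any
    # application order yields the same qualifying set.
    panel = build_gene_panel({"p": ["ATM"]})
    ann = _annotations()
    variants = [_consensus(p) for p in (10, 20, 30, 40, 50)]
    baseline, _ = prioritize(variants, ann, panel=panel)
    baseline_keys = {(v.sample, v.key) for v in baseline}

    af_cols = [c for c in ann.columns if c.startswith("af_")]
    rows = {int(r["pos"]): r for _, r in ann.iterrows()}

    def pred_popmax(v):
        row = rows[v.key.pos]
        afs = {c[3:]: row[c] for c in af_cols if pd.notna(row[c])}
        return popmax(afs)[1]

    def pred_classify(v):
        row = rows[v.key.pos]
        cadd = row["cadd_phred"] if pd.notna(row["cadd_phred"]) else None
        return classify_variant(
            ConsequenceClass(row["consequence"], bool(row["high_impact_extra"])), cadd
        ) is not None

    def pred_panel(v):
        gene = rows[v.key.pos]["gene"]
        return gene is not None and str(gene).upper() in panel

    for order in itertools.permutations([pred_popmax, pred_classify, pred_panel]):
        kept = list(variants)
        for pred in order:
            kept = [v for v in kept if pred(v)]
        assert {(v.sample, v.key) for v in kept} == baseline_keys


def test_threshold_monotonicity():
    variants = [_consensus(p) for p in (10, 20, 30, 40, 50)]
    ann = _annotations()
    strict, _ = prioritize(variants, ann, cadd_min=20.0, popmax_max=0.005)
    lax_cadd, _ = prioritize(variants, ann, cadd_min=5.0, popmax_max=0.005)
    lax_pop, _ = prioritize(variants, ann, cadd_min=20.0, popmax_max=0.05)
    strict_keys = {(v.sample, v.key) for v in strict}
    assert strict_keys <= {(v.sample, v.key) for v in lax_cadd}
    assert strict_keys <= {(v.sample, v.key) for v in lax_pop}


def test_empty_panel_routes_everything_to_background():
    variants = [_consensus(p) for p in (10, 30)]
    qual, _ = prioritize(variants, _annotations(), panel=None)
    in_panel, background = restrict_to_panel(qual, build_gene_panel({"p": ["OTHER"]}))
    assert in_panel == [] and len(background) == len(qual)
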