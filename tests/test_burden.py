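"""Carrier collapsing, the one-sided exact burden test, FDR, and lambda."""

import math

import numpy as np
import pandas as pd
import pytest

from lymphgerm.burden import (
    collapse_carriers,
    control_carrier_estimate,
    fdr_adjust,
    fisher_burden,
    genomic_lambda,
)
from lymphgerm.consensus import VariantKey
from lymphgerm.prioritization import QualifyingVariant


def hypergeom_tail_oracle(a, n_cases, c, n_controls):
    """Direct summation of the upper hypergeometric tail with math.comb."""
    total, k = n_cases + n_controls, a + c
    den = math.comb(total, n_cases)
    num = sum(
        math.comb(k, x) * math.comb(total - k, n_cases - x)
        for x in range(a, min(k, n_cases) + 1)
    )
    return num / den


def test_fisher_burden_worked_example():
    # table (3 of 10 cases, 1 of 50 controls):
    # C(4,3)C(56,7) + C(4,4)C(56,6) over C(60,10)
    assert fisher_burden(3, 10, 1, 50) == pytest.approx(0.012734934941093236, rel=1e-12)


def test_fisher_burden_zero_case_carriers_is_one():
    assert fisher_burden(0, 30, 7, 100) == 1.0
    assert fisher_burden(0, 30, 0, 100) == 1.0


def test_fisher_burden_all_cases_carriers_closed_form():
    n, m = 5, 7
    assert fisher_burden(n, n, 0, m) == pytest.approx(1 / math.comb(n + m, n), rel=1e-12)


def test_fisher_burden_matches_enumeration_oracle():
    # exhaustive over all tables with small totals, plus a seeded sample of
    # larger tables with total <= 200
    for total in range(2, 27):
        for n_cases in range(1, total):
            n_controls = total - n_cases
            for k in range(0, total + 1):
                for a in range(max(0, k - n_controls), min(k, n_cases) + 1):
                    c = k - a
                    assert fisher_burden(a, n_cases, c, n_controls) == pytest.approx(
                        hypergeom_tail_oracle(a, n_cases, c, n_controls), rel=1e-9
                    )
    rng = np.random.default_rng(42)
    for _ in range(300):
        total = int(rng.integers(20, 201))
        n_cases = int(rng.integers(1, total))
        n_controls = total - n_cases
        a = int(rng.integers(0, n_cases + 1))
        c = int(rng.integers(0, n_controls + 1))
        assert fisher_burden(a, n_cases, c, n_controls) == pytest.approx(
            hypergeom_tail_oracle(a, n_cases, c, n_controls), rel=1e-9
        )


def qv(pos, sample, gene="ATM", category="PTV"):
    return QualifyingVariant(
        key=VariantKey("chr1", pos, "A", "T"), sample=sample, gene=gene,
        category=category, cadd_phred=None, popmax=0.0, zygosity="het",
        consequence="stop_gained",
    )


def test_dominant_collapsing_counts_each_patient_once():
    variants = [qv(10, "P1"), qv(20, "P1"), qv(30, "P1")]
    assert collapse_carriers(variants, "ptv_only") == {"ATM": {"P1"}}


def test_disjoint_carrier_sets_add():
    variants = [qv(10, f"P{i}") for i in range(8)] + [qv(20, f"Q{i}") for i in range(7)]
    assert len(collapse_carriers(variants)["ATM"]) == 15


def test_model_restricts_categories():
    variants = [
        qv(10, "P1", category="PTV"),
        qv(20, "P2", category="missense_high_cadd"),
        qv(30, "P3", category="high_impact_other"),
    ]
    assert collapse_carriers(variants, "ptv_only")["ATM"] == {"P1"}
    assert collapse_carriers(variants, "ptv_plus_high_impact")["ATM"] == {"P1", "P3"}
    assert collapse_carriers(variants)["ATM"] == {"P1", "P2", "P3"}


def test_adding_a_variant_never_decreases_carriers():
    base = [qv(10, "P1"), qv(20, "P2")]
    more = base + [qv(30, "P3")]
    assert len(collapse_carriers(more)["ATM"]) >= len(collapse_carriers(base)["ATM"])


def test_control_carrier_estimate_sums_and_caps():
    df = pd.DataFrame([{"ac": 3, "an": 31416}, {"ac": 5, "an": 31416}])
    assert control_carrier_estimate(df, 15708) == 8
    big = pd.DataFrame([{"ac": 20000, "an": 31416}])
    assert control_carrier_estimate(big, 15708) == 15708
    assert control_carrier_estimate(pd.DataFrame(columns=["ac", "an"]), 15708) == 0


def test_control_estimate_missing_an_contributes_zero(caplog):
    df = pd.DataFrame([{"ac": 3, "an": np.nan}, {"ac": 2, "an": 31416}])
    assert control_carrier_estimate(df, 15708) == 2


def test_bh_adjustment_hand_example():
    assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert fdr_adjust([0.5]) == pytest.approx([0.5])
    assert list(fdr_adjust([])) == []


def test_bh_is_monotone_and_dominates_p():
    rng = np.random.default_rng(0)
    p = rng.random(50)
    q = fdr_adjust(p)
    assert np.all(q >= p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_lambda_examples():
    assert genomic_lambda([0.5]) == pytest.approx(1.0)
    rng = np.random.default_rng(1)
    assert genomic_lambda(rng.random(10000)) == pytest.approx(1.0, abs=0.05)
    assert genomic_lambda([1e-6] * 10) > 1.0
    assert genomic_lambda([1.0, 1.0]) == 0.0
    with pytest.raises(ValueError):
        genomic_lambda([])
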