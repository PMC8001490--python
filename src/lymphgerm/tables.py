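"""Packaged transcriptions of the published per-variant tables.

Two small reference tables ship with the package: the homozygote /
germline-double-hit catalog (one row per patient-gene event; one homozygote
row lists two semicolon-separated patients sharing the same variant) and the
WRN variant table for CLL survival (per-variant occurrence counts, two
variants flagged as co-occurring in a single compound-heterozygous patient).
The counting helpers here reconcile patient-level and occurrence-level
numbers from those tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("lymphgerm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_double_hit_table() -> pd.DataFrame:
    """Homozygote and germline-double-hit events (one row per patient-gene,
    except shared homozygous variants which list all patients)."""
    return _load("double_hit_table.tsv")


def load_wrn_table() -> pd.DataFrame:
    """WRN qualifying variants in CLL with per-variant occurrence counts."""
    df = _load("wrn_variant_table.tsv")
    df["cll_cases"] = df["cll_cases"].astype(int)
    return df


def count_double_hit_patients(table: pd.DataFrame | None = None) -> int:
    """Distinct patients with a germline double hit."""
    table = load_double_hit_table() if table is None else table
    rows = table[table["zygosity"] == "germline_double_hit"]
    patients = {p for ids in rows["case_id"] for p in str(ids).split(";")}
    return len(patients)


def count_homozygous_variants(table: pd.DataFrame | None = None) -> int:
    """Distinct homozygous variants (a variant shared by several patients
    counts once)."""
    table = load_double_hit_table() if table is None else table
    return int((table["zygosity"] == "homozygote").sum())


def count_homozygote_patients(table: pd.DataFrame | None = None) -> int:
    """Distinct patients carrying a homozygous qualifying variant."""
    table = load_double_hit_table() if table is None else table
    rows = table[table["zygosity"] == "homozygote"]
    patients = {p for ids in rows["case_id"] for p in str(ids).split(";")}
    return len(patients)


def distinct_carriers_from_occurrences(table: pd.DataFrame | None = None) -> int:
    """Distinct carriers implied by per-variant occurrence counts.

    Variants flagged ``in_compound_het_patient`` share one patient per
    flagged group: that patient is counted once, not once per variant.
    """
    table = load_wrn_table() if table is None else table
    total = int(table["cll_cases"].sum())
    n_flagged = int((table["in_compound_het_patient"] == "yes").sum())
    if n_flagged >= 2:
        total -= n_flagged - 1
    return total
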