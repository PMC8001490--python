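"""Synthetic study generator: validation, determinism, planted structure."""

import filecmp
import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from lymphgerm.synthetic_cohort import (
    CALLERS,
    DEFAULT_TYPE_MIX,
    CohortSpec,
    generate_cohort,
    simulate_cohort,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 1},
        {"subgroup_fractions": {"CLL": 0.6, "lymphoma": 0.3}},
        {"background_qualifying_rate": 1.5},
        {"chip_rate": -0.1},
        {"survival_genes": [("G0001", 0.0)]},
        {"panel_size": 0},
        {"panel_size": 200, "n_genes": 100},
    ],
)
def test_invalid_specs_are_rejected(kwargs):
    with pytest.raises(ValueError):
        CohortSpec(**kwargs)


def _tree_digest(root: Path) -> dict[str, str]:
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return out


def test_same_seed_gives_byte_identical_output(tmp_path):
    spec = CohortSpec(n_patients=8, n_genes=12, panel_size=8, seed=5)
    a = generate_cohort(spec, tmp_path / "a")
    b = generate_cohort(spec, tmp_path / "b")
    da, db = _tree_digest(a.root), _tree_digest(b.root)
    assert da == db and len(da) > 10


def test_full_sensitivity_puts_every_variant_in_all_callers(tmp_path):
    spec = CohortSpec(
        n_patients=10, n_genes=15, panel_size=10, seed=3,
        caller_sensitivity=1.0, qc_fail_rate=0.0,
    )
    bundle = generate_cohort(spec, tmp_path)
    sim = simulate_cohort(spec)
    catalog = sim.catalog.set_index("var_id")
    # parse emitted VCFs as text (independent of the writer's library)
    for r in sim.occurrences.itertuples(index=False):
        var = catalog.loc[r.var_id]
        for caller in CALLERS:
            vcf = bundle.vcf_dir / f"{r.patient}.{caller}.vcf"
            positions = set()
            for line in vcf.read_text().splitlines():
                if line.startswith("#"):
                    continue
                chrom, pos = line.split("\t")[:2]
                positions.add(int(pos))
            # the un-normalizing caller may anchor indels at the same start
            assert any(abs(p - int(var["pos"])) <= 2 for p in positions)


def test_variant_type_mix_matches_configuration_within_2pp():
    spec = CohortSpec(n_patients=2, n_genes=2600, panel_size=2600, seed=13,
                      noise_rate=0.0)
    sim = simulate_cohort(spec)
    pool = sim.catalog[sim.catalog["role"] == "pool"]
    assert len(pool) >= 10000
    observed = pool["variant_type"].value_counts(normalize=True) * 100
    for vtype, pct in DEFAULT_TYPE_MIX.items():
        assert observed.get(vtype, 0.0) == pytest.approx(pct, abs=2.0)


def test_planted_enrichment_detected_by_binomial_oracle():
    spec = CohortSpec(
        n_patients=500, n_genes=20, panel_size=20, seed=17,
        enriched_genes=[("G0001", 10.0)],
        compound_het_rate=0, homozygote_rate=0, chip_rate=0,
        somatic_second_hit_rate=0, loh_second_hit_rate=0, noise_rate=0.0,
    )
    sim = simulate_cohort(spec)
    carriers = len(sim.truth.carriers.get("G0001", []))
    p = stats.binomtest(
        carriers, 500, spec.background_qualifying_rate, alternative="greater"
    ).pvalue
    assert p < 0.01


def test_every_planted_event_has_an_emitted_record(recovery_bundle):
    """SyntheticTruth invariant: planted events appear in the written files."""
    truth = recovery_bundle.truth
    vcf_text = "".join(
        p.read_text() for p in sorted(recovery_bundle.vcf_dir.glob("*.callerA.vcf"))
    )
    for event in truth.homozygotes + truth.chip + truth.loh_second_hits:
        chrom, pos, _ = event["variant"].split(":", 2)
        assert f"\t{pos}\t" in vcf_text
    somatic_text = recovery_bundle.somatic_table.read_text()
    for event in truth.germline_somatic:
        assert event["patient"] in somatic_text
    clinical_text = recovery_bundle.clinical_table.read_text()
    assert "os_time" in clinical_text and "ttft_time" in clinical_text


def test_null_cohort_produces_no_planted_findings():
    spec = CohortSpec(
        n_patients=60, n_genes=30, panel_size=20, seed=19,
        compound_het_rate=0, homozygote_rate=0, chip_rate=0,
        somatic_second_hit_rate=0, loh_second_hit_rate=0,
        caller_sensitivity=1.0, qc_fail_rate=0.0,
    )
    sim = simulate_cohort(spec)
    assert sim.truth.homozygotes == []
    assert sim.truth.compound_hets == []
    assert sim.truth.chip == []
    assert sim.truth.germline_somatic == []
    assert sim.truth.loh_second_hits == []
    # and no occurrence carries one of the planted roles
    assert set(sim.occurrences["role"]) <= {"background", "noise"}


def test_survival_null_hr_cis_cover_one_in_most_replicates():
    """Planted hazard ratio 1 for all genes: the fitted carrier CI covers 1
    in at least 90% of replicates."""
    from lymphgerm.survival import cox_association

    covered = 0
    total = 0
    for seed in range(20):
        spec = CohortSpec(
            n_patients=300, n_genes=5, panel_size=5, seed=100 + seed,
            subgroup_fractions={"CLL": 1.0},
            enriched_genes=[("G0001", 10.0)],
            compound_het_rate=0, homozygote_rate=0, chip_rate=0,
            somatic_second_hit_rate=0, loh_second_hit_rate=0, noise_rate=0.0,
        )
        sim = simulate_cohort(spec)
        carriers = set(sim.truth.carriers.get("G0001", []))
        if len(carriers) < 5:
            continue
        res = cox_association(sim.clinical, carriers, "OS")
        total += 1
        if res.ci95[0] <= 1.0 <= res.ci95[1]:
            covered += 1
    assert total >= 15
    assert covered / total >= 0.9
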