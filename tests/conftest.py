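import pytest

from lymphgerm.pipeline import RunConfig, run_pipeline
from lymphgerm.synthetic_cohort import CohortSpec, generate_cohort


def make_run_config(bundle, out_dir, **overrides) -> RunConfig:
    """RunConfig wired to a written synthetic bundle."""
    kwargs = dict(
        vcf_dir=str(bundle.vcf_dir),
        reference_fasta=str(bundle.reference_fasta),
        popaf_table=str(bundle.popaf_table),
        cadd_table=str(bundle.cadd_table),
        consequence_table=str(bundle.consequence_table),
        clinical_table=str(bundle.clinical_table),
        panel_files={"panel": str(bundle.panel_file)},
        chip_gene_file=str(bundle.chip_gene_file),
        tumor_vaf_table=str(bundle.tumor_vaf_table),
        somatic_table=str(bundle.somatic_table),
        loh_table=str(bundle.loh_table),
        control_counts=str(bundle.control_counts),
        excluded_bed=str(bundle.excluded_bed),
        known_variants=str(bundle.known_variants),
        out_dir=str(out_dir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def recovery_spec():
    """Noise-free study with boosted event rates so every planted-event kind
    occurs several times at this cohort size."""
    return CohortSpec(
        n_patients=40,
        n_genes=30,
        panel_size=20,
        compound_het_rate=0.15,
        homozygote_rate=0.15,
        chip_rate=0.15,
        somatic_second_hit_rate=0.20,
        loh_second_hit_rate=0.10,
        caller_sensitivity=1.0,
        qc_fail_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def recovery_bundle(recovery_spec, tmp_path_factory):
    return generate_cohort(recovery_spec, tmp_path_factory.mktemp("recovery_cohort"))


@pytest.fixture(scope="session")
def recovery_run(recovery_bundle, tmp_path_factory):
    """Full pipeline run over the noise-free bundle."""
    out = tmp_path_factory.mktemp("recovery_run")
    cfg = make_run_config(recovery_bundle, out)
    manifest = run_pipeline(cfg)
    return recovery_bundle, out, manifest
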