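import pytest

from hlaensemble import (
    CallRecord,
    Genotype,
    SimConfig,
    parse_allele,
    simulate_cohort_reads,
    simulate_reference,
    to_two_field,
)


def allele(text: str):
    return parse_allele(text)


def genotype(gene: str, *allele_texts: str) -> Genotype:
    return Genotype(gene, tuple(to_two_field(parse_allele(t)) for t in allele_texts))


def rec(
    patient: str,
    tool: str,
    source: str,
    level: str,
    gene: str,
    *allele_texts: str,
    quality_value=None,
    quality_class="unavailable",
    status="ok",
) -> CallRecord:
    return CallRecord(
        patient_id=patient,
        tool=tool,
        source=source,
        filter_level=level,
        gene=gene,
        genotype=genotype(gene, *allele_texts),
        quality_value=quality_value,
        quality_class=quality_class,
        status=status,
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A tiny deterministic cohort: 3 patients, 5 loci, clean reads."""
    return SimConfig(
        n_patients=3,
        alleles_per_gene=4,
        allele_length=600,
        pairs_per_haplotype=3,
        background_pairs=30,
        base_error_rate=0.0,
        call_error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_reference(small_cfg):
    db, ancestors = simulate_reference(small_cfg)
    return db


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_reference):
    return simulate_cohort_reads(small_reference, small_cfg)
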