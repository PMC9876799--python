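import warnings

import pytest

from b2mcall import (
    PhasingObservation,
    SampleGenomics,
    SimulationConfig,
    SomaticMutation,
    simulate_cohort,
)


def make_mutation(
    mutation_id="m1",
    gene="B2M",
    vaf=0.5,
    effect="non_synonymous",
    subclonal_probability=0.0,
    pos=100,
):
    return SomaticMutation(
        mutation_id=mutation_id,
        gene=gene,
        chrom="15",
        pos=pos,
        ref="A",
        alt="T",
        vaf=vaf,
        effect=effect,
        subclonal_probability=subclonal_probability,
    )


def make_genomics(
    sample_id="s1", purity=0.5, gene_total_cn=2, gene_minor_cn=None
):
    return SampleGenomics(
        sample_id=sample_id,
        purity=purity,
        gene_total_cn=gene_total_cn,
        gene_minor_cn=gene_minor_cn,
    )


def phasing_obs(id_a, id_b, relation):
    if relation == "cis":
        return PhasingObservation(id_a, id_b, spanning_reads_both_alt=3)
    if relation == "trans":
        return PhasingObservation(
            id_a, id_b, spanning_reads_a_only=4, spanning_reads_b_only=5
        )
    return PhasingObservation(id_a, id_b)


def call_classes(cohort, gene="B2M"):
    """Classify every sample of a cohort; returns {sample_id: call}."""
    from b2mcall import classify_allelic_status

    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, genome in cohort.genomics.items():
            out[sid] = classify_allelic_status(
                cohort.mutations[sid], genome, cohort.phasing[sid], gene=gene
            )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimulationConfig(n_samples=80, seed=42))


@pytest.fixture(scope="session")
def recovery_cohort():
    return simulate_cohort(
        SimulationConfig(
            n_samples=500, depth=80.0, purity_range=(0.3, 0.9), seed=7
        )
    )
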