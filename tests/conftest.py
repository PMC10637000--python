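import pytest

from teactivity import (
    GeneModel,
    GenomicInterval,
    SimulationParams,
    TEIntegrant,
    build_promoters,
    merge_fragments,
    simulate_annotation,
    simulate_counts,
)


def make_gene(gene_id, chrom, tss, exons, strand="+"):
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tss=sorted(tss),
        promoters=build_promoters(sorted(tss), chrom),
        exon_union=[GenomicInterval(chrom, s, e) for s, e in exons],
    )


def make_te(chrom, start, end, subfamily, strand="+", instance=None):
    return TEIntegrant(
        GenomicInterval(chrom, start, end, strand),
        subfamily,
        instance or f"{subfamily}:{chrom}:{start}",
    )


@pytest.fixture
def toy_genes():
    """Three genes on one chromosome with known promoters/exons/windows."""
    return [
        make_gene("gA", "chr1", [100_000], [(101_000, 102_000)]),
        make_gene("gB", "chr1", [300_000, 300_400], [(301_000, 302_500)]),
        make_gene("gC", "chr1", [700_000], [(701_000, 701_800)]),
    ]


@pytest.fixture(scope="session")
def standard_params():
    return SimulationParams(seed=0)


@pytest.fixture(scope="session")
def standard_annotation(standard_params):
    return simulate_annotation(standard_params)


@pytest.fixture(scope="session")
def standard_experiment(standard_params, standard_annotation):
    return simulate_counts(standard_annotation, standard_params, seed=1)


@pytest.fixture(scope="session")
def standard_merged(standard_annotation):
    return merge_fragments(standard_annotation.tes)
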