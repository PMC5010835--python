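import pytest

from quadprio import (
    AnnotatedVariant,
    GenotypeCall,
    RunConfig,
    VariantAnnotation,
    VariantRecord,
    make_worked_example,
    prioritize,
)
from quadprio.simulate import default_quad_pedigree


@pytest.fixture(scope="session")
def quad():
    """Default quad: female affected proband, male unaffected sibling."""
    return default_quad_pedigree()


def call(*alleles, gq=99, dp=50):
    return GenotypeCall(alleles=tuple(alleles), gq=gq, dp=dp)


def make_variant(
    proband,
    mother,
    father,
    sibling,
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    gene="GENE1",
    functional_class="nonsynonymous",
    maf=None,
    variant_id=None,
):
    """Build an AnnotatedVariant from genotype tuples, e.g. (0, 1)."""
    calls = {
        "proband": proband if isinstance(proband, GenotypeCall) else call(*proband),
        "mother": mother if isinstance(mother, GenotypeCall) else call(*mother),
        "father": father if isinstance(father, GenotypeCall) else call(*father),
        "sibling": sibling if isinstance(sibling, GenotypeCall) else call(*sibling),
    }
    return AnnotatedVariant(
        record=VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt, calls=calls, variant_id=variant_id
        ),
        annotation=VariantAnnotation(gene=gene, functional_class=functional_class, maf=maf),
    )


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    """The myopathy-quad fixture dataset written to disk once per session."""
    return make_worked_example(tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def worked_example_report(worked_example, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_out")
    config = RunConfig.build(
        vcf=worked_example.vcf,
        ped=worked_example.ped,
        annotations=worked_example.annotations,
        genes=worked_example.genes,
        out_dir=out,
    )
    return prioritize(config)
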