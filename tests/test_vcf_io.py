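import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadprio import (
    GenotypeCall,
    genotype_equal,
    normalize_chrom,
    read_quad_vcf,
    write_quad_vcf,
)
from quadprio.vcf_io import (
    SampleMissingError,
    VcfError,
    normalize_male_sex_chrom_call,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=10>
##contig=<ID=X>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFATHER\tMOTHER\tPROBAND\tBROTHER
"""


def write_vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


def gt(father, mother, proband, brother, chrom="1", pos=100, ref="A", alt="G"):
    cols = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:GQ:DP"]
    cols += [f"{g}:99:50" for g in (father, mother, proband, brother)]
    return "\t".join(cols) + "\n"


def test_female_x_site_normalizes_males_to_haploid(tmp_path, quad):
    """An X site with diploid-style male calls yields haploid father/brother."""
    path = write_vcf(tmp_path, gt("0/0", "0/1", "0/1", "0/0", chrom="X", pos=135291325))
    (rec,) = read_quad_vcf(path, quad)
    assert rec.calls["father"].alleles == (0,)
    assert rec.calls["sibling"].alleles == (0,)
    assert rec.calls["proband"].is_het and rec.calls["mother"].is_het


def test_triallelic_site_decomposes_into_biallelic_records(tmp_path, quad):
    """Proband 1/2 at A->{G,T}: the G record carries {1, missing}, the T
    record {missing, 1}; allele mass is conserved across the decomposition."""
    path = write_vcf(tmp_path, gt("0/0", "0/1", "1/2", "0/2", alt="G,T"))
    recs = read_quad_vcf(path, quad)
    assert [(r.alt, r.ref) for r in recs] == [("G", "A"), ("T", "A")]
    g_rec, t_rec = recs
    assert sorted(g_rec.calls["proband"].alleles, key=str) == [1, None]
    assert sorted(t_rec.calls["proband"].alleles, key=str) == [1, None]
    # each sample's non-missing alt allele appears in exactly one record
    for role in ("proband", "mother", "father", "sibling"):
        n_alt = sum(
            sum(a == 1 for a in r.calls[role].alleles) for r in recs
        )
        expected = {"proband": 2, "mother": 1, "father": 0, "sibling": 1}
        assert n_alt == expected[role]


@pytest.mark.parametrize(
    "gt_str, expected",
    [
        ("0/0", (0,)),
        ("1/1", (1,)),
        ("0/1", (None,)),  # het male X is invalid-for-sex -> missing
        ("1/0", (None,)),
        ("./.", (None,)),
        ("./0", (None,)),
        ("1/.", (None,)),
        ("0", (0,)),
        ("1", (1,)),
        (".", (None,)),
    ],
)
def test_male_x_genotype_normalization_table(tmp_path, quad, gt_str, expected):
    """Every male X GT string maps to the expected haploid call."""
    path = write_vcf(tmp_path, gt(gt_str, "0/1", "0/1", "0", chrom="X"))
    (rec,) = read_quad_vcf(path, quad)
    assert rec.calls["father"].alleles == expected


def test_unsorted_input_is_sorted(tmp_path, quad):
    body = (
        gt("0/0", "0/1", "0/1", "0/0", chrom="X", pos=5)
        + gt("0/0", "0/1", "0/1", "0/0", chrom="10", pos=9)
        + gt("0/0", "0/1", "0/1", "0/0", chrom="10", pos=3)
        + gt("0/0", "0/1", "0/1", "0/0", chrom="1", pos=7)
    )
    recs = read_quad_vcf(write_vcf(tmp_path, body), quad)
    assert [(r.chrom, r.pos) for r in recs] == [("1", 7), ("10", 3), ("10", 9), ("X", 5)]


def test_missing_sample_raises(tmp_path, quad):
    p = tmp_path / "bad.vcf"
    p.write_text(HEADER.replace("BROTHER", "SOMEONE_ELSE"))
    with pytest.raises(SampleMissingError, match="sample not in VCF"):
        read_quad_vcf(p, quad)


def test_missing_gt_field_raises(tmp_path, quad):
    body = "1\t100\t.\tA\tG\t.\tPASS\t.\tDP\t50\t50\t50\t50\n"
    with pytest.raises(VcfError, match="GT required"):
        read_quad_vcf(write_vcf(tmp_path, body), quad)


def test_symbolic_alleles_are_skipped(tmp_path, quad):
    body = gt("0/0", "0/1", "0/1", "0/0") + gt(
        "0/0", "0/1", "0/1", "0/0", pos=200, alt="<DEL>"
    )
    recs = read_quad_vcf(write_vcf(tmp_path, body), quad)
    assert len(recs) == 1 and recs[0].pos == 100


def test_write_read_round_trip(tmp_path, quad):
    """read -> write -> read is the identity on normalized biallelic files."""
    body = (
        gt("0/0", "0/1", "0/1", "0/0", chrom="1", pos=10)
        + gt("0/1", "0/0", "0/1", "0/1", chrom="10", pos=20, ref="C", alt="T")
        + gt("0", "0/1", "0/1", "0", chrom="X", pos=30)
    )
    first = read_quad_vcf(write_vcf(tmp_path, body), quad)
    out = tmp_path / "rt.vcf"
    write_quad_vcf(out, first, quad)
    second = read_quad_vcf(out, quad)
    assert [(r.chrom, r.pos, r.ref, r.alt) for r in first] == [
        (r.chrom, r.pos, r.ref, r.alt) for r in second
    ]
    for a, b in zip(first, second):
        for role in ("proband", "mother", "father", "sibling"):
            assert a.calls[role].alleles == b.calls[role].alleles
            assert a.calls[role].gq == b.calls[role].gq
            assert a.calls[role].dp == b.calls[role].dp


@pytest.mark.parametrize(
    "a, b, equal",
    [
        ((0, 1), (1, 0), True),
        ((0, 1), (1, 1), False),
        ((0, None), (0, 1), False),  # missing never asserts identity
        ((None, None), (None, None), False),
        ((0,), (0, 0), False),  # haploid vs diploid differ
    ],
)
def test_genotype_equal_semantics(a, b, equal):
    assert genotype_equal(GenotypeCall(alleles=a), GenotypeCall(alleles=b)) is equal


allele_sets = st.lists(st.sampled_from([0, 1]), min_size=1, max_size=2).map(tuple)


@settings(derandomize=True)
@given(a=allele_sets, b=allele_sets)
def test_genotype_equal_symmetric_and_reflexive(a, b):
    ca, cb = GenotypeCall(alleles=a), GenotypeCall(alleles=b)
    assert genotype_equal(ca, ca)
    assert genotype_equal(ca, cb) == genotype_equal(cb, ca)


@pytest.mark.parametrize(
    "label, expected",
    [("chr10", "10"), ("10", "10"), ("chrX", "X"), ("x", "X"), ("chrM", "MT"), ("MT", "MT")],
)
def test_chromosome_label_normalization(label, expected):
    assert normalize_chrom(label) == expected


def test_male_call_normalization_is_idempotent():
    for alleles in [(0, 0), (0, 1), (1, 1), (None, None), (0,), (1,), (None,)]:
        once = normalize_male_sex_chrom_call(GenotypeCall(alleles=alleles))
        assert normalize_male_sex_chrom_call(once) == once
        assert once.ploidy == 1
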