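import pytest

from introcaps.trio import GeneModel, Genotype, TrioVariantSite


def make_site(chrom="chr1", pos=100, ref="A", alt="C", qual=50.0,
              donor=Genotype.HOM_ALT, recipient=Genotype.HOM_REF,
              line=Genotype.HOM_ALT) -> TrioVariantSite:
    return TrioVariantSite(chrom, pos, ref, alt, qual, donor, recipient, line)


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def plus_gene():
    """Gene on + strand: 5' UTR 1001-1100 (inside exon 1), 3' UTR 3901-4000
    (inside last exon), introns between exons."""
    return GeneModel(
        gene_id="gplus", chrom="chr1", start=1001, end=4000, strand="+",
        exons=((1001, 1500), (2001, 2500), (3501, 4000)),
        five_prime_utrs=((1001, 1100),),
        three_prime_utrs=((3901, 4000),))


@pytest.fixture
def minus_gene():
    """Gene on - strand: 5' UTR at the high-coordinate end."""
    return GeneModel(
        gene_id="gminus", chrom="chr1", start=20001, end=23000, strand="-",
        exons=((20001, 20500), (22501, 23000)),
        five_prime_utrs=((22901, 23000),),
        three_prime_utrs=((20001, 20100),))
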