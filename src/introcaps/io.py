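"""Reading and writing the standard formats around the pipeline.

VCF goes through pysam/htslib, GFF3 reading through gffutils, FASTA through
Biopython.  All external coordinates follow the formats' conventions: VCF
and GFF3 are 1-based closed, BED is 0-based half-open.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trio import GeneModel, Genotype, TrioVariantSite

_GT_TUPLES = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HOM_ALT: (1, 1),
    Genotype.HET: (0, 1),
    Genotype.MISSING: (None, None),
}


def _code_genotype(allele_indices: tuple | None, alt_index: int) -> Genotype:
    """Collapse a diploid GT tuple onto one alt allele of a split record."""
    if allele_indices is None or any(a is None for a in allele_indices):
        return Genotype.MISSING
    distinct = set(allele_indices)
    if len(distinct) > 1:
        return Genotype.HET
    (allele,) = distinct
    if allele == 0:
        return Genotype.HOM_REF
    if allele == alt_index:
        return Genotype.HOM_ALT
    return Genotype.HOM_OTHER


def read_trio_vcf(path: str | Path, donor: str, recipient: str, line: str,
                  ) -> tuple[list[TrioVariantSite], dict[str, int]]:
    """Read a multi-sample VCF into biallelic trio sites.

    Multiallelic records are split: one site per alternate allele, with each
    sample's genotype recoded against that allele (a genotype homozygous for
    a different alternate becomes HOM_OTHER, which downstream parental
    assignment treats as a potential conflict).  Returns the sites and the
    contig lengths declared in the header.
    """
    sites: list[TrioVariantSite] = []
    with pysam.VariantFile(str(path)) as vf:
        for name in (donor, recipient, line):
            if name not in vf.header.samples:
                raise KeyError(f"sample {name!r} not in VCF header")
        contigs = {c: ctg.length for c, ctg in vf.header.contigs.items()
                   if ctg.length is not None}
        for rec in vf:
            if not rec.alts:
                continue
            for ai, alt in enumerate(rec.alts, start=1):
                gts = tuple(
                    _code_genotype(rec.samples[s].get("GT"), ai)
                    for s in (donor, recipient, line))
                sites.append(TrioVariantSite(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    qual=float(rec.qual) if rec.qual is not None else 0.0,
                    gt_donor=gts[0], gt_recipient=gts[1], gt_line=gts[2]))
    return sites, contigs


def write_trio_vcf(path: str | Path, sites: Sequence[TrioVariantSite],
                   sample_names: Sequence[str],
                   contigs: Mapping[str, int]) -> None:
    """Write biallelic trio sites as a 3-sample VCF v4.2 (GT + QUAL)."""
    if len(sample_names) != 3:
        raise ValueError("expected exactly three sample names (donor, recipient, line)")
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for s in sites:
            rec = vf.new_record(contig=s.chrom, start=s.pos - 1,
                                alleles=(s.ref, s.alt), qual=s.qual)
            for name, gt in zip(sample_names, (s.gt_donor, s.gt_recipient, s.gt_line)):
                rec.samples[name]["GT"] = _GT_TUPLES[gt]
            vf.write(rec)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read single-transcript gene models with exon/UTR structure from GFF3."""
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        def intervals(ftype: str) -> tuple[tuple[int, int], ...]:
            return tuple(sorted((f.start, f.end)
                                for f in db.children(g, featuretype=ftype)))
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, start=g.start, end=g.end,
            strand=g.strand, exons=intervals("exon"),
            five_prime_utrs=intervals("five_prime_UTR"),
            three_prime_utrs=intervals("three_prime_UTR")))
    return genes


def write_gene_models_gff3(genes: Iterable[GeneModel], path: str | Path,
                           source: str = "introcaps") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            for ftype, ivs in (("exon", g.exons),
                               ("five_prime_UTR", g.five_prime_utrs),
                               ("three_prime_UTR", g.three_prime_utrs)):
                for a, b in ivs:
                    fh.write(f"{g.chrom}\t{source}\t{ftype}\t{a}\t{b}\t.\t"
                             f"{g.strand}\t.\tParent={tid}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
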