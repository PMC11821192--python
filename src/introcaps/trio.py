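"""Trio-based introgression block mapping.

An introgression line carries a small chromosomal segment from a donor
genotype inside a recipient genetic background.  Given variant calls for
the trio (donor parent, recipient parent, derived line), each biallelic
site where the line's homozygous allele matches one parent and differs
from the other reveals local parental origin; runs of donor-origin sites
delineate the introgressed blocks.  Variants are additionally classified
against gene models (5' UTR / exon / 3' UTR / intron / upstream /
downstream / intergenic); only genic classes (UTRs and exons) enter the
gene-origin bookkeeping, mirroring how annotation-based variant filtering
is done before functional interpretation.

:class:`TrioIntrogressionModel` bundles the pipeline statsmodels-style: the
model is built from the data (sites + gene models), ``fit()`` runs quality
filtering, parental assignment, region classification, gene-origin calling
and block detection, and returns an :class:`IntrogressionResults` with the
tables, the genome-wide inheritance fraction and a ``summary()``.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class Genotype(str, Enum):
    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    MISSING = "MISSING"
    HOM_OTHER = "HOM_OTHER"  # homozygous for a different alt of a split record


class ParentalAssignment(str, Enum):
    DONOR = "DONOR"
    RECIPIENT = "RECIPIENT"
    UNINFORMATIVE = "UNINFORMATIVE"
    CONFLICT = "CONFLICT"


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "indel"


class RegionClass(str, Enum):
    FIVE_UTR = "FIVE_UTR"
    EXON = "EXON"
    THREE_UTR = "THREE_UTR"
    INTRON = "INTRON"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


#: classes retained for gene-level analysis (genic, non-intronic)
RETAINED_CLASSES = (RegionClass.FIVE_UTR, RegionClass.EXON, RegionClass.THREE_UTR)

#: precedence when a position falls in several feature classes of a gene
_CLASS_RANK = {RegionClass.FIVE_UTR: 0, RegionClass.THREE_UTR: 0,
               RegionClass.EXON: 1, RegionClass.INTRON: 2}


class GeneOrigin(str, Enum):
    DONOR = "DONOR"
    RECIPIENT = "RECIPIENT"
    NON_POLYMORPHIC = "NON_POLYMORPHIC"
    CONFLICT = "CONFLICT"


@dataclass(frozen=True)
class TrioVariantSite:
    """One biallelic variant with the three genotypes of the trio.

    ``pos`` is 1-based (VCF convention); for indels it is the anchor-base
    position of the record.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    gt_donor: Genotype
    gt_recipient: Genotype
    gt_line: Genotype

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    @property
    def variant_class(self) -> VariantClass:
        return VariantClass.SNV if len(self.ref) == 1 and len(self.alt) == 1 \
            else VariantClass.INDEL


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene with exon and UTR intervals (1-based closed)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    five_prime_utrs: tuple[tuple[int, int], ...] = ()
    three_prime_utrs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name, ivs in (("exon", self.exons), ("five_prime_UTR", self.five_prime_utrs),
                          ("three_prime_UTR", self.three_prime_utrs)):
            prev_end = None
            for a, b in ivs:
                if a > b or a < self.start or b > self.end:
                    raise ValueError(f"{self.gene_id}: bad {name} interval ({a},{b})")
                if prev_end is not None and a <= prev_end:
                    raise ValueError(f"{self.gene_id}: {name} intervals overlap/unsorted")
                prev_end = b

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class IntrogressionBlock:
    """A contiguous donor-derived segment, bounded by its supporting sites."""

    chrom: str
    start: int
    end: int
    n_donor_sites: int
    n_interior_other: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BlockSummary:
    block: IntrogressionBlock
    span: int
    gene_count: int
    gene_ids: tuple[str, ...]


@dataclass(frozen=True)
class InheritanceSummary:
    """Genome-wide gene-origin counts and the donor inheritance fraction."""

    donor_genes: int
    recipient_genes: int
    non_polymorphic_genes: int
    conflict_genes: int

    @property
    def fraction_percent(self) -> float:
        return inheritance_fraction(self.donor_genes, self.recipient_genes)


# ---------------------------------------------------------------------------
# elementary operations

def filter_quality(sites: Iterable[TrioVariantSite],
                   min_quality: float = 20.0) -> list[TrioVariantSite]:
    """Retain sites with QUAL >= min_quality (inclusive), preserving order."""
    if min_quality < 0:
        raise ValueError("min_quality must be >= 0")
    return [s for s in sites if s.qual >= min_quality]


def assign_parent(site: TrioVariantSite) -> ParentalAssignment:
    """Parental origin of one site from the trio genotypes.

    Only fixed differences are informative: a heterozygous or missing
    genotype anywhere, or parents in the same state, make the site
    UNINFORMATIVE.  A homozygous line state matching neither parent (an
    allele private to the line, e.g. from a split multiallelic record) is a
    CONFLICT.
    """
    gts = (site.gt_donor, site.gt_recipient, site.gt_line)
    if any(g in (Genotype.HET, Genotype.MISSING) for g in gts):
        return ParentalAssignment.UNINFORMATIVE
    if site.gt_donor == site.gt_recipient:
        return ParentalAssignment.UNINFORMATIVE
    if site.gt_line == site.gt_donor:
        return ParentalAssignment.DONOR
    if site.gt_line == site.gt_recipient:
        return ParentalAssignment.RECIPIENT
    return ParentalAssignment.CONFLICT


class GeneIndex:
    """Chromosome-indexed gene models supporting region classification."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = list(genes)
        self._bodies: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._bodies.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
        self._warned: set[str] = set()

    @staticmethod
    def _within_gene(gene: GeneModel, pos: int) -> RegionClass:
        for a, b in gene.five_prime_utrs:
            if a <= pos <= b:
                return RegionClass.FIVE_UTR
        for a, b in gene.three_prime_utrs:
            if a <= pos <= b:
                return RegionClass.THREE_UTR
        for a, b in gene.exons:
            if a <= pos <= b:
                return RegionClass.EXON
        return RegionClass.INTRON

    def classify(self, chrom: str, pos: int,
                 flank_window: int = 5000) -> tuple[RegionClass, str | None]:
        """(RegionClass, gene id) for a position; gene id is None when
        intergenic."""
        if flank_window <= 0:
            raise ValueError("flank_window must be > 0")
        tree = self._bodies.get(chrom)
        if tree is None:
            if chrom not in self._warned:
                warnings.warn(f"chromosome {chrom!r} absent from annotation; "
                              "sites there are classified INTERGENIC")
                self._warned.add(chrom)
            return RegionClass.INTERGENIC, None
        hits = [iv.data for iv in tree.at(pos)]
        if hits:
            best = min(hits, key=lambda g: (_CLASS_RANK[self._within_gene(g, pos)], g.start))
            return self._within_gene(best, pos), best.gene_id
        near = [iv.data for iv in tree.overlap(pos - flank_window, pos + flank_window + 1)]
        if near:
            def distance(g: GeneModel) -> int:
                return g.start - pos if pos < g.start else pos - g.end
            best = min(near, key=lambda g: (distance(g), g.start))
            left_of_gene = pos < best.start
            upstream = left_of_gene if best.strand == "+" else not left_of_gene
            return (RegionClass.UPSTREAM if upstream else RegionClass.DOWNSTREAM,
                    best.gene_id)
        return RegionClass.INTERGENIC, None


def classify_region(site: TrioVariantSite, genes: GeneIndex | Iterable[GeneModel],
                    flank_window: int = 5000) -> RegionClass:
    """7-way gene-region class of a variant (UTRs take precedence over exons,
    exons over introns; flanks are strand-aware; nearest gene wins a flank
    tie, then the smaller start coordinate)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.classify(site.chrom, site.pos, flank_window)[0]


def apply_region_filter(
        classified: Iterable[tuple[TrioVariantSite, RegionClass]],
) -> list[tuple[TrioVariantSite, RegionClass]]:
    """Keep only sites in 5' UTR, exon or 3' UTR."""
    return [(s, c) for s, c in classified if c in RETAINED_CLASSES]


def variant_region_table(
        classified: Iterable[tuple[TrioVariantSite, RegionClass]]) -> pd.DataFrame:
    """Counts of SNVs and indels per retained region class (3 x 2 table)."""
    table = pd.DataFrame(0, index=[c.value for c in RETAINED_CLASSES],
                         columns=[v.value for v in VariantClass])
    n = 0
    for site, cls in classified:
        if cls not in RETAINED_CLASSES:
            raise ValueError(f"non-retained class {cls} in region table input")
        table.loc[cls.value, site.variant_class.value] += 1
        n += 1
    assert int(table.to_numpy().sum()) == n
    return table


def assign_gene_origin(gene: GeneModel,
                       assigned: Iterable[tuple[TrioVariantSite, ParentalAssignment]],
                       ) -> GeneOrigin:
    """Origin of one gene from its retained, parent-assigned sites."""
    n_donor = n_recipient = 0
    for site, assignment in assigned:
        if assignment is ParentalAssignment.DONOR:
            n_donor += 1
        elif assignment is ParentalAssignment.RECIPIENT:
            n_recipient += 1
    if n_donor and n_recipient:
        return GeneOrigin.CONFLICT
    if n_donor:
        return GeneOrigin.DONOR
    if n_recipient:
        return GeneOrigin.RECIPIENT
    return GeneOrigin.NON_POLYMORPHIC


def inheritance_fraction(donor_genes: int, recipient_genes: int,
                         ndigits: int | None = 1) -> float:
    """Percent of origin-assigned genes inherited from the donor:
    100 x donor / (donor + recipient), reported to one decimal by default
    (``ndigits=None`` returns the exact value)."""
    total = donor_genes + recipient_genes
    if total == 0:
        raise ValueError("no origin-assigned genes; fraction undefined")
    pct = 100.0 * donor_genes / total
    return pct if ndigits is None else round(pct, ndigits)


def detect_blocks(assignments: Iterable[tuple[str, int, ParentalAssignment]],
                  max_gap_sites: int = 2,
                  min_support_sites: int = 5) -> list[IntrogressionBlock]:
    """Delineate donor blocks as maximal runs of donor-assigned sites.

    Input must be sorted by (chromosome, position).  A run tolerates up to
    ``max_gap_sites`` consecutive non-donor informative sites (RECIPIENT or
    CONFLICT) in its interior; UNINFORMATIVE sites are transparent.  Runs
    supported by fewer than ``min_support_sites`` donor sites are dropped.
    Block bounds are the first and last supporting donor positions.
    """
    blocks: list[IntrogressionBlock] = []
    seen: set[str] = set()
    cur_chrom: str | None = None
    last_pos = -1
    donor_pos: list[int] = []
    interior = 0
    gap = 0

    def close() -> None:
        nonlocal donor_pos, interior, gap
        if len(donor_pos) >= min_support_sites:
            blocks.append(IntrogressionBlock(cur_chrom, donor_pos[0], donor_pos[-1],
                                             len(donor_pos), interior))
        donor_pos, interior, gap = [], 0, 0

    for chrom, pos, assignment in assignments:
        if chrom != cur_chrom:
            if chrom in seen:
                raise ValueError("input not sorted: chromosome revisited")
            close()
            seen.add(chrom)
            cur_chrom, last_pos = chrom, -1
        if pos < last_pos:
            raise ValueError(f"input not sorted at {chrom}:{pos}")
        last_pos = pos
        if assignment is ParentalAssignment.DONOR:
            if donor_pos:
                interior += gap
            gap = 0
            donor_pos.append(pos)
        elif assignment in (ParentalAssignment.RECIPIENT, ParentalAssignment.CONFLICT):
            if donor_pos:
                gap += 1
                if gap > max_gap_sites:
                    close()
    close()
    return blocks


def summarize_block(block: IntrogressionBlock,
                    genes: Iterable[GeneModel]) -> BlockSummary:
    """Span and overlapping-gene content of a block (>= 1 bp overlap counts)."""
    ids = tuple(sorted(g.gene_id for g in genes
                       if g.chrom == block.chrom
                       and g.start <= block.end and g.end >= block.start))
    return BlockSummary(block, block.span, len(ids), ids)


def chromosome_distribution(assignments: Iterable[tuple[str, int, ParentalAssignment]],
                            bin_size: int,
                            chrom_lengths: Mapping[str, int] | None = None,
                            ) -> pd.DataFrame:
    """Donor-site counts per genomic bin (columns: chrom, bin_start, count).

    ``chrom_lengths`` pads chromosomes with empty trailing bins so plots
    share a common axis; otherwise bins run to the last donor site.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    per_chrom: dict[str, dict[int, int]] = {}
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            per_chrom[chrom] = {b: 0 for b in range(1, length + 1, bin_size)}
    for chrom, pos, assignment in assignments:
        if assignment is not ParentalAssignment.DONOR:
            continue
        b = ((pos - 1) // bin_size) * bin_size + 1
        per_chrom.setdefault(chrom, {}).setdefault(b, 0)
        per_chrom[chrom][b] += 1
    rows = [(chrom, b, n) for chrom, bins in per_chrom.items()
            for b, n in sorted(bins.items())]
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "count"])


# ---------------------------------------------------------------------------
# model / results

class TrioIntrogressionModel:
    """Introgression mapping model for a donor/recipient/line trio.

    Parameters
    ----------
    sites
        Biallelic trio variant sites (any order; sorted internally).
    genes
        Gene models from the annotation.
    chrom_lengths
        Optional chromosome sizes, used for binned distributions/plots.
    """

    def __init__(self, sites: Iterable[TrioVariantSite], genes: Iterable[GeneModel],
                 chrom_lengths: Mapping[str, int] | None = None):
        order: dict[str, int] = {}
        for s in sites if isinstance(sites, list) else list(sites):
            order.setdefault(s.chrom, len(order))
        self.sites = sorted(sites, key=lambda s: (order[s.chrom], s.pos))
        self.genes = list(genes)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        self._index = GeneIndex(self.genes)

    @classmethod
    def from_files(cls, vcf_path: str | Path, gff_path: str | Path,
                   donor: str, recipient: str, line: str,
                   ) -> "TrioIntrogressionModel":
        """Build the model from a 3-sample VCF and a GFF3 annotation."""
        from . import io as _io
        sites, contigs = _io.read_trio_vcf(vcf_path, donor, recipient, line)
        genes = _io.read_gene_models(gff_path)
        return cls(sites, genes, chrom_lengths=contigs or None)

    def fit(self, min_quality: float = 20.0, flank_window: int = 5000,
            max_gap_sites: int = 2, min_support_sites: int = 5,
            ) -> "IntrogressionResults":
        """Run the full pipeline and return the results object."""
        retained = filter_quality(self.sites, min_quality)
        rows = []
        for s in retained:
            assignment = assign_parent(s)
            region, gene_id = self._index.classify(s.chrom, s.pos, flank_window)
            rows.append((s.chrom, s.pos, s.variant_class.value, s.qual,
                         assignment.value, region.value, gene_id))
        site_table = pd.DataFrame(
            rows, columns=["chrom", "pos", "variant_class", "qual",
                           "assignment", "region", "gene_id"])

        # Table-1-style summary: donor-assigned sites in retained regions
        retained_cls = {c.value for c in RETAINED_CLASSES}
        donor_genic = [(s, RegionClass(r)) for s, (a, r) in
                       zip(retained, site_table[["assignment", "region"]].itertuples(index=False))
                       if a == ParentalAssignment.DONOR.value and r in retained_cls]
        region_table = variant_region_table(donor_genic)

        # gene origins from retained (genic, parent-assigned) sites
        per_gene: dict[str, list[tuple[TrioVariantSite, ParentalAssignment]]] = {}
        for s, (a, r, g) in zip(retained,
                                site_table[["assignment", "region", "gene_id"]]
                                .itertuples(index=False)):
            if g is not None and r in retained_cls:
                per_gene.setdefault(g, []).append((s, ParentalAssignment(a)))
        gene_origins = pd.DataFrame(
            [(g.gene_id, assign_gene_origin(g, per_gene.get(g.gene_id, ())).value)
             for g in self.genes], columns=["gene_id", "origin"])
        origin_counts = gene_origins["origin"].value_counts()
        inheritance = InheritanceSummary(
            donor_genes=int(origin_counts.get(GeneOrigin.DONOR.value, 0)),
            recipient_genes=int(origin_counts.get(GeneOrigin.RECIPIENT.value, 0)),
            non_polymorphic_genes=int(origin_counts.get(GeneOrigin.NON_POLYMORPHIC.value, 0)),
            conflict_genes=int(origin_counts.get(GeneOrigin.CONFLICT.value, 0)))

        # block detection uses every informative site genome-wide
        assignments = [(c, p, ParentalAssignment(a)) for c, p, a in
                       site_table[["chrom", "pos", "assignment"]].itertuples(index=False)]
        blocks = detect_blocks(assignments, max_gap_sites, min_support_sites)
        summaries = [summarize_block(b, self.genes) for b in blocks]
        return IntrogressionResults(
            model=self, params=dict(min_quality=min_quality, flank_window=flank_window,
                                    max_gap_sites=max_gap_sites,
                                    min_support_sites=min_support_sites),
            site_table=site_table, region_table=region_table,
            gene_origins=gene_origins, inheritance=inheritance,
            blocks=blocks, block_summaries=summaries)


@dataclass
class IntrogressionResults:
    """Fitted introgression map: per-site assignments, region table, gene
    origins, inheritance fraction and donor blocks."""

    model: TrioIntrogressionModel
    params: dict
    site_table: pd.DataFrame
    region_table: pd.DataFrame
    gene_origins: pd.DataFrame
    inheritance: InheritanceSummary
    blocks: list[IntrogressionBlock]
    block_summaries: list[BlockSummary]

    def block_table(self) -> pd.DataFrame:
        rows = [(b.block.chrom, b.block.start, b.block.end, b.span,
                 b.block.n_donor_sites, b.block.n_interior_other, b.gene_count,
                 ",".join(b.gene_ids)) for b in self.block_summaries]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "span_bp",
                                           "donor_sites", "interior_other_sites",
                                           "gene_count", "gene_ids"])

    def chromosome_distribution(self, bin_size: int = 100_000) -> pd.DataFrame:
        assignments = [(c, p, ParentalAssignment(a)) for c, p, a in
                       self.site_table[["chrom", "pos", "assignment"]]
                       .itertuples(index=False)]
        return chromosome_distribution(assignments, bin_size,
                                       chrom_lengths=self.model.chrom_lengths)

    def plot_distribution(self, bin_size: int = 100_000, ax=None):
        """Per-chromosome histogram of donor-assigned sites."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        dist = self.chromosome_distribution(bin_size)
        chroms = list(dict.fromkeys(dist["chrom"]))
        if ax is None:
            _, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.6 * len(chroms)),
                                   sharex=True, squeeze=False)
            axes = axes.ravel()
        else:
            axes = [ax] * len(chroms)
        for a, chrom in zip(axes, chroms):
            sub = dist[dist["chrom"] == chrom]
            a.bar(sub["bin_start"], sub["count"], width=bin_size * 0.9, align="edge")
            a.set_ylabel(chrom, fontsize=8)
        axes[-1].set_xlabel("position (bp)")
        return axes

    def summary(self) -> str:
        inh = self.inheritance
        lines = [
            "Trio introgression mapping results",
            "==================================",
            f"sites analysed (QUAL >= {self.params['min_quality']:g}): "
            f"{len(self.site_table)}",
            "parental assignment: "
            + ", ".join(f"{k}={v}" for k, v in
                        self.site_table["assignment"].value_counts().items()),
            "",
            "Donor-inherited variants in retained regions (5' UTR / exon / 3' UTR):",
            self.region_table.to_string(),
            f"  total retained donor variants: {int(self.region_table.to_numpy().sum())}",
            "",
            f"gene origins: donor={inh.donor_genes} recipient={inh.recipient_genes} "
            f"non-polymorphic={inh.non_polymorphic_genes} conflict={inh.conflict_genes}",
            f"donor inheritance fraction: {inh.fraction_percent:.1f}%",
            "",
            f"donor blocks (max_gap_sites={self.params['max_gap_sites']}, "
            f"min_support_sites={self.params['min_support_sites']}): {len(self.blocks)}",
        ]
        for b in self.block_summaries:
            lines.append(f"  {b.block.chrom}:{b.block.start}-{b.block.end}  "
                         f"span {b.span / 1e6:.1f} Mb  donor sites "
                         f"{b.block.n_donor_sites}  genes {b.gene_count}")
        return "\n".join(lines)

    def to_tsv(self, outdir: str | Path) -> None:
        """Write site assignments, region table, gene origins, block table
        (TSV) and blocks as 0-based half-open BED."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.site_table.to_csv(outdir / "site_assignments.tsv", sep="\t", index=False)
        self.region_table.to_csv(outdir / "region_table.tsv", sep="\t",
                                 index_label="region")
        self.gene_origins.to_csv(outdir / "gene_origins.tsv", sep="\t", index=False)
        self.block_table().to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        with open(outdir / "blocks.bed", "w") as fh:
            for b in self.blocks:
                fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tdonor_block\t"
                         f"{b.n_donor_sites}\t.\n")
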