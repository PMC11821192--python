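"""Synthetic inputs for every pipeline stage, with recorded ground truth.

Three generators emulate the three data layers of an introgression-line
study without any sequencing data:

* :func:`generate_trio_dataset` — a small diploid genome with gene models
  and a trio of genotypes in which the derived line equals the recipient
  everywhere except inside planted donor blocks;
* :func:`generate_marker_templates` — a pair of ~1 kb allele sequences with
  embedded primer sites and a single discriminating restriction-site SNP;
* :func:`generate_nodule_assays` — per-nodule PCR/digest observations drawn
  with specified category proportions.

Each generator consumes one ``numpy`` Generator seeded from its config, in
a fixed field order (references, then gene models, then variants for the
trio generator), so a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .caps import (Amplicon, EnzymeSpec, IUPAC_CODES, PrimerPair, digest,
                   find_discriminating_enzymes, get_enzyme, in_silico_pcr,
                   load_enzyme_table, revcomp)
from .occupancy import AssayRecord, DigestPattern, NoduleCall
from .trio import GeneModel, Genotype, TrioVariantSite

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: primer pair targeting the rhizobial nodX gene (TOM/A1-specific)
DEFAULT_NODX_PRIMERS = PrimerPair(
    forward="GATGAATGCCACTTTCACAGTAAG",
    reverse="CAGATACTGCAAGATGCCGGTA")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside each synthetic dataset."""

    site_origin: dict | None = None          # (chrom, pos) -> "donor"/"recipient"
    donor_blocks: tuple | None = None        # (chrom, start, end) planted blocks
    gene_origin: dict | None = None          # gene_id -> "donor"/"recipient"
    enzyme_name: str | None = None           # marker: planted discriminating enzyme
    site_position: int | None = None         # marker: 1-based start of planted site
    difference_positions: tuple | None = None
    categories: dict | None = None           # assays: nodule_id -> category name

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k):
                        _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        with open(path, "w") as fh:
            json.dump({k: _clean(v) for k, v in asdict(self).items()
                       if v is not None}, fh, indent=1)


@dataclass
class TrioSimConfig:
    """Study conditions for the synthetic trio.

    Defaults give three 1 Mb chromosomes at a variant density of
    1.7e-3 / bp (~5,000 variants overall) with an SNV:indel ratio of 29:1,
    echoing the scale at which fixed differences between two pea cultivars
    are observed once scaled to a toy genome.
    """

    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000, 1_000_000)
    variant_density: float = 1.7e-3
    donor_blocks: tuple[tuple[str, int, int], ...] = ()
    het_fraction: float = 0.0
    missing_fraction: float = 0.0
    discordant_fraction: float = 0.9
    snv_indel_ratio: float = 29.0
    qual_shape: float = 4.0
    qual_scale: float = 20.0
    n_genes: int = 120
    mean_gene_length: int = 3000
    mean_exon_length: int = 300
    mean_utr_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        for frac in (self.het_fraction, self.missing_fraction, self.discordant_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.het_fraction + self.missing_fraction > 1.0:
            raise ValueError("het_fraction + missing_fraction must be <= 1")
        if self.variant_density <= 0 or self.variant_density > 1:
            raise ValueError("variant density must lie in (0, 1]")
        names = self.chrom_names
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.donor_blocks:
            if chrom not in names:
                raise ValueError(f"donor block on unknown chromosome {chrom!r}")
            length = self.chrom_lengths[names.index(chrom)]
            if not 1 <= start <= end <= length:
                raise ValueError(f"donor block {chrom}:{start}-{end} outside chromosome")
            per_chrom.setdefault(chrom, []).append((start, end))
        for chrom, blocks in per_chrom.items():
            blocks.sort()
            for (a0, b0), (a1, b1) in zip(blocks, blocks[1:]):
                if a1 <= b0:
                    raise ValueError(f"overlapping donor blocks on {chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass
class TrioDataset:
    """In-memory synthetic trio dataset plus its ground truth."""

    config: TrioSimConfig
    references: dict[str, str]
    genes: list[GeneModel]
    sites: list[TrioVariantSite]
    truth: SimTruth
    sample_names: tuple[str, str, str] = ("donor", "recipient", "line")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.config.chrom_names, self.config.chrom_lengths))

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "reference.fa", "gff": outdir / "genes.gff3",
                 "vcf": outdir / "trio.vcf", "truth": outdir / "truth.json"}
        _io.write_fasta(self.references, paths["fasta"])
        _io.write_gene_models_gff3(self.genes, paths["gff"])
        _io.write_trio_vcf(paths["vcf"], self.sites, self.sample_names,
                           self.chrom_lengths)
        self.truth.to_json(paths["truth"])
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
               cfg: TrioSimConfig) -> GeneModel:
    """One single-transcript gene; UTRs are sub-intervals of terminal exons."""
    utr5 = max(30, int(rng.poisson(cfg.mean_utr_length)))
    utr3 = max(30, int(rng.poisson(cfg.mean_utr_length)))
    n_exons = int(rng.integers(2, 5))
    exon_lens = [max(80, int(rng.poisson(cfg.mean_exon_length))) for _ in range(n_exons)]
    exon_lens[0] += utr5
    exon_lens[-1] += utr3
    intron_lens = [max(60, int(rng.poisson(400))) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < n_exons - 1:
            pos += intron_lens[i]
    end = exons[-1][1]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        five = ((start, start + utr5 - 1),)
        three = ((end - utr3 + 1, end),)
    else:
        five = ((end - utr3 + 1, end),)
        three = ((start, start + utr5 - 1),)
    return GeneModel(gene_id, chrom, start, end, strand, tuple(exons), five, three)


def _place_genes(rng: np.random.Generator, cfg: TrioSimConfig) -> list[GeneModel]:
    genes: list[GeneModel] = []
    total_len = sum(cfg.chrom_lengths)
    counter = 0
    for chrom, length in zip(cfg.chrom_names, cfg.chrom_lengths):
        n_target = max(1, round(cfg.n_genes * length / total_len))
        mean_gap = max(300.0, length / n_target - cfg.mean_gene_length)
        cursor = 1 + int(rng.exponential(mean_gap / 2))
        for _ in range(n_target):
            counter += 1
            gene = _make_gene(rng, f"gene{counter:04d}", chrom, cursor, cfg)
            if gene.end > length:
                counter -= 1
                break
            genes.append(gene)
            cursor = gene.end + 1 + max(200, int(rng.exponential(mean_gap)))
    return genes


def _apply_noise(rng: np.random.Generator, gts: list[Genotype],
                 cfg: TrioSimConfig) -> list[Genotype]:
    u = rng.random()
    which = int(rng.integers(0, 3))  # drawn unconditionally to keep stream alignment
    if u < cfg.het_fraction:
        gts[which] = Genotype.HET
    elif u < cfg.het_fraction + cfg.missing_fraction:
        gts[which] = Genotype.MISSING
    return gts


def generate_trio_dataset(config: TrioSimConfig) -> TrioDataset:
    """Generate references, gene models, trio variant sites and truth.

    Inside every planted donor block the line's genotype equals the donor's
    at donor/recipient-discordant sites; everywhere else it equals the
    recipient's.  Heterozygous/missing noise is applied afterwards, one
    randomly chosen sample per affected site.
    """
    rng = np.random.default_rng(config.seed)
    references = {chrom: _random_seq(rng, length)
                  for chrom, length in zip(config.chrom_names, config.chrom_lengths)}
    genes = _place_genes(rng, config)
    blocks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in config.donor_blocks:
        blocks_by_chrom.setdefault(chrom, []).append((start, end))

    sites: list[TrioVariantSite] = []
    site_origin: dict[tuple[str, int], str] = {}
    snv_prob = config.snv_indel_ratio / (config.snv_indel_ratio + 1.0)
    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        ref_seq = references[chrom]
        n = int(rng.poisson(config.variant_density * length))
        n = min(n, length - 10)
        positions = np.sort(rng.choice(np.arange(1, length - 6), size=n, replace=False))
        for pos in positions:
            pos = int(pos)
            ref_base = ref_seq[pos - 1]
            if rng.random() < snv_prob:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref = ref_base
            else:  # short indel anchored at pos
                ilen = int(rng.integers(1, 6))
                if rng.random() < 0.5:  # deletion
                    ref = ref_seq[pos - 1:pos + ilen]
                    alt = ref_base
                else:  # insertion
                    ref = ref_base
                    alt = ref_base + _random_seq(rng, ilen)
            discordant = rng.random() < config.discordant_fraction
            if discordant:
                donor_alt = rng.random() < 0.5
                gt_d = Genotype.HOM_ALT if donor_alt else Genotype.HOM_REF
                gt_r = Genotype.HOM_REF if donor_alt else Genotype.HOM_ALT
            else:
                gt_d = gt_r = Genotype.HOM_ALT
            in_block = any(a <= pos <= b for a, b in blocks_by_chrom.get(chrom, ()))
            gt_l = gt_d if in_block else gt_r
            if discordant:
                site_origin[(chrom, pos)] = "donor" if in_block else "recipient"
            gt_d, gt_r, gt_l = _apply_noise(rng, [gt_d, gt_r, gt_l], config)
            qual = round(float(rng.gamma(config.qual_shape, config.qual_scale)), 1)
            sites.append(TrioVariantSite(chrom, pos, ref, alt, qual, gt_d, gt_r, gt_l))

    gene_origin = {}
    for g in genes:
        overlaps = any(g.start <= b and g.end >= a
                       for a, b in blocks_by_chrom.get(g.chrom, ()))
        gene_origin[g.gene_id] = "donor" if overlaps else "recipient"
    truth = SimTruth(site_origin=site_origin,
                     donor_blocks=tuple(config.donor_blocks),
                     gene_origin=gene_origin)
    return TrioDataset(config, references, genes, sites, truth)


# ---------------------------------------------------------------------------
# marker templates

@dataclass
class MarkerTemplates:
    allele_a: str   # carries the planted recognition site
    allele_b: str   # site destroyed by one substitution
    primer_pair: PrimerPair
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "alleles.fa", "truth": outdir / "truth.json"}
        _io.write_fasta({"allele_A": self.allele_a, "allele_B": self.allele_b},
                        paths["fasta"])
        self.truth.to_json(paths["truth"])
        return paths


def _concrete_site(rng: np.random.Generator, pattern: str) -> str:
    """A concrete realisation of an IUPAC pattern."""
    return "".join(str(rng.choice(sorted(IUPAC_CODES[c]))) for c in pattern.upper())


def _destroy_site(rng: np.random.Generator, site: str, pattern: str) -> tuple[int, str]:
    """(offset, base) substitution inside ``site`` that breaks ``pattern``."""
    # prefer the most constrained pattern position: any disallowed base breaks it
    offsets = sorted(range(len(pattern)), key=lambda i: len(IUPAC_CODES[pattern[i].upper()]))
    off = offsets[0]
    allowed = IUPAC_CODES[pattern[off].upper()]
    choices = [b for b in "ACGT" if b not in allowed and b != site[off]]
    if not choices:
        choices = [b for b in "ACGT" if b not in allowed]
    return off, str(rng.choice(choices))


def generate_marker_templates(seed: int, length: int = 1106,
                              n_differences: int = 24,
                              primer_pair: PrimerPair = DEFAULT_NODX_PRIMERS,
                              enzyme: EnzymeSpec | str = "RsaI",
                              plant_site: bool = True,
                              enzyme_table: Sequence[EnzymeSpec] | None = None,
                              max_attempts: int = 200) -> MarkerTemplates:
    """Two allele templates differing at ``n_differences`` positions, one of
    which (when ``plant_site``) creates/destroys the recognition site of the
    chosen enzyme.

    The random background is resampled until both alleles amplify as exactly
    one product with the given primers, the amplicons cover the planted
    site, and — for a single-difference pair — the planted enzyme is the
    only discriminating enzyme in the table; this keeps the generated pair a
    clean positive control rather than a probabilistic one.
    """
    if n_differences < 0:
        raise ValueError("n_differences must be >= 0")
    if plant_site and n_differences == 0:
        raise ValueError("cannot plant a discriminating site with zero differences")
    if isinstance(enzyme, str):
        enzyme = get_enzyme(enzyme, enzyme_table)
    table = list(enzyme_table) if enzyme_table is not None else load_enzyme_table()
    rng = np.random.default_rng(seed)
    f, r = primer_pair.forward.upper(), primer_pair.reverse.upper()
    plen = len(enzyme.pattern)
    f_start = 10                     # 0-based primer footprint offsets
    r_start = length - len(r) - 10
    if r_start <= f_start + len(f) + plen + 20:
        raise ValueError("template too short for primers and planted site")
    reserved = set(range(f_start, f_start + len(f))) | set(range(r_start, r_start + len(r)))

    for _ in range(max_attempts):
        base = list(_random_seq(rng, length))
        base[f_start:f_start + len(f)] = f
        base[r_start:r_start + len(r)] = revcomp(r)
        free = [i for i in range(f_start + len(f) + 2, r_start - plen - 2)
                if i not in reserved]
        diff_positions: list[int] = []
        allele_a = list(base)
        allele_b = list(base)
        if plant_site:
            site_start = int(rng.choice(free[:len(free) - plen]))
            site = _concrete_site(rng, enzyme.pattern)
            allele_a[site_start:site_start + plen] = site
            allele_b[site_start:site_start + plen] = site
            off, broken = _destroy_site(rng, site, enzyme.pattern)
            allele_b[site_start + off] = broken
            diff_positions.append(site_start + off)
            blocked = set(range(site_start, site_start + plen))
        else:
            site_start = None
            blocked = set()
        n_extra = n_differences - len(diff_positions)
        candidates = [i for i in free if i not in blocked]
        for i in map(int, rng.choice(candidates, size=n_extra, replace=False)) \
                if n_extra else []:
            allele_b[i] = str(rng.choice([b for b in "ACGT" if b != allele_b[i]]))
            diff_positions.append(i)
        seq_a, seq_b = "".join(allele_a), "".join(allele_b)

        amps_a = in_silico_pcr(seq_a, primer_pair, max_product=length, template_id="A")
        amps_b = in_silico_pcr(seq_b, primer_pair, max_product=length, template_id="B")
        if len(amps_a) != 1 or len(amps_b) != 1:
            continue
        if plant_site:
            if not (amps_a[0].start <= site_start + 1
                    and site_start + plen <= amps_a[0].end):
                continue
            markers = find_discriminating_enzymes(amps_a[0], amps_b[0], table)
            names = {m.enzyme.name for m in markers}
            if enzyme.name not in names:
                continue
            if n_differences == 1 and names != {enzyme.name}:
                continue
        truth = SimTruth(enzyme_name=enzyme.name if plant_site else None,
                         site_position=site_start + 1 if plant_site else None,
                         difference_positions=tuple(sorted(p + 1 for p in diff_positions)))
        return MarkerTemplates(seq_a, seq_b, primer_pair, truth)
    raise RuntimeError(f"failed to generate marker templates in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# nodule assays

_CATEGORY_FIELDS: dict[NoduleCall, tuple[bool, bool, DigestPattern]] = {
    NoduleCall.FAILED: (False, False, DigestPattern.NA),
    NoduleCall.NODX_MINUS: (True, False, DigestPattern.NA),
    NoduleCall.TOM_ONLY: (True, True, DigestPattern.CUT),
    NoduleCall.NON_TOM_ONLY: (True, True, DigestPattern.UNCUT),
    NoduleCall.MIXED: (True, True, DigestPattern.BOTH),
}


@dataclass
class AssayDataset:
    records: list[AssayRecord]
    truth: SimTruth

    def write(self, path: str | Path) -> None:
        rows = [(r.nodule_id, r.group, int(r.control_band), int(r.target_band),
                 r.digest_pattern.value) for r in self.records]
        pd.DataFrame(rows, columns=["nodule_id", "group", "control_band",
                                    "target_band", "digest_pattern"]
                     ).to_csv(path, sep="\t", index=False)


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer counts summing to ``n`` closest to ``n * p`` (largest-remainder
    rounding; ties broken by declaration order)."""
    raw = [n * p for p in proportions]
    base = [math.floor(x) for x in raw]
    short = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def generate_nodule_assays(seed: int, group_sizes: Mapping[str, int],
                           proportions: Mapping[str, Mapping[str, float]],
                           mode: str = "exact") -> AssayDataset:
    """Per-nodule assay records with specified per-group category proportions.

    ``proportions`` maps each group to {category name: proportion}; the
    categories are :class:`NoduleCall` names.  In ``exact`` mode counts are
    the largest-remainder rounding of n*p; in ``multinomial`` mode they are
    drawn from a multinomial with those probabilities.
    """
    if mode not in ("exact", "multinomial"):
        raise ValueError("mode must be 'exact' or 'multinomial'")
    rng = np.random.default_rng(seed)
    records: list[AssayRecord] = []
    categories_truth: dict[str, str] = {}
    for group, n in group_sizes.items():
        if n <= 0:
            raise ValueError(f"group {group!r} has size {n}")
        props = proportions[group]
        cats = [NoduleCall(c) for c in props]
        p = [float(props[c.value]) for c in cats]
        if any(x < 0 for x in p):
            raise ValueError("negative proportions")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"proportions for group {group!r} sum to {sum(p)}")
        if mode == "exact":
            counts = largest_remainder_counts(n, p)
        else:
            counts = rng.multinomial(n, p).tolist()
        i = 0
        for cat, count in zip(cats, counts):
            control, target, pattern = _CATEGORY_FIELDS[cat]
            for _ in range(count):
                i += 1
                nid = f"{group}_{i:03d}"
                records.append(AssayRecord(nid, group, control, target, pattern))
                categories_truth[nid] = cat.value
    return AssayDataset(records, SimTruth(categories=categories_truth))
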