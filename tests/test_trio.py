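"""Parental assignment, region classification and block detection."""

from collections import defaultdict

import numpy as np
import pytest

from introcaps.trio import (GeneIndex, GeneModel, GeneOrigin, Genotype,
                            IntrogressionBlock, ParentalAssignment, RegionClass,
                            assign_gene_origin, assign_parent,
                            chromosome_distribution, classify_region,
                            detect_blocks, filter_quality, inheritance_fraction,
                            summarize_block, variant_region_table)

from conftest import make_site

D, R, U, C = (ParentalAssignment.DONOR, ParentalAssignment.RECIPIENT,
              ParentalAssignment.UNINFORMATIVE, ParentalAssignment.CONFLICT)


def brute_force_blocks(assignments, max_gap_sites, min_support_sites):
    """Enumerate every qualifying donor run and keep the maximal ones."""
    per = defaultdict(list)
    for chrom, pos, a in assignments:
        if a in (D, R, C):
            per[chrom].append((pos, a))
    blocks = []
    for chrom, items in per.items():
        donor_idx = [i for i, (_, a) in enumerate(items) if a is D]
        qualifying = []
        for ii in range(len(donor_idx)):
            for jj in range(ii, len(donor_idx)):
                i, j = donor_idx[ii], donor_idx[jj]
                run = donor_idx[ii:jj + 1]
                if any(b - a - 1 > max_gap_sites for a, b in zip(run, run[1:])):
                    continue
                if len(run) >= min_support_sites:
                    qualifying.append((i, j))
        maximal = [(i, j) for i, j in qualifying
                   if not any(x <= i and j <= y and (x, y) != (i, j)
                              for x, y in qualifying)]
        for i, j in sorted(maximal):
            n_donor = sum(1 for k in range(i, j + 1) if items[k][1] is D)
            interior = (j - i + 1) - n_donor
            blocks.append(IntrogressionBlock(chrom, items[i][0], items[j][0],
                                             n_donor, interior))
    return blocks


class TestQualityFilter:
    def test_boundary_is_inclusive(self):
        sites = [make_site(qual=20.0), make_site(pos=200, qual=19.9)]
        kept = filter_quality(sites, 20)
        assert [s.qual for s in kept] == [20.0]

    def test_empty_and_order(self):
        assert filter_quality([], 20) == []
        sites = [make_site(pos=p, qual=q) for p, q in ((5, 30), (1, 40), (9, 25))]
        assert [s.pos for s in filter_quality(sites, 20)] == [5, 1, 9]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_quality([], -1)


class TestAssignParent:
    HR, HA, HET, MISS, OTH = (Genotype.HOM_REF, Genotype.HOM_ALT, Genotype.HET,
                              Genotype.MISSING, Genotype.HOM_OTHER)

    @pytest.mark.parametrize("donor,recipient,line,expected", [
        ("HA", "HR", "HA", D),           # line matches donor
        ("HR", "HA", "HR", D),           # symmetric allele orientation
        ("HA", "HR", "HR", R),           # line matches recipient
        ("HA", "HA", "HA", U),           # parents agree: uninformative
        ("HET", "HR", "HA", U),          # het anywhere: uninformative
        ("HA", "MISS", "HA", U),         # missing anywhere: uninformative
        ("HA", "HR", "HET", U),
        ("HA", "HR", "OTH", C),          # line allele absent from both parents
    ])
    def test_rules(self, donor, recipient, line, expected):
        gts = {"HR": self.HR, "HA": self.HA, "HET": self.HET,
               "MISS": self.MISS, "OTH": self.OTH}
        site = make_site(donor=gts[donor], recipient=gts[recipient], line=gts[line])
        assert assign_parent(site) is expected


class TestClassifyRegion:
    def classify(self, pos, genes, flank=5000):
        return classify_region(make_site(pos=pos), genes, flank_window=flank)

    def test_seven_classes_plus_strand(self, plus_gene):
        genes = [plus_gene]
        assert self.classify(1050, genes) is RegionClass.FIVE_UTR   # UTR > exon
        assert self.classify(1200, genes) is RegionClass.EXON
        assert self.classify(3950, genes) is RegionClass.THREE_UTR
        assert self.classify(1700, genes) is RegionClass.INTRON
        assert self.classify(900, genes) is RegionClass.UPSTREAM
        assert self.classify(4100, genes) is RegionClass.DOWNSTREAM
        assert self.classify(400_000, genes) is RegionClass.INTERGENIC

    def test_strand_aware_flanks(self, minus_gene):
        genes = [minus_gene]
        assert self.classify(23500, genes) is RegionClass.UPSTREAM
        assert self.classify(19500, genes) is RegionClass.DOWNSTREAM
        assert self.classify(22950, genes) is RegionClass.FIVE_UTR
        assert self.classify(20050, genes) is RegionClass.THREE_UTR

    def test_flank_window_limits(self, plus_gene):
        assert self.classify(4000 + 5000, [plus_gene]) is RegionClass.DOWNSTREAM
        assert self.classify(4000 + 5001, [plus_gene]) is RegionClass.INTERGENIC

    def test_nearest_gene_wins_overlapping_flanks(self, plus_gene, minus_gene):
        # 4001..20000 separates the genes; 10 kb windows overlap in 10001..14000
        genes = [plus_gene, minus_gene]
        assert self.classify(11000, genes, flank=10_000) is RegionClass.DOWNSTREAM  # gplus, +
        assert self.classify(13000, genes, flank=10_000) is RegionClass.DOWNSTREAM  # gminus, -

    def test_flank_tie_broken_by_smaller_start(self):
        # two + strand genes equidistant from pos 3000: ga (ends 2000) wins,
        # making the position DOWNSTREAM rather than gb's UPSTREAM
        ga = GeneModel("ga", "chr1", 1000, 2000, "+", ((1000, 2000),))
        gb = GeneModel("gb", "chr1", 4000, 5000, "+", ((4000, 5000),))
        assert self.classify(3000, [ga, gb]) is RegionClass.DOWNSTREAM

    def test_absent_chromosome_warns_intergenic(self, plus_gene):
        site = make_site(chrom="chrZ")
        with pytest.warns(UserWarning):
            assert classify_region(site, [plus_gene]) is RegionClass.INTERGENIC


class TestRegionTable:
    def test_region_filter(self, plus_gene):
        pairs = [(make_site(pos=1200), RegionClass.EXON),
                 (make_site(pos=1700), RegionClass.INTRON),
                 (make_site(pos=900), RegionClass.UPSTREAM),
                 (make_site(pos=1050), RegionClass.FIVE_UTR)]
        from introcaps.trio import apply_region_filter
        kept = apply_region_filter(pairs)
        assert [c for _, c in kept] == [RegionClass.EXON, RegionClass.FIVE_UTR]

    def test_counts_by_class_and_variant_type(self):
        pairs = [(make_site(pos=1), RegionClass.EXON),
                 (make_site(pos=2), RegionClass.EXON),
                 (make_site(pos=3, ref="A", alt="AT"), RegionClass.FIVE_UTR)]
        table = variant_region_table(pairs)
        assert table.loc["EXON", "SNV"] == 2
        assert table.loc["FIVE_UTR", "indel"] == 1
        assert int(table.to_numpy().sum()) == 3

    def test_non_retained_class_rejected(self):
        with pytest.raises(ValueError):
            variant_region_table([(make_site(), RegionClass.INTRON)])

    def test_empty_input_all_zero(self):
        assert int(variant_region_table([]).to_numpy().sum()) == 0


class TestGeneOrigin:
    def test_rules(self, plus_gene):
        s = make_site()
        donor_sites = [(s, D)] * 3
        assert assign_gene_origin(plus_gene, donor_sites) is GeneOrigin.DONOR
        assert assign_gene_origin(plus_gene, []) is GeneOrigin.NON_POLYMORPHIC
        assert assign_gene_origin(plus_gene, [(s, D), (s, R)]) is GeneOrigin.CONFLICT
        assert assign_gene_origin(plus_gene, [(s, R), (s, U)]) is GeneOrigin.RECIPIENT


class TestInheritanceFraction:
    def test_reported_values(self):
        assert inheritance_fraction(464, 14365) == 3.1
        assert inheritance_fraction(0, 1000) == 0.0
        assert inheritance_fraction(7, 7) == 50.0

    def test_complement_sums_to_100_exactly(self):
        for a, b in ((464, 14365), (1, 999), (123, 4567)):
            assert inheritance_fraction(a, b, ndigits=None) + \
                inheritance_fraction(b, a, ndigits=None) == 100.0

    def test_undefined_when_no_assigned_genes(self):
        with pytest.raises(ValueError):
            inheritance_fraction(0, 0)


class TestDetectBlocks:
    def test_uninterrupted_run(self):
        asg = [("chr1", 100 * i, D) for i in range(1, 11)]
        (block,) = detect_blocks(asg, max_gap_sites=0, min_support_sites=5)
        assert (block.start, block.end, block.n_donor_sites) == (100, 1000, 10)

    def test_gap_rule_splits_runs(self):
        asg = ([("chr1", i, D) for i in range(1, 7)]
               + [("chr1", 10, R)]
               + [("chr1", 20 + i, D) for i in range(6)])
        assert len(detect_blocks(asg, max_gap_sites=0, min_support_sites=5)) == 2
        assert len(detect_blocks(asg, max_gap_sites=1, min_support_sites=5)) == 1

    def test_uninformative_sites_are_transparent(self):
        asg = [("chr1", 1, D), ("chr1", 2, U), ("chr1", 3, U), ("chr1", 4, U),
               ("chr1", 5, D), ("chr1", 6, D), ("chr1", 7, D), ("chr1", 8, D)]
        (block,) = detect_blocks(asg, max_gap_sites=0, min_support_sites=5)
        assert block.n_donor_sites == 5 and block.n_interior_other == 0

    def test_min_support_discards_small_runs(self):
        asg = [("chr1", i, D) for i in (1, 2, 3)]
        assert detect_blocks(asg, max_gap_sites=2, min_support_sites=5) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            detect_blocks([("chr1", 10, D), ("chr1", 5, D)])
        with pytest.raises(ValueError):
            detect_blocks([("chr1", 1, D), ("chr2", 1, D), ("chr1", 2, D)])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_enumeration(self, seed):
        """Greedy block delineation equals exhaustive maximal-run search."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 201))
        positions = np.sort(rng.choice(np.arange(1, 10_000), size=n, replace=False))
        labels = rng.choice([D, R, U, C], size=n, p=[0.55, 0.25, 0.15, 0.05])
        asg = [("chr1", int(p), a) for p, a in zip(positions, labels)]
        max_gap = int(rng.integers(0, 4))
        min_support = int(rng.integers(1, 7))
        got = detect_blocks(asg, max_gap, min_support)
        expected = brute_force_blocks(asg, max_gap, min_support)
        assert got == expected


class TestSummaries:
    def test_block_span_and_gene_overlap(self, plus_gene):
        block = IntrogressionBlock("chr1", 100, 1099, 10, 0)
        overlapping = GeneModel("g2", "chr1", 50, 150, "+", ((50, 150),))
        distant = GeneModel("g3", "chr1", 2000, 2500, "+", ((2000, 2500),))
        summary = summarize_block(block, [overlapping, distant, plus_gene])
        assert summary.span == 1000
        assert summary.gene_ids == ("g2", "gplus")  # gplus starts at 1001 <= 1099

    def test_chromosome_distribution_conserves_counts(self):
        rng = np.random.default_rng(7)
        asg = [("chr1", int(p), D) for p in
               np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))]
        asg += [("chr2", 10, R)]
        dist = chromosome_distribution(asg, bin_size=10_000)
        assert int(dist["count"].sum()) == 50
        first_bin = [("chr1", i, D) for i in range(1, 6)]
        d2 = chromosome_distribution(first_bin, bin_size=1000)
        assert d2.iloc[0]["count"] == 5 and d2.iloc[0]["bin_start"] == 1

    def test_empty_chromosome_padded_with_zero_bins(self):
        dist = chromosome_distribution([], bin_size=1000,
                                       chrom_lengths={"chr1": 5000})
        assert len(dist) == 5 and dist["count"].sum() == 0
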